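#!/usr/bin/env python
"""Depth attenuation: red vs green indicator length constants.

Simulates 19 red-GECI and 14 green-GECI dendrite brightness profiles
(generator truths 130 um and 75 um, 10% multiplicative noise), fits an
exponential per dendrite, and compares the groups with a rank-sum test.
Output: results/depth_summary.csv.
"""

from pathlib import Path

import pandas as pd

from gecibench.benchmarks import depth_attenuation_recovery


def main():
    med_red, med_green, p, n_red, n_green = depth_attenuation_recovery(seed=1)
    df = pd.DataFrame(
        {
            "group": ["red", "green"],
            "n_dendrites": [n_red, n_green],
            "true_lambda_um": [130.0, 75.0],
            "median_fitted_lambda_um": [med_red, med_green],
        }
    )
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/depth_summary.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"rank-sum red vs green: p = {p:.2e}")
    print("wrote results/depth_summary.csv")


if __name__ == "__main__":
    main()
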