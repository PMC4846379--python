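"""Depth-dependent fluorescence attenuation.

For a fixed excitation power, measured fluorescence from a dendrite
decays approximately exponentially with imaging depth below the pia
because of scattering and absorption, F(z) = F0 * exp(-z / lambda).
Red indicators attenuate more slowly (longer length constant lambda)
than green ones. Profiles are fitted per dendrite; groups of fits are
summarized as median +/- sd and compared with a two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit


@dataclass
class DepthProfile:
    """Fluorescence of one dendrite sampled at increasing depths (um)."""

    depths: np.ndarray
    fluorescence: np.ndarray
    dendrite_id: int | str = 0
    indicator: str = ""

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.depths) < 4:
            raise ValueError("need at least 4 depth points")
        if len(self.depths) != len(self.fluorescence):
            raise ValueError("depths and fluorescence lengths differ")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.fluorescence <= 0):
            raise ValueError("fluorescence must be positive")


class DepthFit(NamedTuple):
    lambda_um: float
    f_surface: float  # fitted fluorescence at the shallowest depth
    r_squared: float
    ok: bool  # False when the profile does not decay


def fit_depth_profile(profile: DepthProfile, nonlinear: bool = False) -> DepthFit:
    """Exponential attenuation fit, F(z) = F(z0) * exp(-(z - z0)/lambda).

    Default is an unweighted log-linear least-squares fit; the
    nonlinear option refines it with a direct exponential fit. A
    non-decaying profile (slope >= 0 in log space) is flagged with
    lambda = inf.
    """
    z = profile.depths - profile.depths[0]
    logf = np.log(profile.fluorescence)
    slope, intercept = np.polyfit(z, logf, 1)
    if slope >= 0:
        return DepthFit(np.inf, float(np.exp(intercept)), 0.0, False)
    lam = -1.0 / slope
    f0 = float(np.exp(intercept))
    if nonlinear:
        popt, _ = curve_fit(
            lambda zz, f, l: f * np.exp(-zz / l),
            z, profile.fluorescence, p0=[f0, lam], maxfev=10000,
        )
        f0, lam = float(popt[0]), float(popt[1])
        resid = profile.fluorescence - f0 * np.exp(-z / lam)
        ss_tot = float(((profile.fluorescence - profile.fluorescence.mean()) ** 2).sum())
    else:
        resid = logf - (intercept + slope * z)
        ss_tot = float(((logf - logf.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return DepthFit(float(lam), f0, r2, True)


def summarize_attenuation(
    groups: dict[str, Sequence[DepthProfile]], nonlinear: bool = False
) -> tuple[pd.DataFrame, float]:
    """Per-group median/sd of fitted length constants plus a rank-sum p.

    ``groups`` maps a group label (e.g. indicator class "red"/"green")
    to its profiles; each group needs at least 2. The p-value is the
    two-sided Wilcoxon rank-sum comparison between the two groups (NaN
    when the number of groups differs from two).
    """
    rows = {}
    for label, profiles in groups.items():
        if len(profiles) < 2:
            raise ValueError("need at least 2 profiles per group")
        lams = np.array(
            [fit_depth_profile(p, nonlinear=nonlinear).lambda_um for p in profiles]
        )
        lams = lams[np.isfinite(lams)]
        rows[label] = lams
    summary = pd.DataFrame(
        {
            "group": list(rows),
            "n": [len(v) for v in rows.values()],
            "median_lambda_um": [float(np.median(v)) for v in rows.values()],
            "sd_lambda_um": [float(np.std(v, ddof=1)) for v in rows.values()],
        }
    )
    if len(rows) == 2:
        a, b = rows.values()
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        p = np.nan
    return summary, p
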