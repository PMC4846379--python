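"""Convenience chains over the per-stage modules.

These helpers wire the stages together the way the analysis drivers
use them: raw two-channel recordings -> neuropil-corrected traces ->
per-cell trial tables -> responsiveness/tuning results.
"""

from __future__ import annotations

import pandas as pd

from .synth import Population
from .traceproc import CorrectionParams, Trace, neuropil_correct
from .tuning import TrialTable, build_trial_table, classify_responsive, fit_tuning


def corrected_traces(pop: Population, params: CorrectionParams | None = None) -> dict[int, Trace]:
    """Neuropil-correct every cell of a simulated population."""
    params = params or CorrectionParams()
    return {
        cell.cell_id: neuropil_correct(cell.f_meas, cell.f_np, params)
        for cell in pop.cells
    }


def population_trial_tables(
    pop: Population, params: CorrectionParams | None = None
) -> dict[int, TrialTable]:
    corr = corrected_traces(pop, params)
    return {
        cid: build_trial_table(tr, pop.schedule, cell_id=cid)
        for cid, tr in corr.items()
    }


def tuning_results(
    pop: Population,
    params: CorrectionParams | None = None,
    dff_min: float = 0.05,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-cell responsiveness and tuning-fit table for a population."""
    tables = population_trial_tables(pop, params)
    rows = []
    for cid, table in tables.items():
        responsive, p = classify_responsive(table, dff_min=dff_min, alpha=alpha)
        rec = {"cell_id": cid, "responsive": responsive, "p_anova": p}
        if responsive:
            fit = fit_tuning(table)
            rec.update(
                theta_pref=fit.theta_pref,
                sigma=fit.sigma,
                A1=fit.a1,
                A2=fit.a2,
                B=fit.baseline,
                OSI=fit.osi,
                degenerate=fit.degenerate,
            )
        rows.append(rec)
    return pd.DataFrame(rows)
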