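"""Visual responsiveness and orientation tuning.

Cells are classified as visually responsive when their trial-averaged
stimulus-period ΔF/F0 exceeds 0.05 for at least one grating direction
AND a one-way ANOVA across the nine trial groups (blank + 8 directions)
rejects at p < 0.01. The eight-point tuning curve of a responsive cell
is fitted with a constant baseline plus two wrapped Gaussians of common
width sigma centered on the preferred direction and the direction
``delta`` away (180 degrees by default); the orientation selectivity
index is OSI = (R_pref - R_ortho) / (R_pref + R_ortho), evaluated from
the fitted model at the preferred direction and 90 degrees away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .traceproc import Trace, compute_dff, compute_f0

DIRECTIONS = np.arange(0.0, 360.0, 45.0)


@dataclass
class TrialTable:
    """Per-cell trial responses: (8 directions x 5 trials) stimulus means.

    ``responses[i, j]`` is the mean ΔF/F0 over the stimulus period of
    the j-th trial at direction ``DIRECTIONS[i]``; ``blanks`` holds the
    matching blank-period means. For the ANOVA the blank group is
    condensed to one observation per repetition cycle (the mean of the
    8 blank periods within the cycle), giving nine groups of equal
    size.
    """

    responses: np.ndarray  # (8, n_trials)
    blanks: np.ndarray  # (8, n_trials)
    cell_id: int | str = 0

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.blanks = np.asarray(self.blanks, dtype=float)
        if self.responses.shape[0] != len(DIRECTIONS):
            raise ValueError("expected one row per direction (8)")
        if self.responses.shape != self.blanks.shape:
            raise ValueError("responses and blanks must have matching shape")
        if not (np.isfinite(self.responses).all() and np.isfinite(self.blanks).all()):
            raise ValueError("missing trials in table")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]

    def direction_means(self) -> np.ndarray:
        return self.responses.mean(axis=1)

    def blank_group(self) -> np.ndarray:
        """One blank observation per repetition cycle."""
        return self.blanks.mean(axis=0)


@dataclass
class TuningFit:
    theta_pref: float  # degrees in [0, 360)
    sigma: float  # degrees
    a1: float
    a2: float
    baseline: float
    delta: float  # separation of the second Gaussian, degrees
    residual: float
    degenerate: bool = False

    def model(self, theta) -> np.ndarray:
        return _double_gaussian(
            np.asarray(theta, dtype=float),
            self.baseline, self.a1, self.a2, self.theta_pref, self.sigma, self.delta,
        )

    @property
    def osi(self) -> float:
        return compute_osi(self)


def circ_dist(a, b, period: float = 360.0):
    """Minimal circular distance |a - b| on a circle of given period."""
    d = np.abs(np.asarray(a, dtype=float) - b) % period
    return np.minimum(d, period - d)


def _double_gaussian(theta, b, a1, a2, theta_pref, sigma, delta):
    g1 = np.exp(-(circ_dist(theta, theta_pref) ** 2) / (2.0 * sigma**2))
    g2 = np.exp(-(circ_dist(theta, theta_pref + delta) ** 2) / (2.0 * sigma**2))
    return b + a1 * g1 + a2 * g2


def build_trial_table(
    f_corr: Trace,
    schedule,
    f0_window_s: float = 1.0,
    cell_id: int | str = 0,
) -> TrialTable:
    """Condense a corrected trace into a direction x trial response table.

    ``schedule`` is an iterable of trial records with fields
    ``direction``, ``blank_start``, ``stim_start``, ``stim_end``
    (seconds; e.g. rows of the stimulus-schedule DataFrame). Each
    trial is normalized with its own F0 (mean over ``f0_window_s``
    immediately before stimulus onset).
    """
    per_dir: dict[float, list[tuple[float, float]]] = {d: [] for d in DIRECTIONS}
    records = schedule.itertuples() if hasattr(schedule, "itertuples") else schedule
    count = 0
    for rec in records:
        d = float(rec.direction)
        if d not in per_dir:
            raise ValueError(f"unexpected direction label {d}")
        t_end = rec.stim_end
        if t_end > f_corr.t0 + f_corr.duration + 1e-9:
            raise ValueError("schedule extends beyond trace")
        f0 = compute_f0(f_corr, (rec.stim_start - f0_window_s, rec.stim_start))
        dff = compute_dff(f_corr, f0)
        stim = dff.samples[dff.window_slice(rec.stim_start, rec.stim_end)]
        blank = dff.samples[dff.window_slice(rec.blank_start, rec.stim_start)]
        per_dir[d].append((float(stim.mean()), float(blank.mean())))
        count += 1
    n_trials = {len(v) for v in per_dir.values()}
    if len(n_trials) != 1 or count == 0:
        raise ValueError("schedule must cover every direction equally")
    responses = np.array([[s for s, _ in per_dir[d]] for d in DIRECTIONS])
    blanks = np.array([[b for _, b in per_dir[d]] for d in DIRECTIONS])
    return TrialTable(responses, blanks, cell_id=cell_id)


def classify_responsive(
    table: TrialTable, dff_min: float = 0.05, alpha: float = 0.01
) -> tuple[bool, float]:
    """Amplitude gate plus one-way ANOVA across blank and directions."""
    if table.n_trials < 2:
        raise ValueError("need at least 2 observations per group")
    groups = [table.blank_group()] + [row for row in table.responses]
    if all(np.allclose(g, groups[0][0]) for g in groups):
        return False, 1.0  # identical constant groups: no evidence of response
    p = float(stats.f_oneway(*groups).pvalue)
    amp_ok = bool(table.direction_means().max() > dff_min)
    return amp_ok and p < alpha, p


def preferred_stimulus(table: TrialTable) -> float:
    """Direction evoking the greatest trial-averaged response.

    Ties break toward the lowest direction label (np.argmax convention).
    """
    return float(DIRECTIONS[int(np.argmax(table.direction_means()))])


def fit_tuning(
    table: TrialTable,
    delta: float = 180.0,
    n_starts: int = 4,
    seed: int = 0,
) -> TuningFit:
    """Least-squares double-Gaussian fit to the 8-point tuning curve.

    ``delta`` is the angular separation of the second Gaussian: 180
    degrees fits direction tuning (default); 90 degrees is the literal
    orientation-space variant. Multi-start (``n_starts`` sigma/theta
    initializations, deterministic given ``seed``) with bounds sigma in
    [5, 180] degrees and nonnegative amplitudes. A flat curve yields a
    degenerate flag.
    """
    y = table.direction_means()
    span = float(y.max() - y.min())
    theta0 = preferred_stimulus(table)
    rng = np.random.default_rng(seed)

    if span < 1e-12:
        return TuningFit(theta0, 45.0, 0.0, 0.0, float(y.mean()), delta, 0.0, True)

    def resid(params):
        b, a1, a2, tp, sg = params
        return _double_gaussian(DIRECTIONS, b, a1, a2, tp, sg, delta) - y

    lo = [y.min() - span, 0.0, 0.0, theta0 - 90.0, 5.0]
    hi = [y.max() + span, 4.0 * span, 4.0 * span, theta0 + 90.0, 180.0]
    sigmas0 = [15.0, 30.0, 60.0, 120.0]
    best = None
    for i in range(n_starts):
        tp0 = theta0 + rng.uniform(-20.0, 20.0) if i else theta0
        x0 = [float(y.min()), span, 0.25 * span, float(np.clip(tp0, lo[3], hi[3])),
              sigmas0[i % len(sigmas0)]]
        sol = least_squares(resid, x0, bounds=(lo, hi))
        if best is None or sol.cost < best.cost:
            best = sol
    b, a1, a2, tp, sg = best.x
    rms = float(np.sqrt(2.0 * best.cost / len(y)))
    degenerate = (a1 + a2) < 1e-3 * max(span, 1e-12)
    return TuningFit(float(tp % 360.0), float(sg), float(a1), float(a2),
                     float(b), delta, rms, degenerate)


def compute_osi(fit: TuningFit) -> float:
    """(R_pref - R_ortho) / (R_pref + R_ortho) from the fitted model.

    R_pref and R_ortho are the model responses at the preferred
    direction and 90 degrees away. Returns NaN (undefined) when
    R_pref + R_ortho <= 0.
    """
    r_pref = float(fit.model(fit.theta_pref))
    r_ortho = float(fit.model(fit.theta_pref + 90.0))
    denom = r_pref + r_ortho
    if denom <= 0:
        return np.nan
    return (r_pref - r_ortho) / denom
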