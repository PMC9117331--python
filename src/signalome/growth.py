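"""Growth/division homeostasis analysis.

Cell counts and bulk protein mass over time are fit to exponential models:
the division rate ``alpha`` (and cycle length ``tau = ln2 / alpha``) from
log-linear regression of counts, and the per-cell mass accumulation rate
``gamma`` from the trend of mean cell mass plus ``alpha`` (in exponential
steady state, total synthesis = dilution by division + net mass change).
Condition estimates are normalized to untreated controls and the
growth/division imbalance ``log2(gamma~ / alpha~)`` locates each condition
relative to the proportionality line: below (imbalance < 0) means growth is
disproportionately inhibited, above means division is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from signalome.simulate.growth import GrowthTimecourse

log = logging.getLogger(__name__)


@dataclass
class GrowthEstimate:
    """Per-condition rates; normalized fields are filled by normalization."""

    alpha: float  # division rate [1/h]
    tau: float  # cycle length [h]; inf -> degenerate flag
    gamma: float  # per-cell mass accumulation rate [1/h]
    degenerate: bool = False
    gamma_rel: float | None = None
    alpha_rel: float | None = None
    imbalance: float | None = None


def _pooled_loglinear_slope(times: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope of ln(values) on time, pooling replicate points."""
    t = np.tile(times, values.shape[0])
    y = values.ravel()
    keep = y > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropping %d nonpositive points from log-linear fit", dropped)
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive points for an exponential fit")
    slope, _ = np.polyfit(t[keep], np.log(y[keep]), 1)
    return float(slope)


def fit_division(tc: GrowthTimecourse) -> tuple[float, float]:
    """Division rate alpha and cycle length tau from counts.

    Log-linear least squares of ln N(t) jointly over all replicate points;
    tau = ln2 / alpha.  A flat series yields alpha = 0 and tau = inf (the
    caller receives inf rather than an error; treat as not-proliferating).
    """
    alpha = _pooled_loglinear_slope(tc.times, tc.counts)
    tau = math.log(2.0) / alpha if alpha > 0 else math.inf
    return alpha, tau


def fit_growth(tc: GrowthTimecourse) -> float:
    """Per-cell mass accumulation rate gamma.

    Mean cell mass m(t) = M(t) / N(t); gamma = d ln m / dt + alpha, so in
    balanced growth (m constant) gamma equals the division rate.
    """
    if not np.any(tc.mass > 0):
        raise ValueError("mass channel contains no positive values")
    alpha, _ = fit_division(tc)
    if not math.isfinite(alpha):
        raise ValueError("cannot estimate gamma without a finite division rate")
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_mass = np.where(tc.counts > 0, tc.mass / tc.counts, np.nan)
    valid = np.nan_to_num(mean_mass, nan=-1.0)
    slope = _pooled_loglinear_slope(tc.times, valid)
    return slope + alpha


def fit_condition(tc: GrowthTimecourse) -> GrowthEstimate:
    """Convenience wrapper: both fits on one timecourse."""
    alpha, tau = fit_division(tc)
    degenerate = not math.isfinite(tau)
    gamma = fit_growth(tc) if not degenerate else math.nan
    return GrowthEstimate(alpha=alpha, tau=tau, gamma=gamma, degenerate=degenerate)


def normalize_to_control(
    e: GrowthEstimate, control: GrowthEstimate
) -> tuple[float, float, float]:
    """Control-normalized rates and the growth/division imbalance.

    Returns (gamma~, alpha~, imbalance) with imbalance = log2(gamma~/alpha~).
    Negative imbalance tags growth-limited conditions (below the
    proportionality line), positive tags division-limited ones.
    """
    if control.alpha <= 0 or control.gamma <= 0:
        raise ValueError("control rates must be positive")
    gamma_rel = e.gamma / control.gamma
    alpha_rel = e.alpha / control.alpha
    imbalance = math.log2(gamma_rel / alpha_rel)
    e.gamma_rel, e.alpha_rel, e.imbalance = gamma_rel, alpha_rel, imbalance
    return gamma_rel, alpha_rel, imbalance


def size_state_correlation(per_drug_size, per_drug_pc1) -> tuple[float, float]:
    """Pearson correlation between per-drug mean cell size and PC1.

    Accepts mappings/Series keyed by drug; only common drugs are used
    (at least 3 required).  Returns (r, two-sided p).
    """
    import pandas as pd

    size = pd.Series(per_drug_size, dtype=float)
    pc1 = pd.Series(per_drug_pc1, dtype=float)
    common = size.index.intersection(pc1.index)
    if len(common) < 3:
        raise ValueError("need at least 3 drugs in common")
    r, p = stats.pearsonr(size[common], pc1[common])
    return float(r), float(p)
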