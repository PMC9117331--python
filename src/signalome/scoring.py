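"""Signed Kolmogorov-Smirnov reporter activity scores.

A drug's effect on one reporter at one timepoint is scored by comparing the
per-cell readout distribution of the treated cells against pooled
time-matched vehicle-control (DMSO) cells of the same clone.  The score is
the two-sample KS statistic ``D = sup |F_treated - F_control|`` signed by the
direction of the median shift: +1 means maximum activation, -1 maximum
inactivation.  Scores are not computed for groups with fewer than
``MIN_CELLS`` cells on either side.

The significance threshold is derived from vehicle controls: each DMSO well
is scored against the pool of the remaining DMSO wells, and the threshold is
the 99.5th percentile of the absolute null scores (the extreme half-percent
tail); the conventional fallback is 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from signalome.simulate.screen import DMSO

log = logging.getLogger(__name__)

#: Minimum cells per group for a score to be valid.
MIN_CELLS = 30
#: Conventional activity threshold when no control-derived one is available.
DEFAULT_THRESHOLD = 0.2


def per_cell_readout(cell, mode: str) -> float:
    """Scalar readout of one cell record for the given reporter mode.

    ``ratio`` (translocation reporters): cytoplasm mean / nucleus mean.
    ``nuclear_intensity`` (transcription reporters): nucleus mean minus the
    cell-specific background, clipped at 0.
    """
    if mode == "ratio":
        nuc = float(cell["nuc_mean"])
        if nuc == 0:
            raise ZeroDivisionError("zero nuclear mean in ratio mode")
        return float(cell["cyto_mean"]) / nuc
    if mode == "nuclear_intensity":
        value = float(cell["nuc_mean"]) - float(cell["bg_mean"])
        return max(value, 0.0)
    raise ValueError(f"unknown readout mode {mode!r}")


def _readout_column(cells: pd.DataFrame, modes: dict[str, str]) -> np.ndarray:
    """Vectorized :func:`per_cell_readout` over a cell table."""
    clone = cells["clone"].astype(str).to_numpy()
    is_ratio = np.array([modes[c] == "ratio" for c in clone])
    nuc = cells["nuc_mean"].to_numpy(dtype=float)
    cyto = cells["cyto_mean"].to_numpy(dtype=float)
    bg = cells["bg_mean"].to_numpy(dtype=float)
    out = np.empty(len(cells))
    bad = is_ratio & (nuc == 0)
    if bad.any():
        log.warning("dropping %d cells with zero nuclear mean", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out[is_ratio] = cyto[is_ratio] / nuc[is_ratio]
    sub = nuc[~is_ratio] - bg[~is_ratio]
    n_clip = int((sub < 0).sum())
    if n_clip:
        log.info("clipped %d negative background-subtracted readouts", n_clip)
    out[~is_ratio] = np.clip(sub, 0.0, None)
    out[bad] = np.nan
    return out


def signed_ks(treated, control) -> float:
    """Two-sample KS statistic signed by the treated-vs-control median shift.

    The sign is +1 if the treated median exceeds the control median, -1 if it
    is lower; on a median tie the sign of the mean difference is used, and 0
    if both are tied.  The magnitude is the classical
    ``D = sup_x |F_treated(x) - F_control(x)|``.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both samples must be nonempty")
    t_sorted = np.sort(t)
    c_sorted = np.sort(c)
    grid = np.concatenate([t_sorted, c_sorted])
    cdf_t = np.searchsorted(t_sorted, grid, side="right") / t.size
    cdf_c = np.searchsorted(c_sorted, grid, side="right") / c.size
    d = float(np.abs(cdf_t - cdf_c).max())
    med_diff = float(np.median(t) - np.median(c))
    if med_diff > 0:
        sign = 1.0
    elif med_diff < 0:
        sign = -1.0
    else:
        mean_diff = float(t.mean() - c.mean())
        sign = float(np.sign(mean_diff))
    return sign * d


@dataclass
class ScoreMatrix:
    """Drug x pathway x timepoint activity scores with missing-value support.

    ``table`` is long-format with one row per (drug, pathway, timepoint):
    ``score``, ``n_treated``, ``n_control`` and a ``valid`` flag (False
    whenever either group had fewer than :data:`MIN_CELLS` cells).
    """

    table: pd.DataFrame
    pathways: tuple[str, ...] = ()
    timepoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.pathways:
            self.pathways = tuple(pd.unique(self.table["pathway"]))
        if not self.timepoints:
            self.timepoints = tuple(sorted(pd.unique(self.table["time_h"])))

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["drug"]))

    def slice(self, time_h: float, drop_missing_pathways: bool = True) -> pd.DataFrame:
        """Drug x pathway score frame at one timepoint (NaN where invalid).

        With ``drop_missing_pathways`` (default) any pathway column containing
        missing values is dropped listwise, mirroring the exclusion of a
        reporter that was not measured for all drugs.
        """
        sub = self.table[self.table["time_h"] == time_h]
        frame = sub.pivot_table(
            index="drug", columns="pathway", values="score", dropna=False,
            observed=True,
        )
        mask = sub.pivot_table(
            index="drug", columns="pathway", values="valid", dropna=False,
            observed=True,
        ).astype(bool)
        frame = frame.where(mask)
        frame = frame.reindex(columns=[p for p in self.pathways if p in frame])
        if drop_missing_pathways:
            frame = frame.dropna(axis=1)
        return frame

    def to_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, missing-mask) arrays shaped (drug, pathway, timepoint)."""
        drugs = self.drugs
        d_i = {d: i for i, d in enumerate(drugs)}
        p_i = {p: i for i, p in enumerate(self.pathways)}
        t_i = {t: i for i, t in enumerate(self.timepoints)}
        scores = np.full((len(drugs), len(self.pathways), len(self.timepoints)), np.nan)
        for row in self.table.itertuples(index=False):
            if bool(row.valid):
                scores[d_i[row.drug], p_i[row.pathway], t_i[row.time_h]] = row.score
        return scores, np.isnan(scores)


def score_screen(
    cells: pd.DataFrame,
    modes: dict[str, str],
    control: str = DMSO,
    min_cells: int = MIN_CELLS,
) -> ScoreMatrix:
    """Score every (drug, pathway, timepoint) group against pooled controls.

    The control sample for a clone at a timepoint is the pool of all cells of
    that clone in control wells at the same timepoint.  Groups with fewer
    than ``min_cells`` cells on either side are marked invalid.
    """
    work = cells.copy()
    work["readout"] = _readout_column(work, modes)
    work = work.dropna(subset=["readout"])
    is_ctrl = work["drug"].astype(str) == control

    # pre-sorted control pools per (clone, time)
    pools: dict[tuple[str, float], np.ndarray] = {}
    for (clone, t), grp in work[is_ctrl].groupby(["clone", "time_h"], observed=True):
        pools[(str(clone), float(t))] = np.sort(grp["readout"].to_numpy())

    records = []
    treated = work[~is_ctrl]
    times = sorted(pd.unique(work["time_h"]))
    missing_ctrl_times = {
        float(t) for t in times
        if not any(k[1] == float(t) for k in pools)
    }
    for t in missing_ctrl_times:
        log.warning("no control wells at t=%g h; scores there are invalid", t)
    for (drug, clone, t), grp in treated.groupby(
        ["drug", "clone", "time_h"], observed=True
    ):
        key = (str(clone), float(t))
        ctrl = pools.get(key, np.empty(0))
        n_t, n_c = len(grp), ctrl.size
        valid = n_t >= min_cells and n_c >= min_cells
        score = (
            signed_ks(grp["readout"].to_numpy(), ctrl) if valid else np.nan
        )
        records.append(
            {
                "drug": str(drug),
                "pathway": str(clone),
                "time_h": float(t),
                "score": score,
                "n_treated": n_t,
                "n_control": n_c,
                "valid": valid,
            }
        )
    table = pd.DataFrame(records)
    pathways = tuple(str(c) for c in pd.unique(cells["clone"]))
    return ScoreMatrix(table=table, pathways=pathways, timepoints=tuple(map(float, times)))


def dmso_null_scores(
    cells: pd.DataFrame,
    modes: dict[str, str],
    control: str = DMSO,
    min_cells: int = MIN_CELLS,
) -> np.ndarray:
    """Leave-one-well-out control scores: each control well vs the rest.

    These scores estimate the null distribution of the statistic under no
    treatment and feed :func:`derive_threshold`.
    """
    work = cells[cells["drug"].astype(str) == control].copy()
    work["readout"] = _readout_column(work, modes)
    work = work.dropna(subset=["readout"])
    scores = []
    for (clone, t), grp in work.groupby(["clone", "time_h"], observed=True):
        wells = pd.unique(grp["well"])
        if len(wells) < 2:
            continue
        values = grp["readout"].to_numpy()
        well_ids = grp["well"].to_numpy()
        for w in wells:
            mine = values[well_ids == w]
            rest = values[well_ids != w]
            if mine.size >= min_cells and rest.size >= min_cells:
                scores.append(signed_ks(mine, rest))
    return np.asarray(scores)


def derive_threshold(dmso_scores, min_scores: int = 20) -> float:
    """Activity threshold = 99.5th percentile of |null scores|.

    Quantile rule: linear interpolation (numpy default).  Requires at least
    ``min_scores`` control-vs-control scores.
    """
    scores = np.asarray(dmso_scores, dtype=float)
    if scores.size < min_scores:
        raise ValueError(
            f"need at least {min_scores} control scores, got {scores.size}"
        )
    return float(np.percentile(np.abs(scores), 99.5))


def active_drugs(m: ScoreMatrix, threshold: float = DEFAULT_THRESHOLD) -> set[str]:
    """Drugs with any valid |score| above threshold at any timepoint > 0."""
    t = m.table
    hits = t[(t["valid"]) & (t["time_h"] > 0) & (t["score"].abs() > threshold)]
    return set(hits["drug"].astype(str))
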