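"""Correlation-structure similarity between cohorts and a reference panel.

For each cohort (sample x protein matrix) the full pairwise Pearson
correlation matrix is computed; cohorts must have *more than* ``min_n``
samples to be analyzed.  Similarity to a reference correlation matrix is
scored row-wise: the diagonal is removed (it is trivially 1) and each
protein's remaining correlation row is Pearson-correlated with the matching
reference row, giving one similarity per protein and an overall mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN_COHORT_N = 30
MIN_SHARED_ENTRIES = 4


@dataclass
class SimilarityScore:
    cohort: str
    per_protein: pd.Series
    overall: float


def cohort_correlations(
    c: pd.DataFrame, min_n: int = MIN_COHORT_N
) -> pd.DataFrame | None:
    """Protein x protein Pearson matrix, or None for under-sized cohorts.

    The size rule is strict: a cohort with exactly ``min_n`` samples is
    skipped.  Constant protein columns yield an NA row/column with a warning.
    """
    name = c.attrs.get("cohort", "<unnamed>")
    if len(c) <= min_n:
        log.info("cohort %s skipped: %d samples (need > %d)", name, len(c), min_n)
        return None
    constant = c.columns[c.nunique() <= 1].tolist()
    if constant:
        log.warning("cohort %s: constant protein columns -> NA rows: %s", name, constant)
    corr = c.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for p in constant:
        corr.loc[p, :] = np.nan
        corr.loc[:, p] = np.nan
    return corr


def similarity_to_reference(
    cohort_corr: pd.DataFrame,
    reference_corr: pd.DataFrame,
    cohort: str = "<unnamed>",
) -> SimilarityScore:
    """Row-wise similarity of two correlation matrices over a shared panel.

    For each protein the diagonal entry is deleted from both matrices and
    the remaining p-1 entries, aligned by protein identity, are
    Pearson-correlated.  NA entries are handled pairwise-complete with a
    minimum of :data:`MIN_SHARED_ENTRIES` shared entries per row.
    """
    missing = set(reference_corr.columns).symmetric_difference(cohort_corr.columns)
    if missing:
        raise ValueError(f"protein panels do not match; unmatched: {sorted(missing)}")
    proteins = list(reference_corr.columns)
    cohort_corr = cohort_corr.loc[proteins, proteins]
    reference_corr = reference_corr.loc[proteins, proteins]
    sims = {}
    for p in proteins:
        others = [q for q in proteins if q != p]
        a = cohort_corr.loc[p, others].to_numpy(dtype=float)
        b = reference_corr.loc[p, others].to_numpy(dtype=float)
        shared = ~(np.isnan(a) | np.isnan(b))
        required = min(MIN_SHARED_ENTRIES, len(others))
        if shared.sum() < max(required, 2):
            sims[p] = np.nan
            continue
        a, b = a[shared], b[shared]
        with np.errstate(invalid="ignore"):
            sims[p] = float(np.corrcoef(a, b)[0, 1])
    per_protein = pd.Series(sims, name="similarity")
    overall = float(per_protein.mean(skipna=True))
    return SimilarityScore(cohort=cohort, per_protein=per_protein, overall=overall)


def enrichment_strength(observed: float, expected: float) -> float:
    """log10(observed / expected); 0 observations yield NaN (flagged -inf)."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if observed == 0:
        log.warning("enrichment strength undefined for observed=0 (-inf); returning NaN")
        return math.nan
    return math.log10(observed / expected)
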