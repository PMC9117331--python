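"""Signaling-state analysis: clustering, correlations, and PCA metrics.

Drug response signatures (drug x pathway activity-score slices) are clustered
hierarchically (Euclidean distance, Ward.D2 agglomeration), summarized by
pathway-pathway Pearson correlations, and decomposed by PCA.  Per-drug
metrics derived from the PCA coordinates quantify the two-state structure:

``phi``
    persistence of a reference correlation structure: the product of
    per-axis variances after projecting the data onto a reference orthonormal
    coordinate system, divided by the product of per-pathway variances on the
    original axes.  phi is 1 for uncorrelated data in any basis and tends to
    0 as the data concentrate on a lower-dimensional subspace aligned with
    the reference.
``psi``
    conformity: PC1 / sqrt(sum_i PC_i^2), in [-1, 1].
``adherence``
    |PC1| / sum_i PC_i^2 as conventionally printed (scale-dependent); a
    normalized alternative |PC1| / sqrt(sum_i PC_i^2) is available.
``strength``
    sqrt(sum_i PC_i^2), the Euclidean norm of the drug's effect coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

log = logging.getLogger(__name__)


@dataclass
class PCACoordinateSystem:
    """An orthonormal coordinate system over pathways.

    ``loadings`` has one column per axis (pathways x components); variances
    are the per-axis variances of the fitted data, nonincreasing.
    """

    loadings: np.ndarray
    variances: np.ndarray
    explained_fraction: np.ndarray
    center: np.ndarray
    pathways: tuple[str, ...]

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings must be orthonormal")
        if np.any(np.diff(self.variances) > 1e-10):
            raise ValueError("axis variances must be nonincreasing")


@dataclass
class ClusterAssignment:
    """Drug cluster labels with the underlying dendrogram."""

    labels: pd.Series  # drug -> cluster letter
    linkage_matrix: np.ndarray
    k: int


def cluster_drugs(m: pd.DataFrame, k: int = 3) -> ClusterAssignment:
    """Hierarchical clustering of drugs by their pathway signatures.

    Euclidean distance with Ward agglomeration in the Ward.D2 convention
    (squared-distance update on raw distances); pathways with any missing
    value are dropped listwise before clustering.  Cluster letters A, B, C...
    are assigned in decreasing cluster size (ties broken by first occurrence).
    """
    data = m.dropna(axis=1)
    if k > len(data):
        raise ValueError(f"k={k} exceeds the number of drugs ({len(data)})")
    z = linkage(data.to_numpy(), method="ward", metric="euclidean")
    flat = fcluster(z, t=k, criterion="maxclust")
    sizes = pd.Series(flat).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    letter = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    labels = pd.Series([letter[c] for c in flat], index=data.index, name="cluster")
    return ClusterAssignment(labels=labels, linkage_matrix=z, k=k)


def pathway_correlations(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between pathways.

    Zero-variance pathways produce an NA row/column with a warning.
    """
    if len(m) < 3:
        raise ValueError("need at least 3 drugs for pathway correlations")
    variances = m.var(skipna=True)
    degenerate = variances[variances == 0].index.tolist()
    if degenerate:
        log.warning("zero-variance pathways produce NA correlations: %s", degenerate)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = m.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    for p in degenerate:
        corr.loc[p, :] = np.nan
        corr.loc[:, p] = np.nan
    return corr


def fit_pca(
    m: pd.DataFrame, orient_axis: np.ndarray | None = None
) -> tuple[PCACoordinateSystem, pd.DataFrame]:
    """Column-centered, unscaled PCA of a drug x pathway slice via SVD.

    The sign of each component is fixed deterministically: the entry of
    largest magnitude in each loading vector is made positive.  Passing
    ``orient_axis`` instead orients PC1 to have nonnegative cosine with that
    vector (e.g. a configured state-axis orientation).

    Returns the coordinate system and a per-drug coordinate frame with
    columns ``PC1..PCk``, ``psi``, ``adherence``, ``strength``.
    """
    if m.isna().any().any():
        raise ValueError("missing values must be dropped before PCA")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 drugs and 2 pathways")
    x = m.to_numpy(dtype=float)
    center = x.mean(axis=0)
    xc = x - center
    if not np.any(xc):
        raise ValueError("rank-0 input: all drugs identical")
    u_svd, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(xc.shape)
    loadings = vt.T[:, :k]
    variances = (s[:k] ** 2) / (xc.shape[0] - 1)
    for j in range(k):
        if orient_axis is not None and j == 0:
            if float(loadings[:, 0] @ np.asarray(orient_axis, dtype=float)) < 0:
                loadings[:, 0] = -loadings[:, 0]
        elif loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = xc @ loadings
    total_var = float(variances.sum())
    system = PCACoordinateSystem(
        loadings=loadings,
        variances=variances,
        explained_fraction=variances / total_var,
        center=center,
        pathways=tuple(m.columns),
    )
    coords = pd.DataFrame(
        scores, index=m.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    strength = drug_strength(scores)
    coords["psi"] = psi_conformity(scores)
    coords["adherence"] = adherence_pc1(scores)
    coords["strength"] = strength
    return system, coords


def phi_metric(data: pd.DataFrame, reference: PCACoordinateSystem) -> float:
    """Variance-product persistence of a reference coordinate system.

    phi = prod_n Var(projection onto reference axis n)
          / prod_p Var(original pathway axis p),
    computed in log space for numerical stability.  Both products run over
    all axes; the data are centered on their own means (variance is
    shift-invariant, so the reference centering plays no role).
    """
    if list(data.columns) != list(reference.pathways):
        raise ValueError("reference pathways must match the data columns")
    x = data.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    var_orig = xc.var(axis=0, ddof=1)
    if np.any(var_orig <= 0):
        raise ValueError("phi undefined: zero variance on an original axis")
    proj = xc @ reference.loadings
    var_proj = proj.var(axis=0, ddof=1)
    if np.any(var_proj <= 0):
        raise ValueError("phi undefined: zero variance on a reference axis")
    return float(np.exp(np.log(var_proj).sum() - np.log(var_orig).sum()))


def _coords_array(c) -> np.ndarray:
    if isinstance(c, pd.DataFrame):
        pc_cols = [col for col in c.columns if col.startswith("PC")]
        return c[pc_cols].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(c, dtype=float))


def psi_conformity(c) -> np.ndarray | float:
    """Conformity psi = PC1 / sqrt(sum_i PC_i^2); NaN for zero coordinates."""
    pcs = _coords_array(c)
    norm = np.sqrt((pcs**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pcs[:, 0] / norm
    if np.any(norm == 0):
        log.warning("psi undefined for %d all-zero coordinate rows", int((norm == 0).sum()))
        out[norm == 0] = np.nan
    return out if out.size > 1 else float(out[0])


def adherence_pc1(c, normalized: bool = False) -> np.ndarray | float:
    """Adherence to PC1.

    As conventionally printed: |PC1| / sum_i PC_i^2 (scale-dependent).  With
    ``normalized=True``: |PC1| / sqrt(sum_i PC_i^2), the scale-free variant.
    """
    pcs = _coords_array(c)
    ss = (pcs**2).sum(axis=1)
    denom = np.sqrt(ss) if normalized else ss
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(pcs[:, 0]) / denom
    out[ss == 0] = np.nan
    return out if out.size > 1 else float(out[0])


def drug_strength(c) -> np.ndarray | float:
    """Total influence: Euclidean norm of the PC coordinates."""
    pcs = _coords_array(c)
    out = np.sqrt((pcs**2).sum(axis=1))
    return out if out.size > 1 else float(out[0])
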