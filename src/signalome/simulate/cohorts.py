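"""Synthetic cohort protein matrices drawn from a reference correlation.

Emulates per-cancer-type sample x protein panels (e.g. reverse-phase protein
array data) whose population correlation structure equals a supplied
reference matrix, for testing correlation-structure similarity scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 8-marker surrogate panel used to compare reporter pathways with tumor
#: (phospho)protein data.
DEFAULT_PROTEIN_PANEL = (
    "AKTpS473",
    "MAPKpT202Y204",
    "JNKpT183Y185",
    "p38pT180Y182",
    "PKCALPHApS657",
    "NFKBP65pS536",
    "p53",
    "YAP",
)


def _validate_correlation(reference: np.ndarray) -> np.ndarray:
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[0] != ref.shape[1]:
        raise ValueError("reference correlation must be square")
    if not np.allclose(ref, ref.T, atol=1e-10):
        raise ValueError("reference correlation must be symmetric")
    if not np.allclose(np.diag(ref), 1.0, atol=1e-10):
        raise ValueError("reference correlation must have unit diagonal")
    eigvals = np.linalg.eigvalsh(ref)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"reference correlation is not positive semidefinite "
            f"(smallest eigenvalue {eigvals.min():.3e})"
        )
    return ref


def generate_cohort_proteomes(
    reference_corr: np.ndarray,
    n_samples: int | list[int],
    n_cohorts: int,
    seed: int = 0,
    proteins: tuple[str, ...] | None = None,
) -> list[pd.DataFrame]:
    """Draw cohorts from a multivariate normal with the reference correlation.

    ``n_samples`` may be a single size for all cohorts or one size per cohort.
    Each returned frame is sample x protein with ``cohort`` and ``n_samples``
    recorded in ``DataFrame.attrs``.
    """
    ref = _validate_correlation(reference_corr)
    p = ref.shape[0]
    if proteins is None:
        proteins = tuple(DEFAULT_PROTEIN_PANEL[:p]) if p <= len(
            DEFAULT_PROTEIN_PANEL
        ) else tuple(f"protein_{i + 1}" for i in range(p))
    if len(proteins) != p:
        raise ValueError("protein names must match reference dimension")
    sizes = (
        [int(n_samples)] * n_cohorts if np.isscalar(n_samples) else list(n_samples)
    )
    if len(sizes) != n_cohorts:
        raise ValueError("one sample size per cohort required")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(ref + 1e-12 * np.eye(p))
    cohorts = []
    for i, n in enumerate(sizes):
        data = rng.standard_normal((n, p)) @ chol.T
        frame = pd.DataFrame(data, columns=list(proteins))
        frame.attrs["cohort"] = f"cohort_{i + 1}"
        frame.attrs["n_samples"] = n
        cohorts.append(frame)
    return cohorts
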