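"""Drug-target deconvolution by interaction-penalized ridge regression.

A compound library maps drugs to annotated target sets.  Responses (e.g. a
PC1 coordinate or a cell-size change per compound) are regressed on an
indicator design with one column per individual target and one product
column per unordered target pair co-annotated in at least one compound.  The
fit minimizes

    sum_i (y_i - sum_j x_ij beta_j)^2 + lambda * sum_j v_j beta_j^2

with v_j = 1 for individual-target columns and v_j = v > 1 for interaction
columns, so interactions must earn their keep.  lambda and v are chosen by
fivefold cross-validation; v is searched over powers of two up to 2^30, and
if the CV error is still decreasing at that boundary the interaction columns
are dropped entirely and the model refit over lambda alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

V_MAX_EXPONENT = 30
N_LAMBDA = 50
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class RidgeProblem:
    """Response over compounds and an indicator + interaction design."""

    y: np.ndarray
    x: pd.DataFrame  # n x p, 0/1 indicators and their products
    interaction_mask: np.ndarray  # per-column, True for interaction columns

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.interaction_mask = np.asarray(self.interaction_mask, dtype=bool)
        if len(self.y) != len(self.x):
            raise ValueError("y and x must have matching rows")
        if self.interaction_mask.size != self.x.shape[1]:
            raise ValueError("one mask entry per design column required")

    def without_interactions(self) -> "RidgeProblem":
        keep = ~self.interaction_mask
        return RidgeProblem(self.y, self.x.loc[:, keep], np.zeros(keep.sum(), bool))


@dataclass
class RidgeFit:
    """Fitted coefficients with the selected penalties and CV trace."""

    beta: pd.Series
    intercept: float
    lam: float
    v: float
    interaction_mask: np.ndarray
    cv_table: pd.DataFrame | None = None
    interactions_dropped: bool = False

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return self.intercept + x[self.beta.index].to_numpy(dtype=float) @ self.beta.to_numpy()


def build_design(
    drug_targets: dict[str, set[str]] | pd.Series,
    include_interactions: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Indicator design from a drug -> target-set table.

    One 0/1 column per target; when enabled, one product column per unordered
    target pair co-annotated in at least one compound.  Column names are
    stable and sorted; interaction columns are named ``T1:T2``.
    """
    if isinstance(drug_targets, pd.Series):
        drug_targets = drug_targets.to_dict()
    for drug, targets in drug_targets.items():
        if not targets:
            raise ValueError(f"drug {drug!r} has an empty target set")
    drugs = list(drug_targets)
    targets = sorted({t for ts in drug_targets.values() for t in ts})
    x = pd.DataFrame(0.0, index=drugs, columns=targets)
    for drug, ts in drug_targets.items():
        x.loc[drug, sorted(ts)] = 1.0
    mask = np.zeros(len(targets), dtype=bool)
    if include_interactions:
        pairs = sorted(
            {
                tuple(sorted(pair))
                for ts in drug_targets.values()
                for pair in itertools.combinations(sorted(ts), 2)
            }
        )
        for a, b in pairs:
            x[f"{a}:{b}"] = x[a] * x[b]
        mask = np.concatenate([mask, np.ones(len(pairs), dtype=bool)])
    return x, mask


def ridge_solve(
    p: RidgeProblem, lam: float, v: float = 1.0, center: bool = True
) -> RidgeFit:
    """Closed-form minimizer of the interaction-penalized ridge loss.

    By default columns and response are centered (indicators are not
    scaled) and the intercept is recovered from the centers, never
    penalized.  With ``center=False`` the loss is minimized exactly as
    written, with no intercept (``beta = (X'X + lam diag(v))^-1 X'y``).
    The per-column penalty is ``lam`` for individual targets and
    ``lam * v`` for interaction columns.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if v < 1:
        raise ValueError("v must be >= 1")
    x = p.x.to_numpy(dtype=float)
    if center:
        x_center = x.mean(axis=0)
        y_center = float(p.y.mean())
    else:
        x_center = np.zeros(x.shape[1])
        y_center = 0.0
    xc = x - x_center
    yc = p.y - y_center
    v_j = np.where(p.interaction_mask, v, 1.0)
    gram = xc.T @ xc + lam * np.diag(v_j)
    try:
        beta = np.linalg.solve(gram, xc.T @ yc)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations (collinear columns at lambda=0); "
            "use lambda > 0"
        ) from err
    if lam == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError(
            "singular normal equations (collinear columns at lambda=0); "
            "use lambda > 0"
        )
    intercept = y_center - float(x_center @ beta)
    return RidgeFit(
        beta=pd.Series(beta, index=p.x.columns),
        intercept=intercept,
        lam=float(lam),
        v=float(v),
        interaction_mask=p.interaction_mask.copy(),
    )


def _lambda_grid(p: RidgeProblem) -> np.ndarray:
    """Data-driven log-spaced grid: lambda_max = max |x_c' y_c| / n."""
    x = p.x.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = p.y - p.y.mean()
    lam_max = float(np.abs(xc.T @ yc).max()) / len(p.y)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * LAMBDA_MIN_RATIO, N_LAMBDA)


def _fold_assignment(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded fold labels, stratified by response quantile."""
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    assignment = np.empty(len(y), dtype=int)
    for start in range(0, len(y), folds):
        block = order[start : start + folds]
        assignment[block] = rng.permutation(folds)[: len(block)]
    return assignment


def cv_select(
    p: RidgeProblem,
    folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    v_grid: np.ndarray | None = None,
    seed: int = 0,
) -> RidgeFit:
    """Select (lambda, v) by k-fold cross-validation and refit on all data.

    v is searched over {2^0, ..., 2^30}.  If the CV error has no genuine
    interior minimum in v -- the best error achievable at the 2^30 boundary
    (where interactions are fully suppressed) lies within one standard
    error of the global CV minimum -- the interaction columns are judged
    unsupported: they are dropped and the model is refit over lambda only,
    with ``interactions_dropped`` set on the returned fit.
    """
    n = len(p.y)
    if n < folds:
        raise ValueError(f"need at least {folds} rows, got {n}")
    lambdas = _lambda_grid(p) if lambda_grid is None else np.asarray(lambda_grid, float)
    has_interactions = bool(p.interaction_mask.any())
    if v_grid is None:
        v_values = (
            2.0 ** np.arange(V_MAX_EXPONENT + 1) if has_interactions else np.array([1.0])
        )
    else:
        v_values = np.asarray(v_grid, dtype=float)
    assignment = _fold_assignment(p.y, folds, seed)

    records = []
    for lam in lambdas:
        for v in v_values:
            errors = []
            for fold in range(folds):
                test = assignment == fold
                sub = RidgeProblem(p.y[~test], p.x.loc[~test], p.interaction_mask)
                fit = ridge_solve(sub, lam, v)
                pred = fit.predict(p.x.loc[test])
                errors.append(float(np.mean((p.y[test] - pred) ** 2)))
            records.append(
                {
                    "lambda": lam,
                    "v": v,
                    "mse": float(np.mean(errors)),
                    "se": float(np.std(errors, ddof=1) / np.sqrt(folds)),
                }
            )
    cv_table = pd.DataFrame(records)
    best = cv_table.loc[cv_table["mse"].idxmin()]
    lam_star, v_star = float(best["lambda"]), float(best["v"])

    boundary = False
    if has_interactions and len(v_values) > 1:
        mse_boundary = float(
            cv_table.loc[cv_table["v"] == float(v_values[-1]), "mse"].min()
        )
        boundary = mse_boundary <= float(best["mse"]) + float(best["se"])
    if boundary:
        reduced = p.without_interactions()
        fit = cv_select(reduced, folds=folds, lambda_grid=lambdas, seed=seed)
        fit.interactions_dropped = True
        fit.cv_table = cv_table
        return fit
    fit = ridge_solve(p, lam_star, v_star)
    fit.cv_table = cv_table
    return fit


def target_effects(fit: RidgeFit) -> pd.Series:
    """Individual (non-interaction) target effects only."""
    keep = ~fit.interaction_mask
    return fit.beta[keep]
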