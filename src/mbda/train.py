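"""Algorithm training: stepwise penalized regression, nested CV, shrinkage.

Per-component linear models are selected by forward stepwise entry order
(greedy RSS for OLS; penalty-path entry order for LASSO and elastic net,
with OLS refit at each model size), the size chosen by nested 10-fold
cross-validation. The two joint-count predictions are then improved by a
2x2 shrinkage matrix estimated with the Breiman-Friedman GCV form of the
curds-and-whey multivariate-response method; predicted PGA and CRP stay out
of the shrinkage. The trained model serializes to a coefficients config
directly consumable by the scoring module.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.linear_model import enet_path, lars_path

from mbda.core import (
    AlgorithmCoefficients,
    Cohort,
    ComponentModel,
    PANEL_ANALYTES,
)
from mbda.indices import das28_crp4

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "ModelPath",
    "CWModel",
    "stepwise_fit",
    "nested_cv_select",
    "curds_whey_matrix",
    "fit_component",
    "train_algorithm",
    "compare_families",
]

FAMILIES = ("ols", "lasso", "en", "cw-ols", "cw-lasso")


@dataclass
class ModelPath:
    """Nested models of increasing size with the variable entry order.

    ``entry_order[i]`` is the i-th variable to enter; ``models[s]`` holds the
    OLS refit (intercept, coefficient map) using the first ``s`` entrants,
    with ``models[0]`` the intercept-only model.
    """

    entry_order: list[str]
    models: list[tuple[float, dict[str, float]]]

    def predict(self, X: pd.DataFrame, size: int) -> np.ndarray:
        intercept, coefs = self.models[size]
        yhat = np.full(len(X), intercept, dtype=float)
        for name, w in coefs.items():
            yhat += w * X[name].to_numpy(dtype=float)
        return yhat


@dataclass
class CWModel:
    """A full trained model: component sub-models plus shrinkage matrix."""

    components: dict[str, ComponentModel]
    shrinkage: np.ndarray
    family: str
    selected_sizes: dict[str, int]
    seed: int | None = None
    shrinkage_factors: np.ndarray | None = None
    canonical_correlations: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def _refit_ols(X: pd.DataFrame, y: np.ndarray, names: Sequence[str]) -> tuple[float, dict[str, float]]:
    if not names:
        return float(np.mean(y)), {}
    A = np.column_stack([np.ones(len(X))] + [X[n].to_numpy(dtype=float) for n in names])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(beta[0]), {n: float(b) for n, b in zip(names, beta[1:])}


def _standardize(X: pd.DataFrame) -> np.ndarray:
    arr = X.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (arr - mu) / sd


def stepwise_fit(
    X: pd.DataFrame,
    y: np.ndarray | Sequence[float],
    family: str = "lasso",
    max_size: int | None = None,
) -> ModelPath:
    """Forward stepwise model path for one component.

    family "ols": greedy forward selection minimizing residual sum of squares.
    family "lasso"/"en": variables enter in the order they first become
    active along the L1 (or mixed, l1_ratio=0.5) penalty path on
    standardized predictors; coefficients are refit by OLS at each size.

    Constant (zero-variance) columns never enter. Rank deficiency shortens
    the path with a warning rather than failing.
    """
    if family not in ("ols", "lasso", "en"):
        raise ValueError(f"unknown stepwise family {family!r}")
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    cols = [c for c in X.columns if X[c].nunique() > 1]
    X = X[cols]
    p = len(cols)
    if max_size is None:
        max_size = p
    max_size = min(max_size, p, max(1, len(y) - 2))

    if family == "ols":
        order = _greedy_order(X, y, max_size)
    else:
        order = _path_order(X, y, family, max_size)

    models = [_refit_ols(X, y, order[:s]) for s in range(len(order) + 1)]
    return ModelPath(entry_order=list(order), models=models)


def _greedy_order(X: pd.DataFrame, y: np.ndarray, max_size: int) -> list[str]:
    remaining = list(X.columns)
    chosen: list[str] = []
    while remaining and len(chosen) < max_size:
        best_name, best_rss = None, np.inf
        for name in remaining:
            names = chosen + [name]
            A = np.column_stack(
                [np.ones(len(X))] + [X[n].to_numpy(dtype=float) for n in names]
            )
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ beta) ** 2))
            if rss < best_rss - 1e-12:
                best_rss, best_name = rss, name
        if best_name is None:
            break
        chosen.append(best_name)
        remaining.remove(best_name)
    return chosen


def _path_order(X: pd.DataFrame, y: np.ndarray, family: str, max_size: int) -> list[str]:
    Z = _standardize(X)
    yc = y - y.mean()
    if family == "lasso":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alphas, active, coefs = lars_path(Z, yc, method="lasso")
        first_active: dict[int, int] = {}
        for step, j in enumerate(active):
            first_active.setdefault(int(j), step)
        order_idx = sorted(first_active, key=first_active.get)
    else:  # elastic net, l1_ratio = 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alphas, coefs, _ = enet_path(Z, yc, l1_ratio=0.5, n_alphas=200, eps=1e-4)
        first_alpha: dict[int, int] = {}
        for j in range(coefs.shape[0]):
            nz = np.nonzero(np.abs(coefs[j]) > 1e-12)[0]
            if nz.size:
                first_alpha[j] = int(nz[0])
        order_idx = sorted(first_alpha, key=lambda j: (first_alpha[j], j))
    names = [X.columns[j] for j in order_idx]
    return names[:max_size]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by outcome tertile (emulates activity-balanced folds)."""
    n = len(y)
    tertiles = np.quantile(y, [1 / 3, 2 / 3])
    strata = np.digitize(y, tertiles)
    fold = np.empty(n, dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def nested_cv_select(
    X: pd.DataFrame,
    y: np.ndarray | Sequence[float],
    family: str = "lasso",
    k: int = 10,
    max_size: int | None = None,
    seed: int = 0,
    one_se: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Choose the model size by k-fold cross-validation within the training set.

    Rows are split into ``k`` folds stratified by outcome tertile; for each
    candidate size the held-out MSE (and Pearson r, reported alongside) is
    averaged over folds. With ``one_se`` (default) the smallest size whose
    mean MSE is within one standard error of the minimum is selected — the
    usual parsimony convention; otherwise the raw minimum wins (ties go to
    the smaller model). Deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, k, rng)
    p_cap = max_size if max_size is not None else len(X.columns)

    per_fold_mse: dict[int, list[float]] = {}
    per_fold_r: dict[int, list[float]] = {}
    for f in range(k):
        train_idx = fold != f
        test_idx = fold == f
        if test_idx.sum() == 0:
            continue
        path = stepwise_fit(X[train_idx], y[train_idx], family, p_cap)
        for size in range(len(path.models)):
            yhat = path.predict(X[test_idx], size)
            mse = float(np.mean((y[test_idx] - yhat) ** 2))
            per_fold_mse.setdefault(size, []).append(mse)
            if np.std(yhat) > 0 and np.std(y[test_idx]) > 0:
                r = float(np.corrcoef(y[test_idx], yhat)[0, 1])
            else:
                r = 0.0
            per_fold_r.setdefault(size, []).append(r)

    # only sizes reached in every fold are comparable
    sizes = sorted(s for s, v in per_fold_mse.items() if len(v) == k)
    curve = pd.DataFrame(
        {
            "size": sizes,
            "mean_mse": [float(np.mean(per_fold_mse[s])) for s in sizes],
            "se_mse": [
                float(np.std(per_fold_mse[s], ddof=1) / math.sqrt(k)) for s in sizes
            ],
            "mean_r": [float(np.mean(per_fold_r[s])) for s in sizes],
        }
    )
    i_best = int(curve["mean_mse"].idxmin())
    if one_se:
        threshold = curve.loc[i_best, "mean_mse"] + curve.loc[i_best, "se_mse"]
        eligible = curve[curve["mean_mse"] <= threshold]
        best = int(eligible["size"].min())
    else:
        best = int(curve.loc[i_best, "size"])
    return best, curve


def curds_whey_matrix(
    Y: np.ndarray,
    Yhat: np.ndarray,
    n_predictors: int,
    epsilon: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate the curds-and-whey shrinkage matrix (GCV form).

    With ``r = p/n`` (p predictors, n samples) and ``c_i^2`` the squared
    canonical correlations between the true responses ``Y`` and the
    sub-model predictions ``Yhat``, the per-coordinate shrinkage factors are

        d_i = (1 - r) (c_i^2 - r) / ((1 - r)^2 c_i^2 + r^2 (1 - c_i^2))

    truncated into [0, 1]. The matrix returned acts on prediction vectors in
    the original coordinates: ``M = T^-1 D T`` with ``T`` the canonical
    y-coordinate transform. A singular canonical problem is ridge-stabilized
    with a logged epsilon.

    Returns ``(M, d, c2)``.
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("Y must have at least 2 response columns")
    if Y.shape != Yhat.shape:
        raise ValueError("Y and Yhat shapes differ")
    n, q = Y.shape
    if n <= q:
        raise ValueError("need more samples than response columns")
    r = n_predictors / n

    Yc = Y - Y.mean(axis=0)
    Hc = Yhat - Yhat.mean(axis=0)
    Syy = Yc.T @ Yc / n
    Shh = Hc.T @ Hc / n
    Syh = Yc.T @ Hc / n

    def _stabilize(S: np.ndarray) -> np.ndarray:
        try:
            np.linalg.cholesky(S)
            return S
        except np.linalg.LinAlgError:
            logger.warning("singular canonical problem; ridge epsilon=%g applied", epsilon)
            return S + epsilon * np.eye(S.shape[0]) * max(1.0, np.trace(S))

    Syy = _stabilize(Syy)
    Shh = _stabilize(Shh)

    # whiten Y: W = Syy^{-1/2}
    evals, evecs = np.linalg.eigh(Syy)
    evals = np.clip(evals, epsilon, None)
    W = evecs @ np.diag(evals ** -0.5) @ evecs.T

    K = W @ Syh @ np.linalg.solve(Shh, Syh.T) @ W  # symmetric, eigvals = c_i^2
    c2, U = np.linalg.eigh(K)
    idx = np.argsort(c2)[::-1]
    c2 = np.clip(c2[idx], 0.0, 1.0)
    U = U[:, idx]

    d = shrinkage_factor(c2, r)
    T = U.T @ W  # canonical coordinates of y: z = T y
    M = np.linalg.solve(T, np.diag(d) @ T)
    return M, d, c2


def shrinkage_factor(c2: np.ndarray | float, r: float) -> np.ndarray:
    """Closed-form GCV shrinkage ``d_i`` for squared canonical correlation(s)."""
    c2 = np.asarray(c2, dtype=float)
    denom = (1 - r) ** 2 * c2 + r ** 2 * (1 - c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, (1 - r) * (c2 - r) / denom, 0.0)
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cohort-level training


def _design_matrix(cohort: Cohort, analytes: Sequence[str], exponent: float) -> pd.DataFrame:
    X = cohort.marker_matrix(analytes)
    X = X.pow(exponent)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing marker values for analytes {bad}")
    return X.reset_index(drop=True)


def _component_targets(cohort: Cohort) -> dict[str, np.ndarray]:
    return {
        "PTJC28": np.array([float(r.tjc28) for r in cohort]),
        "PSJC28": np.array([float(r.sjc28) for r in cohort]),
        "PPGA": np.array([float(r.pga) for r in cohort]),
    }


def fit_component(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str,
    k: int = 10,
    max_size: int | None = None,
    seed: int = 0,
) -> tuple[ComponentModel, int, ModelPath]:
    """Select a size by nested CV, then refit the stepwise path at that size."""
    size, _curve = nested_cv_select(X, y, family, k=k, max_size=max_size, seed=seed)
    path = stepwise_fit(X, y, family, max_size=max_size)
    size = min(size, len(path.models) - 1)
    intercept, coefs = path.models[size]
    return ComponentModel(intercept=intercept, coefficients=coefs), size, path


def train_algorithm(
    cohort: Cohort,
    family: str = "cw-lasso",
    seed: int = 0,
    k: int = 10,
    max_size: int | None = None,
    analytes: Sequence[str] | None = None,
    exponent: float = 0.1,
    combination: Mapping[str, float] | None = None,
) -> tuple[CWModel, AlgorithmCoefficients]:
    """Train component models (and shrinkage, for CW families) on a cohort.

    Markers are power-transformed before fitting; CRP is excluded from the
    predictor set (it enters the combination directly). Returns the trained
    :class:`CWModel` together with an :class:`AlgorithmCoefficients` ready
    for scoring. Deterministic given ``seed``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    base_family = family.replace("cw-", "")
    if analytes is None:
        analytes = [a for a in cohort.analytes if a != "CRP"]
    X = _design_matrix(cohort, analytes, exponent)
    targets = _component_targets(cohort)

    components: dict[str, ComponentModel] = {}
    sizes: dict[str, int] = {}
    paths: dict[str, ModelPath] = {}
    for i, (name, y) in enumerate(targets.items()):
        model, size, path = fit_component(
            X, y, base_family, k=k, max_size=max_size, seed=seed + i
        )
        components[name] = model
        sizes[name] = size
        paths[name] = path

    if family.startswith("cw-"):
        Y = np.column_stack([targets["PTJC28"], targets["PSJC28"]])
        Yhat = np.column_stack(
            [
                paths["PTJC28"].predict(X, sizes["PTJC28"]),
                paths["PSJC28"].predict(X, sizes["PSJC28"]),
            ]
        )
        used = set(components["PTJC28"].coefficients) | set(
            components["PSJC28"].coefficients
        )
        p = max(1, len(used))
        M, d, c2 = curds_whey_matrix(Y, Yhat, n_predictors=p)
    else:
        M = np.eye(2)
        d = np.ones(2)
        c2 = np.ones(2)

    model = CWModel(
        components=components,
        shrinkage=M,
        family=family,
        selected_sizes=sizes,
        seed=seed,
        shrinkage_factors=d,
        canonical_correlations=c2,
        metadata={"n": len(cohort), "analytes": list(analytes)},
    )
    if combination is None:
        combination = {
            "w_tjc": 0.56,
            "w_sjc": 0.28,
            "w_crp": 0.36,
            "w_pga": 0.14,
            "constant": 0.96,
        }
    coeffs = AlgorithmCoefficients(
        components=components,
        shrinkage=((float(M[0, 0]), float(M[0, 1])), (float(M[1, 0]), float(M[1, 1]))),
        combination=dict(combination),
        exponent=exponent,
        panel=tuple(sorted(set(analytes) | {"CRP"})),
    )
    return model, coeffs


def _das_vector(cohort: Cohort) -> np.ndarray:
    return np.array(
        [das28_crp4(r.tjc28, r.sjc28, r.crp_mg_l, r.pga * 10.0) for r in cohort]
    )


def compare_families(
    cohort: Cohort,
    families: Sequence[str] = ("lasso", "cw-lasso"),
    reps: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    k: int = 10,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Compare model families by repeated 70/30 train/test splits.

    Each rep draws one split (shared by all families, so comparisons are
    paired), trains each family on the training rows, scores the held-out
    rows and records Pearson r to DAS28-CRP plus AUROC at the fixed 2.67
    threshold and at the study-median threshold.
    """
    from mbda.evaluate import auroc
    from mbda.scoring import score_record

    das_all = _das_vector(cohort)
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        n = len(cohort)
        idx = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train_idx, test_idx = idx[:n_train], idx[n_train:]
        train = Cohort(records=[cohort[i] for i in train_idx])
        test_records = [cohort[i] for i in test_idx]
        das_test = das_all[test_idx]
        for family in families:
            _, coeffs = train_algorithm(
                train, family=family, seed=seed + rep, k=k, max_size=max_size
            )
            scores = np.array(
                [float(score_record(r, coeffs).pre_scale) for r in test_records]
            )
            if np.std(scores) > 0 and np.std(das_test) > 0:
                r_val = float(stats.pearsonr(das_test, scores)[0])
            else:
                r_val = float("nan")
            labels_fixed = (das_test > 2.67).astype(int)
            labels_med = (das_test > np.median(das_all)).astype(int)
            rows.append(
                {
                    "rep": rep,
                    "family": family,
                    "pearson_r": r_val,
                    "auroc_fixed": _safe_auroc(scores, labels_fixed, auroc),
                    "auroc_median": _safe_auroc(scores, labels_med, auroc),
                    "n_test": len(test_idx),
                }
            )
    return pd.DataFrame(rows)


def _safe_auroc(scores: np.ndarray, labels: np.ndarray, auroc_fn) -> float:
    if labels.min() == labels.max():
        return float("nan")
    return float(auroc_fn(scores, labels))
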