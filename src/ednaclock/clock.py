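"""Grouped penalized-regression epigenetic clocks with objective selection.

A clock is a linear model ``age = b0 + X beta`` fitted on the aging-site
methylation matrix by the group elastic net (``solver``).  The search
space is systematic: every penalty-mixing value on an alpha grid (default
0 to 1 in steps of 0.01), every grouping scheme obtained by "pasting"
subsets of the four site features (gene, modification type, mean coverage,
mean reliability; 16 subsets including the empty one, which leaves every
site in its own group), a configurable fold count for cross-validation
(3 for the six-age design), and B independent re-randomizations of the
fold assignment ("bootstrap" iterations, default 10) to absorb the strong
fold-assignment sensitivity at n = 6.

Model selection uses the dual standardized-MAE criterion: across a pool of
candidates, z-standardize the cross-validated MAE and the training MAE,
sum the two z-scores, and keep the candidate with the lowest total.  MAE
is the *median* absolute error throughout.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solver
from .errors import ClockSerializationError, DataError
from .sites import ClockDesignMatrix

logger = logging.getLogger(__name__)

CLOCK_FORMAT_VERSION = "1"

#: The four site features available for grouping-by-pasting.
GROUPING_FEATURES = ("gene", "mod_type", "coverage", "reliability")

DEFAULT_ALPHA_GRID = np.round(np.arange(0, 101) * 0.01, 2)
DEFAULT_N_BOOTSTRAP = 10


def all_schemes() -> list[tuple[str, ...]]:
    """All 16 grouping schemes, smallest first, deterministic order."""
    out: list[tuple[str, ...]] = []
    for r in range(len(GROUPING_FEATURES) + 1):
        out.extend(itertools.combinations(GROUPING_FEATURES, r))
    return out


def scheme_name(scheme: tuple[str, ...]) -> str:
    return "+".join(scheme) if scheme else "none"


def make_group_labels(metadata: pd.DataFrame, scheme: tuple[str, ...]) -> np.ndarray:
    """One pasted label per site for a grouping scheme.

    Quantitative features are discretized before pasting (mean coverage to
    the nearest integer, mean reliability to 1 decimal); the empty scheme
    gives every site its own label.
    """
    unknown = set(scheme) - set(GROUPING_FEATURES)
    if unknown:
        raise ValueError(f"unknown grouping features: {sorted(unknown)}")
    if not scheme:
        return metadata.index.to_numpy().astype(str)
    parts = []
    for feat in GROUPING_FEATURES:  # fixed pasting order
        if feat not in scheme:
            continue
        if feat == "gene":
            col = metadata["gene"]
        elif feat == "mod_type":
            col = metadata["mod_type"]
        elif feat == "coverage":
            col = metadata["mean_coverage"].round(0).astype(int)
        else:
            col = metadata["mean_reliability"].round(1)
        if col.isna().any():
            raise DataError(f"missing {feat} value in site metadata")
        parts.append(col.astype(str))
    labels = parts[0]
    for p in parts[1:]:
        labels = labels + "|" + p
    return labels.to_numpy()


def mae(y_true, y_pred) -> float:
    """Median absolute error (mid-point convention for even n)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(np.median(np.abs(y_true - y_pred)))


def scaled_mae(mae_days: float, age_min: float, age_max: float) -> float:
    """MAE as a fraction of the age range, reported to 2 decimals."""
    if age_max <= age_min:
        raise ValueError("age range must be positive")
    return round(mae_days / (age_max - age_min), 2)


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Near-even k-fold partition from a seeded permutation."""
    if k < 2 or k > n:
        raise ValueError(f"fold count {k} invalid for {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def default_fold_options(n: int) -> list[int]:
    """Fold counts considered by the grid: for the six-age design the
    usable count is 3; otherwise all k in [2, n/2] leaving every training
    fold at least 2 samples."""
    if n == 6:
        return [3]
    opts = []
    for k in range(2, n // 2 + 1):
        if n - _max_fold_size(n, k) >= 2:
            opts.append(k)
    return opts or [2]


def _max_fold_size(n: int, k: int) -> int:
    return -(-n // k)


# Internal precomputation shared by cross_validate / fit_candidate /
# grid_search so the optimized sweep and the one-off fit take the same
# numerical path.


@dataclass
class _Prep:
    X: np.ndarray
    y: np.ndarray
    Xs: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    ybar: float
    yc: np.ndarray


def _prep_design(X: np.ndarray, y: np.ndarray) -> _Prep:
    Xs, mean, scale = solver.standardize_columns(X)
    ybar = float(y.mean())
    return _Prep(X=X, y=y, Xs=Xs, mean=mean, scale=scale, ybar=ybar, yc=y - ybar)


@dataclass
class _FoldPrep:
    test_idx: np.ndarray
    Xs_tr: np.ndarray
    yc_tr: np.ndarray
    ybar_tr: float
    Xte_std: np.ndarray


def _prep_folds(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]) -> list[_FoldPrep]:
    n = len(y)
    out = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if train_mask.sum() < 2:
            raise DataError(
                f"training fold with {int(train_mask.sum())} samples; need >= 2"
            )
        Xtr = X[train_mask]
        Xs_tr, mean_tr, scale_tr = solver.standardize_columns(Xtr)
        ybar_tr = float(y[train_mask].mean())
        Xte_std = (X[test_idx] - mean_tr) / scale_tr
        out.append(
            _FoldPrep(
                test_idx=test_idx,
                Xs_tr=Xs_tr,
                yc_tr=y[train_mask] - ybar_tr,
                ybar_tr=ybar_tr,
                Xte_std=Xte_std,
            )
        )
    return out


@dataclass
class CVResult:
    lambdas: np.ndarray
    cv_curve: np.ndarray  # per-lambda MAE
    best_index: int
    cv_mae: float
    folds: list[np.ndarray]
    oof_predictions: np.ndarray  # (n, n_lambda)


def _oof_predictions(
    fold_preps: list[_FoldPrep],
    groups: solver.GroupStructure,
    alpha: float,
    lambdas: np.ndarray,
    n: int,
    tol: float,
    max_iter: int,
    Lg_folds: list[np.ndarray] | None = None,
) -> np.ndarray:
    oof = np.empty((n, len(lambdas)))
    for i, fp in enumerate(fold_preps):
        coefs = solver.solve_path_standardized(
            fp.Xs_tr,
            fp.yc_tr,
            groups,
            alpha,
            lambdas,
            tol=tol,
            max_iter=max_iter,
            Lg=None if Lg_folds is None else Lg_folds[i],
        )
        oof[fp.test_idx] = fp.Xte_std @ coefs.T + fp.ybar_tr
    return oof


def _cv_curve(y: np.ndarray, oof: np.ndarray, folds, pooling: str) -> np.ndarray:
    if pooling == "pooled":
        return np.median(np.abs(y[:, None] - oof), axis=0)
    if pooling == "per_fold":
        curves = [
            np.median(np.abs(y[f][:, None] - oof[f]), axis=0) for f in folds
        ]
        return np.mean(curves, axis=0)
    raise ValueError(f"unknown CV pooling {pooling!r}")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    group_labels,
    alpha: float,
    lambdas: np.ndarray | None = None,
    k: int = 3,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
    pooling: str = "pooled",
    tol: float = 1e-4,
    max_iter: int = 1_000,
) -> CVResult:
    """Per-lambda cross-validated MAE curve.

    Out-of-fold predictions over the k folds are pooled and the MAE is
    taken over all n samples (``pooling='per_fold'`` averages fold-wise
    MAEs instead).  The lambda path is computed on the full data and
    shared across folds; ``lambda* = argmin`` of the curve, ties to the
    larger (more regularized) lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    prep = _prep_design(X, y)
    groups = (
        solver.singleton_groups(X.shape[1])
        if group_labels is None
        else solver.group_structure(group_labels)
    )
    if lambdas is None:
        lambdas = solver.lambda_path(prep.Xs, prep.yc, groups, alpha)
    lambdas = np.asarray(lambdas, dtype=float)
    if folds is None:
        folds = make_folds(n, k, seed)
    fold_preps = _prep_folds(X, y, folds)
    oof = _oof_predictions(fold_preps, groups, alpha, lambdas, n, tol, max_iter)
    curve = _cv_curve(y, oof, folds, pooling)
    best = int(np.argmin(curve))
    return CVResult(
        lambdas=lambdas,
        cv_curve=curve,
        best_index=best,
        cv_mae=float(curve[best]),
        folds=folds,
        oof_predictions=oof,
    )


@dataclass
class FittedClock:
    """A fitted epigenetic clock: intercept + per-site coefficients plus
    the hyperparameters and MAE metrics of the winning candidate."""

    intercept: float  # days post-hatch
    coefficients: np.ndarray  # days per methylation %, per site
    site_keys: list[str]
    site_genes: list[str]
    site_mod_types: list[str]
    alpha: float
    lam: float
    scheme: tuple[str, ...]
    k: int
    seed: int
    cv_mae: float
    train_mae: float
    n_selected: int
    dataset: str = "full"
    selection_score: float = float("nan")
    version: str = CLOCK_FORMAT_VERSION

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X_new, dtype=float) @ self.coefficients


def fit_candidate(
    design: ClockDesignMatrix,
    scheme: tuple[str, ...],
    alpha: float,
    k: int,
    seed: int,
    dataset: str = "full",
    pooling: str = "pooled",
    tol: float = 1e-3,
    max_iter: int = 100,
) -> FittedClock:
    """Cross-validate one (scheme, alpha, k, fold-seed) candidate, refit on
    all samples at the CV-optimal lambda, and package the clock."""
    X, y = design.X, design.ages
    labels = make_group_labels(design.metadata, scheme)
    prep = _prep_design(X, y)
    groups = solver.group_structure(labels) if scheme else solver.singleton_groups(X.shape[1])
    lambdas = solver.lambda_path(prep.Xs, prep.yc, groups, alpha)
    # for the empty scheme pass None so cross_validate builds the identical
    # identity-ordered singleton structure the grid sweep uses
    cv = cross_validate(
        X, y, labels if scheme else None, alpha, lambdas=lambdas, k=k,
        seed=seed, pooling=pooling, tol=tol, max_iter=max_iter,
    )
    coefs_std = solver.solve_path_standardized(
        prep.Xs, prep.yc, groups, alpha, lambdas, tol=tol, max_iter=max_iter
    )
    li = cv.best_index
    beta_std = coefs_std[li]
    beta = beta_std / prep.scale
    intercept = prep.ybar - float(beta @ prep.mean)
    train_pred = prep.Xs @ beta_std + prep.ybar
    return FittedClock(
        intercept=intercept,
        coefficients=beta,
        site_keys=design.site_keys,
        site_genes=list(design.metadata["gene"]),
        site_mod_types=list(design.metadata["mod_type"]),
        alpha=float(alpha),
        lam=float(lambdas[li]),
        scheme=tuple(scheme),
        k=k,
        seed=seed,
        cv_mae=cv.cv_mae,
        train_mae=mae(y, train_pred),
        n_selected=int(np.count_nonzero(beta_std)),
        dataset=dataset,
    )


# Model selection -----------------------------------------------------------


def selection_scores(candidates: pd.DataFrame) -> pd.Series:
    """Dual standardized-MAE score: z(cv_mae) + z(train_mae) across the
    candidate pool (a zero-variance metric contributes 0)."""
    if candidates.empty:
        raise ValueError("no candidates to score")

    def z(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.zeros(len(col)), index=col.index)
        return (col - col.mean()) / sd

    return z(candidates["cv_mae"]) + z(candidates["train_mae"])


def select_best(candidates: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Lowest dual-MAE score; ties broken by lower cv_mae, then lower
    alpha, then lower iteration index.  Returns (best row, scores)."""
    scores = selection_scores(candidates)
    order = candidates.assign(selection_score=scores).sort_values(
        ["selection_score", "cv_mae", "alpha", "iteration"],
        kind="stable",
    )
    best = order.iloc[0]
    return best, scores


@dataclass
class SelectionSummary:
    """All candidates of one grid search, the per-scheme optima (one
    optimal candidate per grouping scheme), and the refitted best."""

    candidates: pd.DataFrame
    scheme_optima: pd.DataFrame
    best: pd.Series
    best_clock: FittedClock
    dataset: str = "full"


def grid_search(
    design: ClockDesignMatrix,
    alpha_grid=None,
    fold_options=None,
    schemes=None,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    base_seed: int = 0,
    dataset: str = "full",
    pooling: str = "pooled",
    tol: float = 1e-3,
    max_iter: int = 100,
    progress: bool = False,
) -> SelectionSummary:
    """Evaluate every (scheme, alpha, k, iteration) candidate.

    Iterations are independent fold re-randomizations with seed
    ``base_seed + iteration``.  Per scheme the dual-MAE-optimal candidate
    is retained; the global best over those optima is refitted into a
    ``FittedClock``.  Deterministic given ``base_seed``.
    """
    X, y = design.X, design.ages
    n = len(y)
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    if fold_options is None:
        fold_options = default_fold_options(n)
    if schemes is None:
        schemes = all_schemes()
    prep = _prep_design(X, y)

    # Fold partitions and per-fold standardizations are shared across
    # schemes and alphas; cache them once per (k, iteration).
    fold_cache: dict[tuple[int, int], list[_FoldPrep]] = {}
    fold_parts: dict[tuple[int, int], list[np.ndarray]] = {}
    for k in fold_options:
        for b in range(n_bootstrap):
            folds = make_folds(n, k, base_seed + b)
            fold_parts[(k, b)] = folds
            fold_cache[(k, b)] = _prep_folds(X, y, folds)

    rows = []
    for scheme in schemes:
        labels = make_group_labels(design.metadata, scheme)
        groups = (
            solver.group_structure(labels)
            if scheme
            else solver.singleton_groups(X.shape[1])
        )
        Xp_full = np.asfortranarray(prep.Xs[:, groups.perm])
        Lg_full = solver.group_lipschitz(Xp_full, groups.grp_ptr)
        Lg_folds: dict[tuple[int, int], list[np.ndarray]] = {}
        for key, fps in fold_cache.items():
            Lg_folds[key] = [
                solver.group_lipschitz(
                    np.asfortranarray(fp.Xs_tr[:, groups.perm]), groups.grp_ptr
                )
                for fp in fps
            ]
        if progress:
            logger.info("grid: scheme %s (%d groups)", scheme_name(scheme), groups.n_groups)
        for alpha in alpha_grid:
            alpha = float(alpha)
            lambdas = solver.lambda_path(prep.Xs, prep.yc, groups, alpha)
            full_coefs = solver.solve_path_standardized(
                prep.Xs, prep.yc, groups, alpha, lambdas,
                tol=tol, max_iter=max_iter, Lg=Lg_full,
            )
            train_preds = prep.Xs @ full_coefs.T + prep.ybar  # (n, n_lambda)
            train_curve = np.median(np.abs(y[:, None] - train_preds), axis=0)
            n_nonzero = np.count_nonzero(full_coefs, axis=1)
            for k in fold_options:
                for b in range(n_bootstrap):
                    oof = _oof_predictions(
                        fold_cache[(k, b)], groups, alpha, lambdas, n,
                        tol, max_iter, Lg_folds=Lg_folds[(k, b)],
                    )
                    curve = _cv_curve(y, oof, fold_parts[(k, b)], pooling)
                    li = int(np.argmin(curve))
                    rows.append(
                        {
                            "dataset": dataset,
                            "scheme": scheme_name(scheme),
                            "alpha": alpha,
                            "k": k,
                            "iteration": b,
                            "cv_mae": float(curve[li]),
                            "train_mae": float(train_curve[li]),
                            "n_selected": int(n_nonzero[li]),
                            "lambda": float(lambdas[li]),
                        }
                    )
    candidates = pd.DataFrame(rows)
    candidates["selection_score"] = selection_scores(candidates)

    optima_rows = []
    for scheme in schemes:
        subset = candidates[candidates["scheme"] == scheme_name(scheme)]
        best_row, _ = select_best(subset)
        optima_rows.append(best_row.drop(labels=["selection_score"]))
    scheme_optima = pd.DataFrame(optima_rows).reset_index(drop=True)
    scheme_optima["selection_score"] = selection_scores(scheme_optima)
    best, _ = select_best(scheme_optima)

    scheme_features = tuple(
        () if best["scheme"] == "none" else tuple(best["scheme"].split("+"))
    )
    best_clock = fit_candidate(
        design,
        scheme_features,
        float(best["alpha"]),
        int(best["k"]),
        base_seed + int(best["iteration"]),
        dataset=dataset,
        pooling=pooling,
        tol=tol,
        max_iter=max_iter,
    )
    best_clock.selection_score = float(best["selection_score"])
    return SelectionSummary(
        candidates=candidates,
        scheme_optima=scheme_optima,
        best=best,
        best_clock=best_clock,
        dataset=dataset,
    )


# Prediction and reporting --------------------------------------------------


def predict_ages(clock: FittedClock, X_new, site_keys=None) -> np.ndarray:
    """Predict ages (days post-hatch) for new samples.

    ``X_new`` may be a DataFrame with site-key columns (aligned by name)
    or an array whose columns follow ``site_keys``; every clock site must
    be present.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [k for k in clock.site_keys if k not in X_new.columns]
        if missing:
            raise DataError(f"missing sites in new data: {missing[:10]}")
        X_arr = X_new[clock.site_keys].to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X_new, dtype=float)
        keys = list(site_keys) if site_keys is not None else clock.site_keys
        if keys != clock.site_keys:
            missing = [k for k in clock.site_keys if k not in set(keys)]
            raise DataError(
                f"site keys do not match the clock; missing: {missing[:10]}"
            )
        if X_arr.shape[-1] != len(clock.site_keys):
            raise DataError(
                f"expected {len(clock.site_keys)} site columns, got {X_arr.shape[-1]}"
            )
    if not np.all(np.isfinite(X_arr)):
        raise DataError("non-finite methylation levels in new data")
    return clock.predict(X_arr)


def gene_importance(clock: FittedClock) -> pd.DataFrame:
    """Per-gene importance: sum of |coefficients| over the gene's sites as
    a fraction of the total, plus selected-site counts."""
    abs_coef = np.abs(clock.coefficients)
    total = float(abs_coef.sum())
    if total == 0:
        raise DataError("all coefficients are zero; gene importance undefined")
    df = pd.DataFrame(
        {
            "gene": clock.site_genes,
            "abs_coef": abs_coef,
            "selected": clock.coefficients != 0,
        }
    )
    out = (
        df.groupby("gene", sort=True)
        .agg(sum_abs_coef=("abs_coef", "sum"), n_selected=("selected", "sum"))
        .reset_index()
    )
    out["proportion"] = out["sum_abs_coef"] / total
    return out.sort_values("proportion", ascending=False, kind="stable").reset_index(
        drop=True
    )


# Serialization -------------------------------------------------------------


def write_clock(clock: FittedClock, path) -> None:
    payload = {
        "format_version": clock.version,
        "dataset": clock.dataset,
        "intercept": clock.intercept,
        "coefficients": [float(c) for c in clock.coefficients],
        "site_keys": clock.site_keys,
        "site_genes": clock.site_genes,
        "site_mod_types": clock.site_mod_types,
        "alpha": clock.alpha,
        "lambda": clock.lam,
        "scheme": list(clock.scheme),
        "k": clock.k,
        "seed": clock.seed,
        "cv_mae": clock.cv_mae,
        "train_mae": clock.train_mae,
        "n_selected": clock.n_selected,
        "selection_score": clock.selection_score,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_clock(path) -> FittedClock:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ClockSerializationError(f"{path}: unreadable clock file: {exc}") from exc
    version = payload.get("format_version")
    if version != CLOCK_FORMAT_VERSION:
        raise ClockSerializationError(
            f"{path}: clock format version {version!r}, expected "
            f"{CLOCK_FORMAT_VERSION!r}"
        )
    try:
        return FittedClock(
            intercept=payload["intercept"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            site_keys=list(payload["site_keys"]),
            site_genes=list(payload["site_genes"]),
            site_mod_types=list(payload["site_mod_types"]),
            alpha=payload["alpha"],
            lam=payload["lambda"],
            scheme=tuple(payload["scheme"]),
            k=payload["k"],
            seed=payload["seed"],
            cv_mae=payload["cv_mae"],
            train_mae=payload["train_mae"],
            n_selected=payload["n_selected"],
            dataset=payload.get("dataset", "full"),
            selection_score=payload.get("selection_score", float("nan")),
            version=version,
        )
    except KeyError as exc:
        raise ClockSerializationError(f"{path}: missing field {exc}") from exc
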