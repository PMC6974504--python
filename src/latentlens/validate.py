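"""Model validation: R2/Q2/AUC metrics, Monte-Carlo repeated k-fold
cross-validation over a hyperparameter grid, convex-hull hyperparameter
selection, and permutation testing.

Cross-validation uses stratified k-fold partitions redrawn for each of a
number of Monte-Carlo repartitions; every hyperparameter combination is
evaluated on the *same* partitions so comparisons across the grid are
paired.  Q2 is the cross-validated analogue of R2 (1 - PRESS/SS) and may be
negative; AUC is reported both for the full-data fit (AUC_full) and for the
pooled cross-validated predictions (AUC_cv).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .base import fit_model

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s) & _MAX_SEED for s in ss.generate_state(n, dtype=np.uint32)]


def auc(y_true, y_score) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney U statistic normalised by n1*n0, with tied
    scores counted one half.
    """
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined: only one class present in y_true")
    return float(roc_auc_score(y_true, np.asarray(y_score, float)))


def r2_q2(y_true, y_fit, y_cv_pred):
    """(R2, Q2) of fitted and cross-validated continuous predictions.

    R2 = 1 - SS_res(fit)/SS_tot and Q2 = 1 - PRESS(cv)/SS_tot, both against
    the raw {0,1} outcome.  Q2 can be negative when cross-validated
    predictions are worse than predicting the class mean.
    """
    y_true = np.asarray(y_true, float)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    r2 = 1.0 - np.sum((y_true - np.asarray(y_fit, float)) ** 2) / ss_tot
    q2 = 1.0 - np.sum((y_true - np.asarray(y_cv_pred, float)) ** 2) / ss_tot
    return float(r2), float(q2)


def make_partitions(y, folds=5, repartitions=10, seed=0):
    """Stratified k-fold partitions for each Monte-Carlo repartition.

    Returns a list (one per repartition) of lists of (train_idx, val_idx).
    A repartition whose validation folds do not all contain both classes is
    redrawn with a fresh seed (logged).
    """
    y = np.asarray(y)
    seeds = _child_seeds(seed, 4 * repartitions)
    parts, attempt = [], 0
    while len(parts) < repartitions:
        if attempt >= len(seeds):
            raise ValueError("could not build stratified folds with both classes")
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seeds[attempt])
        attempt += 1
        folds_ix = [(tr, va) for tr, va in skf.split(np.zeros_like(y), y)]
        if any(np.unique(y[va]).size < 2 for _, va in folds_ix):
            logger.warning("repartition redrawn: a fold lacked both classes")
            continue
        parts.append(folds_ix)
    return parts


def _cv_predictions(X, y, family, hyper, partition, fit_seeds):
    """Out-of-fold continuous predictions for one repartition."""
    y_cv = np.empty(len(y))
    for (tr, va), fs in zip(partition, fit_seeds):
        res = fit_model(family, X[tr], y[tr], hyper, seed=fs)
        y_cv[va] = res.predict(X[va])[1]
    return y_cv


@dataclass
class CVGrid:
    """Per-hyperparameter-combination cross-validation summaries."""

    family: str
    grid: list                 # list of hyperparameter dicts
    table: pd.DataFrame        # R2_full, Q2_cv, AUC_full, AUC_cv + dispersion
    folds: int
    repartitions: int
    seed: int

    def __len__(self):
        return len(self.grid)


def expand_grid(**param_lists) -> list:
    """Cartesian product of hyperparameter value lists into a grid."""
    keys = list(param_lists)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(param_lists[k] for k in keys))]


def cv_search(X, y, family, grid, folds=5, repartitions=10, seed=0) -> CVGrid:
    """Evaluate every hyperparameter combination by repeated stratified CV.

    All combinations share identical fold partitions and, for the network,
    identical per-fold initialisation seeds, so grid comparisons are paired.
    Deterministic given ``seed``.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    partitions = make_partitions(y, folds, repartitions, seed)
    fit_seeds = np.array(
        _child_seeds(seed + 1, repartitions * folds + 1)
    ).reshape(-1)
    full_seed = fit_seeds[-1]
    fold_seeds = fit_seeds[:-1].reshape(repartitions, folds)

    rows = []
    for hyper in grid:
        full = fit_model(family, X, y, hyper, seed=int(full_seed))
        y_fit = full.predict(X)[1]
        q2s, aucs = [], []
        for rep, part in enumerate(partitions):
            y_cv = _cv_predictions(X, y, family, hyper, part, fold_seeds[rep])
            _, q2 = r2_q2(y, y_fit, y_cv)
            q2s.append(q2)
            aucs.append(auc(y, y_cv))
        r2 = r2_q2(y, y_fit, y_fit)[0]
        rows.append(
            {
                **hyper,
                "R2_full": r2,
                "Q2_cv": float(np.mean(q2s)),
                "AUC_full": auc(y, y_fit),
                "AUC_cv": float(np.mean(aucs)),
                "Q2_cv_sd": float(np.std(q2s, ddof=1)) if len(q2s) > 1 else 0.0,
                "AUC_cv_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            }
        )
        if rows[-1]["R2_full"] < rows[-1]["Q2_cv"]:
            logger.warning("R2_full < Q2_cv for %s (sampling noise)", hyper)
    return CVGrid(family=family, grid=list(grid), table=pd.DataFrame(rows),
                  folds=folds, repartitions=repartitions, seed=seed)


@dataclass
class HyperSelection:
    index: int
    params: dict
    hull_indices: np.ndarray       # grid rows on the outer convex hull
    diagnostics: pd.DataFrame      # per-point |R2-Q2| and Q2 coordinates
    warning: Optional[str] = None


def _pareto_frontier(d, q):
    """Indices of points not dominated in (smaller gap, larger Q2)."""
    keep = []
    for i in range(len(d)):
        dominated = np.any(
            (d <= d[i]) & (q >= q[i]) & ((d < d[i]) | (q > q[i]))
        )
        if not dominated:
            keep.append(i)
    keep = np.array(keep)
    order = np.lexsort((q[keep], d[keep]))
    return keep[order]


def select_hyperparameters(cvgrid: CVGrid) -> HyperSelection:
    """Pick the grid point at the inflection of the outer convex hull of
    the |R2 - Q2| vs Q2 plot.

    Moving along the non-dominated frontier (increasing gap, increasing Q2),
    the hull's slope -- Q2 gained per unit of overfit gap -- decreases; the
    selected vertex is the interior hull vertex where that slope drops the
    most (the discrete inflection).  Degenerate hulls (fewer than three
    vertices, e.g. a single dominating point or a collinear grid) fall back
    to the maximum-Q2 vertex with a warning.  Full per-point coordinates are
    returned so the choice can be overridden by inspection.
    """
    t = cvgrid.table
    d = np.abs(t["R2_full"].to_numpy() - t["Q2_cv"].to_numpy())
    q = t["Q2_cv"].to_numpy()
    diagnostics = pd.DataFrame({"gap": d, "Q2_cv": q})

    frontier = _pareto_frontier(d, q)
    # upper convex hull over the frontier: slopes must be decreasing
    hull = []
    for i in frontier:
        while len(hull) >= 2:
            (d1, q1), (d2, q2_) = (d[hull[-2]], q[hull[-2]]), (d[hull[-1]], q[hull[-1]])
            # drop middle point if it lies on or below the chord
            if (d2 - d1) * (q[i] - q1) >= (q2_ - q1) * (d[i] - d1):
                hull.pop()
            else:
                break
        hull.append(i)
    hull = np.array(hull)

    warning = None
    if len(hull) < 3:
        # a single hull point means one combination dominates the grid;
        # two points (or a collinear frontier) leave the inflection undefined
        best = hull[np.argmax(q[hull])]
        if len(cvgrid) >= 3 and len(hull) > 1:
            warning = "degenerate hull: fell back to the maximum-Q2 grid point"
            logger.warning(warning)
    else:
        slopes = np.diff(q[hull]) / np.maximum(np.diff(d[hull]), 1e-12)
        slope_drop = slopes[:-1] - slopes[1:]       # change at interior vertices
        best = hull[1 + int(np.argmax(slope_drop))]
    return HyperSelection(
        index=int(best),
        params=cvgrid.grid[int(best)],
        hull_indices=hull,
        diagnostics=diagnostics,
        warning=warning,
    )


@dataclass
class PermutationResult:
    observed: dict                  # R2_full, Q2_cv, AUC_full, AUC_cv
    null: pd.DataFrame              # one row per permutation
    pvalues: dict
    n_perm: int


def permutation_test(X, y, family, hyper, n_perm=100, folds=5, seed=0
                     ) -> PermutationResult:
    """Permutation test of the fixed-hyperparameter model.

    The outcome labels are randomly permuted and the model is refitted and
    re-cross-validated for each of ``n_perm`` permutations, building null
    distributions for R2, Q2, AUC_full and AUC_cv.  Empirical p-values use
    the add-one correction p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 10:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed + 17, 2 * (n_perm + 1))

    def evaluate(labels, base):
        part = make_partitions(labels, folds, 1, seeds[2 * base])[0]
        fs = _child_seeds(seeds[2 * base + 1], folds + 1)
        full = fit_model(family, X, labels, hyper, seed=fs[-1])
        y_fit = full.predict(X)[1]
        y_cv = _cv_predictions(X, labels, family, hyper, part, fs[:-1])
        r2, q2 = r2_q2(labels, y_fit, y_cv)
        return {"R2_full": r2, "Q2_cv": q2,
                "AUC_full": auc(labels, y_fit), "AUC_cv": auc(labels, y_cv)}

    observed = evaluate(y, 0)
    null_rows = []
    for b in range(1, n_perm + 1):
        y_perm = rng.permutation(y)
        while np.unique(y_perm).size < 2:       # cannot happen for binary y
            y_perm = rng.permutation(y)
        null_rows.append(evaluate(y_perm, b))
    null = pd.DataFrame(null_rows)
    pvalues = {
        k: float((1 + np.sum(null[k].to_numpy() >= observed[k])) / (n_perm + 1))
        for k in observed
    }
    return PermutationResult(observed=observed, null=null, pvalues=pvalues,
                             n_perm=n_perm)
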