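"""Bootstrap resampling of a fixed-hyperparameter model with BCa inference.

The final model configuration is refitted on ``r`` resamples drawn with
replacement (the in-bag set, on average ~63% of unique samples) and
evaluated on the samples each resample did not draw (out-of-bag, ~37%,
consistent with the familiar "about one third").  Everything the workflow
visualises -- predictions, projection scores, input-side weights and the
four contribution metrics -- is stored per resample, and 95% confidence
intervals are computed with the bias-corrected and accelerated (BCa)
bootstrap, which adjusts the percentile interval for the bias and skewness
of the replicate distribution.

Latent variables / hidden neurons of each resampled model are sign- and
permutation-matched to the full-data reference model by maximal absolute
correlation of their weight vectors, so that across-resample summaries of
scores and weights are not scrambled by the models' axis indeterminacy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .base import fit_model
from .contribution import (
    METRICS_ANN,
    METRICS_PLS,
    ContributionTable,
    compute_metric,
    importance_threshold,
    significance_flags,
)
from .validate import _child_seeds, auc

logger = logging.getLogger(__name__)


def bca_interval(replicates, observed, alpha=0.05, jackknife=None):
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``z0`` comes from the fraction of replicates below the observed value;
    the acceleration ``a`` comes from the skewness of the leave-one-out
    ``jackknife`` replicates of the observed statistic (``a = 0`` when no
    jackknife values are supplied, i.e. bias correction only).  Adjusted
    percentiles are mapped through the empirical replicate distribution.
    """
    reps = np.asarray(replicates, float)
    reps = reps[np.isfinite(reps)]
    if reps.size < 2:
        raise ValueError("need at least 2 finite bootstrap replicates")
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    if np.ptp(reps) == 0:
        warnings.warn("all bootstrap replicates identical: degenerate interval")
        return float(reps[0]), float(reps[0])

    frac = np.mean(reps < observed) + 0.5 * np.mean(reps == observed)
    if frac <= 0 or frac >= 1:
        warnings.warn(
            "observed statistic outside the replicate range; "
            "bias correction clamped"
        )
        frac = np.clip(frac, 0.5 / reps.size, 1 - 0.5 / reps.size)
    z0 = stats.norm.ppf(frac)

    a = 0.0
    if jackknife is not None:
        jk = np.asarray(jackknife, float)
        jk = jk[np.isfinite(jk)]
        dev = jk.mean() - jk
        denom = np.sum(dev**2) ** 1.5
        if denom > 0:
            a = np.sum(dev**3) / (6.0 * denom)

    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    adj = np.clip(adj, 0.0, 1.0)
    lo, hi = np.quantile(reps, adj, method="hazen")
    return float(lo), float(hi)


def percentile_interval(replicates, alpha=0.05):
    reps = np.asarray(replicates, float)
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2], method="hazen")
    return float(lo), float(hi)


def _match_components(ref_w, w):
    """Greedy sign/permutation match of weight columns to a reference.

    Returns (perm, signs) such that ``w[:, perm] * signs`` has each column
    maximally absolutely correlated with the corresponding reference column.
    """
    k = ref_w.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            c = np.corrcoef(ref_w[:, i], w[:, j])[0, 1]
            corr[i, j] = 0.0 if not np.isfinite(c) else c
    perm = np.full(k, -1)
    used = set()
    for i in np.argsort(-np.abs(corr).max(axis=1)):    # most decisive rows first
        order = np.argsort(-np.abs(corr[i]))
        j = next(jj for jj in order if jj not in used)
        perm[i] = j
        used.add(j)
    signs = np.sign(corr[np.arange(k), perm])
    signs[signs == 0] = 1.0
    return perm, signs


@dataclass
class BootstrapEnsemble:
    """Per-resample artifacts of the bootstrap, aligned by resample index."""

    family: str
    hyper: dict
    r: int
    y: np.ndarray
    reference: object                  # full-data fitted results
    ib_indices: list                   # r arrays, multisets of size N
    oob_indices: list                  # r arrays, complements of unique in-bag
    yhat: np.ndarray                   # r x N predictions of every sample
    scores: np.ndarray                 # r x N x K harmonised projections
    weights: np.ndarray                # r x M x K harmonised input weights
    contributions: dict                # metric name -> r x M
    seed: int

    @property
    def n_samples(self) -> int:
        return self.yhat.shape[1]

    @property
    def n_components(self) -> int:
        return self.scores.shape[2]

    def membership(self):
        """Boolean (r x N) in-bag and out-of-bag membership masks."""
        n = self.n_samples
        ib = np.zeros((self.r, n), bool)
        oob = np.zeros((self.r, n), bool)
        for b in range(self.r):
            ib[b, np.unique(self.ib_indices[b])] = True
            oob[b, self.oob_indices[b]] = True
        return ib, oob

    def oob_fractions(self) -> np.ndarray:
        return np.array([len(o) / self.n_samples for o in self.oob_indices])

    def never_oob(self) -> np.ndarray:
        """Indices of samples that were in-bag in every resample."""
        _, oob = self.membership()
        return np.nonzero(~oob.any(axis=0))[0]


def bootstrap_models(X, y, family, hyper, r=100, seed=0) -> BootstrapEnsemble:
    """Refit the fixed-hyperparameter model on ``r`` bootstrap resamples.

    Deterministic given ``seed``; a resample whose in-bag draw misses a
    class is redrawn (logged).  Weight matrices and projection scores are
    harmonised to the full-data reference model before storage.
    """
    if r < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    fit_seeds = _child_seeds(seed + 29, r + 1)

    reference = fit_model(family, X, y, hyper, seed=fit_seeds[-1])
    ref_w = reference.x_weights
    k = ref_w.shape[1]

    ib_list, oob_list = [], []
    yhat = np.empty((r, n))
    scores = np.empty((r, n, k))
    weights = np.empty((r, X.shape[1], k))
    metrics = METRICS_PLS if family == "pls" else METRICS_ANN
    contributions = {m: np.empty((r, X.shape[1])) for m in metrics}

    for b in range(r):
        ib = rng.integers(0, n, n)
        while np.unique(y[ib]).size < 2:
            logger.warning("bootstrap resample %d redrawn: one class missing", b)
            ib = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), ib)
        res = fit_model(family, X[ib], y[ib], hyper, seed=fit_seeds[b])
        s_all, p_all = res.predict(X)
        perm, signs = _match_components(ref_w, res.x_weights)
        ib_list.append(ib)
        oob_list.append(oob)
        yhat[b] = p_all
        scores[b] = s_all[:, perm] * signs
        weights[b] = res.x_weights[:, perm] * signs
        for m in metrics:
            contributions[m][b] = compute_metric(m, res)

    return BootstrapEnsemble(
        family=family, hyper=dict(hyper), r=r, y=y, reference=reference,
        ib_indices=ib_list, oob_indices=oob_list, yhat=yhat, scores=scores,
        weights=weights, contributions=contributions, seed=seed,
    )


def _jackknife_auc(y, y_score):
    """Leave-one-sample-out replicates of the AUC of fixed predictions."""
    n = len(y)
    out = np.full(n, np.nan)
    mask = np.ones(n, bool)
    for i in range(n):
        mask[i] = False
        if np.unique(y[mask]).size == 2:
            out[i] = auc(y[mask], y_score[mask])
        mask[i] = True
    return out[np.isfinite(out)]


@dataclass
class EvaluationSummary:
    ib_auc: np.ndarray                 # r in-bag (apparent) AUCs
    oob_auc: np.ndarray                # r out-of-bag AUCs
    ib_auc_ci: tuple
    oob_auc_ci: tuple
    ib_auc_median: float
    oob_auc_median: float
    roc_grid: np.ndarray               # common false-positive-rate grid
    roc_ib_band: np.ndarray            # 2 x G pointwise 95% band (TPR)
    roc_oob_band: np.ndarray
    roc_reference: np.ndarray          # reference-model TPR on the grid


def _roc_on_grid(y, y_score, grid):
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, y_score)
    return np.interp(grid, fpr, tpr)


def aggregate_evaluation(ens: BootstrapEnsemble, alpha=0.05,
                         grid_size=101) -> EvaluationSummary:
    """Per-resample in-bag/out-of-bag AUCs with BCa CIs and ROC bands.

    The in-bag AUC is computed on the resample's own (multiset) draw, the
    out-of-bag AUC on the unseen samples; acceleration for the BCa interval
    comes from leave-one-sample-out jackknifing of the reference model's
    apparent AUC.  ROC curves are interpolated onto a common false-positive
    grid and summarised by pointwise 95% percentile bands.
    """
    y = ens.y
    grid = np.linspace(0, 1, grid_size)
    ib_auc = np.empty(ens.r)
    oob_auc = np.full(ens.r, np.nan)
    roc_ib = np.empty((ens.r, grid_size))
    roc_oob = np.full((ens.r, grid_size), np.nan)
    for b in range(ens.r):
        ib, oob = ens.ib_indices[b], ens.oob_indices[b]
        ib_auc[b] = auc(y[ib], ens.yhat[b, ib])
        roc_ib[b] = _roc_on_grid(y[ib], ens.yhat[b, ib], grid)
        if np.unique(y[oob]).size == 2:
            oob_auc[b] = auc(y[oob], ens.yhat[b, oob])
            roc_oob[b] = _roc_on_grid(y[oob], ens.yhat[b, oob], grid)

    y_ref = ens.reference.predict(ens.reference.model.X)[1]
    apparent = auc(y, y_ref)
    jk = _jackknife_auc(y, y_ref)
    ok = np.isfinite(oob_auc)
    # the in-bag replicates estimate apparent performance, so they are
    # bias-corrected against the full-data apparent AUC; no full-data
    # out-of-sample statistic exists, so the OOB interval is centred on the
    # replicate median (z0 ~ 0, i.e. near-percentile)
    return EvaluationSummary(
        ib_auc=ib_auc,
        oob_auc=oob_auc[ok],
        ib_auc_ci=bca_interval(ib_auc, apparent, alpha, jackknife=jk),
        oob_auc_ci=bca_interval(oob_auc[ok], float(np.median(oob_auc[ok])),
                                alpha),
        ib_auc_median=float(np.median(ib_auc)),
        oob_auc_median=float(np.median(oob_auc[ok])),
        roc_grid=grid,
        roc_ib_band=np.nanpercentile(roc_ib, [2.5, 97.5], axis=0),
        roc_oob_band=np.nanpercentile(roc_oob, [2.5, 97.5], axis=0),
        roc_reference=_roc_on_grid(
            y, ens.reference.predict(ens.reference.model.X)[1], grid
        ),
    )


def confidence_ellipse(points, kind="population", coverage=0.95):
    """95% ellipse of 2-D points: (centre, semi-axes, angle in radians).

    ``kind="population"`` scales the sample covariance by the chi-squared
    (2 df) quantile; ``kind="mean"`` additionally divides the covariance by
    n, giving the confidence region of the class mean.
    """
    pts = np.asarray(points, float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for an ellipse")
    centre = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if kind == "mean":
        cov = cov / pts.shape[0]
    elif kind != "population":
        raise ValueError(f"unknown ellipse kind {kind!r}")
    evals, evecs = np.linalg.eigh(cov)
    c2 = stats.chi2.ppf(coverage, df=2)
    semi_axes = np.sqrt(np.maximum(evals, 0) * c2)[::-1]     # major first
    angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
    return centre, semi_axes, angle


@dataclass
class ProjectionSummary:
    agg_ib_scores: np.ndarray          # N x K mean in-bag projection
    agg_oob_scores: np.ndarray         # N x K mean out-of-bag (NaN if never OOB)
    never_oob: np.ndarray
    ellipses: dict                     # (d1, d2) -> class -> kind -> ellipse


def aggregate_projection(ens: BootstrapEnsemble) -> ProjectionSummary:
    """Per-sample aggregate in-bag/out-of-bag scores with class ellipses.

    A sample's aggregate score is its projection averaged over the resamples
    in which it was in-bag (respectively out-of-bag).  For every pairwise
    dimension combination and class, a 95% mean ellipse and a 95% population
    ellipse are fitted to the aggregate out-of-bag and in-bag scores.
    Samples never out-of-bag get a missing aggregate OOB score and are
    excluded from ellipse fitting.
    """
    ib, oob = ens.membership()
    k = ens.n_components

    def masked_mean(mask):
        w = mask[:, :, None].astype(float)
        tot = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, (ens.scores * w).sum(axis=0) / tot, np.nan)

    agg_ib = masked_mean(ib)
    agg_oob = masked_mean(oob)

    ellipses = {}
    for d1 in range(k):
        for d2 in range(d1 + 1, k):
            per_pair = {}
            for cls in (0, 1):
                sel = ens.y == cls
                per_pair[cls] = {}
                for split, scores in (("ib", agg_ib), ("oob", agg_oob)):
                    pts = scores[sel][:, [d1, d2]]
                    per_pair[cls][split] = {
                        kind: confidence_ellipse(pts, kind)
                        for kind in ("mean", "population")
                    }
            ellipses[(d1, d2)] = per_pair
    return ProjectionSummary(
        agg_ib_scores=agg_ib,
        agg_oob_scores=agg_oob,
        never_oob=ens.never_oob(),
        ellipses=ellipses,
    )


def contribution_intervals(ens: BootstrapEnsemble, metric_name: str,
                           alpha=0.05, method="bca",
                           metabolite_names=None) -> ContributionTable:
    """Median and 95% CI of a contribution metric across the ensemble.

    ``method`` is "bca" (bias-corrected, acceleration 0 -- leave-one-out
    refits for every metabolite are not attempted) or "percentile".
    Significance follows the metric's rule: signed metrics when the CI
    excludes zero, VIP when the lower bound exceeds 1, Garson when it
    exceeds K/M.
    """
    if metric_name not in ens.contributions:
        raise ValueError(
            f"metric {metric_name!r} not stored for family {ens.family!r}"
        )
    reps = ens.contributions[metric_name]          # r x M
    observed = compute_metric(metric_name, ens.reference)
    m = reps.shape[1]
    lows = np.empty(m)
    highs = np.empty(m)
    for i in range(m):
        if method == "bca":
            lows[i], highs[i] = bca_interval(reps[:, i], observed[i], alpha)
        elif method == "percentile":
            lows[i], highs[i] = percentile_interval(reps[:, i], alpha)
        else:
            raise ValueError(f"unknown CI method {method!r}")
    threshold = importance_threshold(metric_name, m, ens.n_components)
    if metabolite_names is None:
        metabolite_names = [f"M{i + 1:03d}" for i in range(m)]
    return ContributionTable(
        metric_name=metric_name,
        metabolite_names=list(metabolite_names),
        values=np.median(reps, axis=0),
        ci_low=lows,
        ci_high=highs,
        threshold=threshold,
        significant=significance_flags(metric_name, lows, highs, threshold),
    )
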