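"""Static figures for the workflow and end-to-end orchestration.

All figures are written as SVG/PNG via matplotlib.  Every number that
appears on a figure is also written to a machine-readable CSV/JSON file by
``run_workflow``; figures are presentation only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse as MplEllipse

from . import dataio, preprocess, synthgen
from .base import fit_model
from .bootstrap_infer import (
    aggregate_evaluation,
    aggregate_projection,
    bootstrap_models,
    contribution_intervals,
    percentile_interval,
)
from .contribution import METRICS_ANN, METRICS_PLS
from .validate import auc, cv_search, expand_grid, permutation_test, select_hyperparameters

logger = logging.getLogger(__name__)

_CLASS_COLOURS = {0: "tab:red", 1: "tab:blue"}


class WorkflowError(RuntimeError):
    pass


def plot_optimisation(cvgrid, selection, path_prefix):
    """The two hyperparameter-optimisation figures.

    (i) R2/Q2 (and AUC_full/AUC_cv) against the hyperparameter values and
    (ii) the |R2-Q2| vs Q2 plot with the outer convex hull and the selected
    point marked.  Returns the two file paths written.
    """
    t = cvgrid.table
    hyper_cols = [c for c in t.columns if c in cvgrid.grid[0]]
    x = np.arange(len(t))
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (a_col, b_col) in zip(axes, (("R2_full", "Q2_cv"),
                                         ("AUC_full", "AUC_cv"))):
        ax.plot(x, t[a_col], "o-", label=a_col)
        ax.plot(x, t[b_col], "s--", label=b_col)
        ax.axvline(selection.index, color="red", alpha=0.4)
        ax.set_xticks(x)
        ax.set_xticklabels(
            ["/".join(str(t[c][i]) for c in hyper_cols) for i in x],
            rotation=45, fontsize=7,
        )
        ax.set_xlabel(" / ".join(hyper_cols))
        ax.legend(fontsize=8)
    fig.tight_layout()
    p1 = f"{path_prefix}_metrics.svg"
    fig.savefig(p1)
    plt.close(fig)

    d = selection.diagnostics
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(d["gap"], d["Q2_cv"], "o", color="gray")
    hull = selection.hull_indices
    ax.plot(d["gap"][hull], d["Q2_cv"][hull], "-", color="black", alpha=0.6)
    ax.plot(d["gap"][selection.index], d["Q2_cv"][selection.index], "o",
            color="red", ms=10, mfc="none", label="selected")
    ax.set_xlabel("|R2 - Q2|")
    ax.set_ylabel("Q2")
    ax.legend()
    fig.tight_layout()
    p2 = f"{path_prefix}_hull.svg"
    fig.savefig(p2)
    plt.close(fig)
    return [p1, p2]


def plot_evaluation(y_train, yhat_train, y_test=None, yhat_test=None,
                    evaluation=None, path_prefix="evaluation"):
    """Violin, probability-density and ROC figures of predicted scores.

    With an ``EvaluationSummary`` the ROC panel adds the 95% in-bag and
    out-of-bag bands.  Returns the file path written.
    """
    from scipy.stats import gaussian_kde
    from sklearn.metrics import roc_curve

    groups = [("train", y_train, yhat_train)]
    if y_test is not None:
        groups.append(("test", y_test, yhat_test))
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))

    data, labels = [], []
    for name, yy, ss in groups:
        for cls in (0, 1):
            data.append(np.asarray(ss)[np.asarray(yy) == cls])
            labels.append(f"{name}\nclass {cls}")
    axes[0].violinplot(data, showmedians=True)
    axes[0].set_xticks(range(1, len(labels) + 1))
    axes[0].set_xticklabels(labels, fontsize=7)
    axes[0].set_ylabel("predicted score")

    xs = np.linspace(
        min(np.min(d) for d in data) - 0.2, max(np.max(d) for d in data) + 0.2, 200
    )
    for (name, yy, ss) in groups:
        for cls in (0, 1):
            vals = np.asarray(ss)[np.asarray(yy) == cls]
            if np.ptp(vals) > 0:
                axes[1].plot(xs, gaussian_kde(vals)(xs),
                             color=_CLASS_COLOURS[cls],
                             ls="-" if name == "train" else "--",
                             label=f"{name} class {cls}")
    axes[1].set_xlabel("predicted score")
    axes[1].set_ylabel("density")
    axes[1].legend(fontsize=7)

    for name, yy, ss in groups:
        fpr, tpr, _ = roc_curve(yy, ss)
        axes[2].plot(fpr, tpr, label=f"{name} AUC={auc(yy, ss):.2f}")
    if evaluation is not None:
        axes[2].fill_between(evaluation.roc_grid, *evaluation.roc_ib_band,
                             alpha=0.2, color="green", label="IB 95% band")
        axes[2].fill_between(evaluation.roc_grid, *evaluation.roc_oob_band,
                             alpha=0.2, color="orange", label="OOB 95% band")
    axes[2].plot([0, 1], [0, 1], ":", color="gray")
    axes[2].set_xlabel("1 - specificity")
    axes[2].set_ylabel("sensitivity")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    path = f"{path_prefix}.svg"
    fig.savefig(path)
    plt.close(fig)
    return [path]


def _draw_ellipse(ax, ellipse, colour, ls):
    centre, semi, angle = ellipse
    ax.add_patch(
        MplEllipse(centre, 2 * semi[0], 2 * semi[1],
                   angle=np.degrees(angle), fill=False, color=colour, ls=ls)
    )


def plot_projection(projection, y, path_prefix="projection"):
    """Pairwise aggregate scores plots with mean and population ellipses.

    One figure per dimension pair with in-bag, out-of-bag, and overlay
    panels.  A model with a single projection dimension yields no pairwise
    plot.  Returns the file paths written.
    """
    paths = []
    for (d1, d2), per_class in projection.ellipses.items():
        fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharex=True, sharey=True)
        panels = [("IB", [("ib", "-")]), ("OOB", [("oob", "--")]),
                  ("IB + OOB", [("ib", "-"), ("oob", "--")])]
        for ax, (title, splits) in zip(axes, panels):
            for split, ls in splits:
                scores = (projection.agg_ib_scores if split == "ib"
                          else projection.agg_oob_scores)
                for cls in (0, 1):
                    pts = scores[np.asarray(y) == cls][:, [d1, d2]]
                    ax.plot(pts[:, 0], pts[:, 1], "o", ms=4, alpha=0.6,
                            color=_CLASS_COLOURS[cls])
                    for kind in ("mean", "population"):
                        _draw_ellipse(ax, per_class[cls][split][kind],
                                      _CLASS_COLOURS[cls], ls)
            ax.set_title(title, fontsize=9)
            ax.set_xlabel(f"dimension {d1 + 1}")
        axes[0].set_ylabel(f"dimension {d2 + 1}")
        fig.tight_layout()
        p = f"{path_prefix}_{d1 + 1}v{d2 + 1}.svg"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_weights(ens, alpha=0.05, path_prefix="weights"):
    """Per-dimension input-weight plots with bootstrap 95% CIs.

    Weights whose CI crosses zero are coloured blue (non-significant to the
    latent variable / neuron), the rest red.  Returns the file paths.
    """
    r, m, k = ens.weights.shape
    paths = []
    for comp in range(k):
        w = ens.weights[:, :, comp]
        med = np.median(w, axis=0)
        ci = np.array([percentile_interval(w[:, i], alpha) for i in range(m)])
        crosses = (ci[:, 0] <= 0) & (ci[:, 1] >= 0)
        fig, ax = plt.subplots(figsize=(max(6, m * 0.15), 3.5))
        xs = np.arange(m)
        colours = np.where(crosses, "tab:blue", "tab:red")
        # BCa intervals need not bracket the median; clip bar arms at zero
        yerr = np.clip([med - ci[:, 0], ci[:, 1] - med], 0, None)
        ax.errorbar(xs, med, yerr=yerr, fmt="none", ecolor="gray", alpha=0.5)
        ax.scatter(xs, med, c=colours, s=12)
        ax.axhline(0, color="black", lw=0.5)
        ax.set_xlabel("metabolite")
        ax.set_ylabel(f"weight, dimension {comp + 1}")
        fig.tight_layout()
        p = f"{path_prefix}_dim{comp + 1}.svg"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_contributions(tables, path_prefix="contribution"):
    """Median contribution with 95% CIs per metric; significant in red."""
    paths = []
    for name, tab in tables.items():
        m = len(tab.values)
        fig, ax = plt.subplots(figsize=(max(6, m * 0.15), 3.5))
        xs = np.arange(m)
        colours = np.where(np.asarray(tab.significant), "tab:red", "tab:blue")
        yerr = np.clip([tab.values - tab.ci_low, tab.ci_high - tab.values],
                       0, None)
        ax.errorbar(xs, tab.values, yerr=yerr, fmt="none", ecolor="gray",
                    alpha=0.5)
        ax.scatter(xs, tab.values, c=colours, s=12)
        ax.axhline(tab.threshold, color="black", lw=0.7, ls="--")
        ax.set_xlabel("metabolite")
        ax.set_ylabel(name)
        fig.tight_layout()
        p = f"{path_prefix}_{name}.svg"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths


@dataclass
class RunManifest:
    config: dict
    data_hash: str
    chosen_hyper: dict
    outputs: list = field(default_factory=list)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "data_hash": self.data_hash,
                    "chosen_hyperparameters": self.chosen_hyper,
                    "outputs": self.outputs,
                },
                fh, indent=2, default=str,
            )
        return path


DEFAULT_CONFIG = {
    "families": ["pls", "ann"],
    "rsd_max": 20.0,
    "missing_max": 10.0,
    "test_fraction": 1 / 3,
    "knn_k": 3,
    "folds": 5,
    "repartitions": 10,
    "n_permutations": 100,
    "n_bootstrap": 100,
    "pls_grid": {"n_components": [1, 2, 3, 4, 5, 6]},
    "ann_grid": {"n_hidden": [2, 3, 4, 5, 6],
                 "learning_rate": [0.001, 0.01, 0.03, 0.1, 0.3, 1.0]},
    "seed": 0,
}


def run_workflow(config: dict, outdir: str) -> RunManifest:
    """End-to-end pipeline: prepare -> optimise -> permute -> test-set
    evaluate -> bootstrap evaluate -> visualise -> contribution tables.

    ``config`` overrides entries of ``DEFAULT_CONFIG``; the input table
    comes from ``config["peak_table"]`` (a path) or ``config["synth"]``
    (keyword arguments for the synthetic generator).  Any stage failure
    aborts with an error naming the stage.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config=cfg, data_hash="", chosen_hyper={})

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise WorkflowError(f"stage {name!r} failed: {exc}") from exc

    # -- prepare ----------------------------------------------------------
    if "peak_table" in cfg:
        pt = stage("load", dataio.read_peak_table, cfg["peak_table"],
                   positive_class=cfg.get("positive_class"))
    elif "synth" in cfg:
        def _gen():
            return synthgen.generate(synthgen.SynthSpec(**cfg["synth"]))[0]

        pt = stage("generate", _gen)
    else:
        raise WorkflowError("stage 'prepare' failed: no peak_table or synth config")
    manifest.data_hash = hashlib.sha256(
        np.ascontiguousarray(np.nan_to_num(pt.X)).tobytes()
    ).hexdigest()[:16]

    pt = stage("clean", preprocess.clean_features, pt, cfg["rsd_max"],
               cfg["missing_max"])
    split = stage("split", preprocess.stratified_split, pt,
                  cfg["test_fraction"], cfg["seed"])
    X_train_raw = pt.X[split.train_idx]
    X_test_raw = pt.X[split.test_idx]
    y_train = pt.class_labels[split.train_idx].astype(float)
    y_test = pt.class_labels[split.test_idx].astype(float)
    X_train, params = stage("scale", preprocess.fit_transform_train, X_train_raw)
    X_test = stage("scale", preprocess.transform_test, X_test_raw, params)
    X_train = stage("impute", preprocess.knn_impute, X_train, cfg["knn_k"])
    X_test = stage("impute", preprocess.knn_impute, X_test, cfg["knn_k"])

    summary_rows = {}
    for family in cfg["families"]:
        grid = expand_grid(**cfg[f"{family}_grid"])
        cvgrid = stage("optimise", cv_search, X_train, y_train, family, grid,
                       cfg["folds"], cfg["repartitions"], cfg["seed"])
        selection = stage("select", select_hyperparameters, cvgrid)
        manifest.chosen_hyper[family] = selection.params
        cv_path = os.path.join(outdir, f"{family}_cvgrid.csv")
        cvgrid.table.to_csv(cv_path, index=False)
        manifest.outputs.append(cv_path)
        manifest.outputs += stage(
            "plot_optimisation", plot_optimisation, cvgrid, selection,
            os.path.join(outdir, f"{family}_optimisation"))

        perm = None
        if cfg["n_permutations"] > 0:
            perm = stage("permute", permutation_test, X_train, y_train, family,
                         selection.params, cfg["n_permutations"], cfg["folds"],
                         cfg["seed"])
            perm_path = os.path.join(outdir, f"{family}_permutation.csv")
            perm.null.assign(kind="null").to_csv(perm_path, index=False)
            manifest.outputs.append(perm_path)

        final = stage("final_fit", fit_model, family, X_train, y_train,
                      selection.params, cfg["seed"])
        yhat_train = final.predict(X_train)[1]
        yhat_test = final.predict(X_test)[1]

        ens = stage("bootstrap", bootstrap_models, X_train, y_train, family,
                    selection.params, cfg["n_bootstrap"], cfg["seed"])
        evaluation = stage("evaluate", aggregate_evaluation, ens)
        projection = stage("project", aggregate_projection, ens)

        manifest.outputs += stage(
            "plot_evaluation", plot_evaluation, y_train, yhat_train, y_test,
            yhat_test, evaluation, os.path.join(outdir, f"{family}_evaluation"))
        manifest.outputs += stage(
            "plot_projection", plot_projection, projection, y_train,
            os.path.join(outdir, f"{family}_projection"))
        manifest.outputs += stage(
            "plot_weights", plot_weights, ens,
            path_prefix=os.path.join(outdir, f"{family}_weights"))

        metrics = METRICS_PLS if family == "pls" else METRICS_ANN
        tables = {
            m: stage("contribution", contribution_intervals, ens, m,
                     metabolite_names=pt.metabolite_names)
            for m in metrics
        }
        manifest.outputs += stage(
            "plot_contribution", plot_contributions, tables,
            os.path.join(outdir, f"{family}_contribution"))

        summary_rows.update({
            f"{family}_auc_train": auc(y_train, yhat_train),
            f"{family}_auc_test": auc(y_test, yhat_test),
            f"{family}_auc_ib_low": evaluation.ib_auc_ci[0],
            f"{family}_auc_ib_high": evaluation.ib_auc_ci[1],
            f"{family}_auc_oob_low": evaluation.oob_auc_ci[0],
            f"{family}_auc_oob_high": evaluation.oob_auc_ci[1],
            f"{family}_q2_cv": float(cvgrid.table["Q2_cv"][selection.index]),
            f"{family}_perm_p_q2": (perm.pvalues["Q2_cv"]
                                    if perm is not None else np.nan),
            f"{family}_n_significant_signed": int(
                np.sum(tables[metrics[0]].significant)),
        })
        manifest.outputs += stage(
            "write_results", dataio.write_results, tables, None,
            os.path.join(outdir, f"{family}_results"))

    eval_path = os.path.join(outdir, "evaluation_summary.csv")
    pd.DataFrame([summary_rows]).to_csv(eval_path, index=False)
    manifest.outputs.append(eval_path)
    manifest_path = os.path.join(outdir, "manifest.json")
    manifest.save(manifest_path)
    manifest.outputs.append(manifest_path)
    return manifest
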