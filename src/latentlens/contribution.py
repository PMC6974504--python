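"""Per-metabolite feature-contribution metrics for the two model families.

PLS-DA contributes two metrics: the signed regression coefficients B (the
model collapsed to a single linear regression) and the variable influence on
projection (VIP), the weight-squared combination of the Y sum of squares
explained by each latent variable, normalised so that the squared VIPs sum
to the number of variables -- a variable contributing averagely scores
exactly 1, the conventional importance cut-off.

The network analogues are the Connection Weight Approach (CWA), the signed
product-sum of input-hidden and hidden-output weights (identical in form to
composing a linear network into regression coefficients), and Garson's
algorithm, which normalises absolute connection weights within each hidden
neuron and sums across neurons; the Garson vector sums to K, so its mean
K/M serves as the importance cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import NeuralNetResults
from .pls import PLSDAResults

METRICS_PLS = ("B_PLS", "VIP")
METRICS_ANN = ("CWA", "Garson")
ALL_METRICS = METRICS_PLS + METRICS_ANN
SIGNED_METRICS = ("B_PLS", "CWA")


@dataclass
class ContributionTable:
    """Aggregated per-metabolite contribution metric with 95% CIs."""

    metric_name: str
    metabolite_names: list
    values: np.ndarray       # median over bootstrap resamples (or point value)
    ci_low: np.ndarray
    ci_high: np.ndarray
    threshold: float
    significant: np.ndarray


def coefficient_scores(res: PLSDAResults) -> np.ndarray:
    """Signed PLS regression coefficients B = W C'."""
    return res.coef.copy()


def vip_scores(res: PLSDAResults) -> np.ndarray:
    """Variable influence on projection.

    VIP_i = sqrt(M * sum_k w_ik^2 SSY_k / SSY_cum) with the weight columns
    normalised to unit length and SSY_k the Y sum of squares explained by
    latent variable k.  This normalisation makes sum(VIP^2) = M identically.
    """
    W = res.x_weights
    m = W.shape[0]
    ssy = res.y_ss_per_component
    ssy_cum = ssy.sum()
    if ssy_cum <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    Wn = W / np.linalg.norm(W, axis=0)
    return np.sqrt(m * (Wn**2 @ ssy) / ssy_cum)


def cwa_scores(res: NeuralNetResults) -> np.ndarray:
    """Connection Weight Approach: CWA_i = sum_j c_j w_ij (signed)."""
    return res.W1 @ res.w2


def garson_scores(res: NeuralNetResults) -> np.ndarray:
    """Garson's algorithm: per-neuron-normalised absolute connection weights.

    GA_i = sum_j |w_ij c_j| / sum_i' |w_i'j c_j|; the result is non-negative
    and sums exactly to the number of hidden neurons K.
    """
    abs_cwa = np.abs(res.W1 * res.w2)          # M x K, |w_ij * c_j|
    totals = abs_cwa.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError(
            "a hidden neuron has zero total connection weight; "
            "Garson normalisation is undefined"
        )
    return (abs_cwa / totals).sum(axis=1)


def importance_threshold(metric_name: str, n_metabolites: int,
                         n_components: int) -> float:
    """Reference line above (or about) which a variable is called important.

    VIP uses the conventional cut-off 1; Garson uses its mean K/M; the signed
    metrics use 0 -- their significance is decided by whether the bootstrap
    CI excludes zero.
    """
    if metric_name == "VIP":
        return 1.0
    if metric_name == "Garson":
        return n_components / n_metabolites
    if metric_name in SIGNED_METRICS:
        return 0.0
    raise ValueError(f"unknown metric {metric_name!r}")


def compute_metric(metric_name: str, res) -> np.ndarray:
    """Dispatch a metric name to the matching fitted-results object."""
    funcs = {
        "B_PLS": coefficient_scores,
        "VIP": vip_scores,
        "CWA": cwa_scores,
        "Garson": garson_scores,
    }
    if metric_name not in funcs:
        raise ValueError(f"unknown metric {metric_name!r}")
    return funcs[metric_name](res)


def significance_flags(metric_name: str, ci_low, ci_high, threshold: float
                       ) -> np.ndarray:
    """Apply the per-metric significance rule to 95% CI bounds.

    Signed metrics (B_PLS, CWA) are significant when the CI excludes zero;
    VIP when the lower bound exceeds 1; Garson when the lower bound exceeds
    K/M.
    """
    ci_low = np.asarray(ci_low, float)
    ci_high = np.asarray(ci_high, float)
    if metric_name in SIGNED_METRICS:
        return (ci_low > 0) | (ci_high < 0)
    return ci_low > threshold
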