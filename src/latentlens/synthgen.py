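"""Synthetic two-class metabolomics peak tables with known ground truth.

Concentrations follow a log-scale latent-factor model: each metabolite's
log-abundance is a baseline plus a low-rank shared-factor term (inducing the
correlated blocks typical of co-regulated metabolites) plus independent
noise.  A chosen subset of metabolites carries a class-mean shift expressed
in units of that metabolite's marginal log-scale standard deviation, so
``effect_size`` is directly a standardised effect.  Exponentiation keeps all
concentrations strictly positive and log-transform safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .dataio import PeakTable


@dataclass
class SynthSpec:
    """Parameters of the synthetic peak-table generator.

    Defaults describe a moderately powered two-class study: 50 samples per
    class, 52 metabolites (the size of a typical cleaned NMR panel) of which
    5 discriminate the classes at 2 standardised log-units, rank-2 shared
    covariance, and no missing data unless requested.
    """

    n_per_class: Tuple[int, int] = (50, 50)
    n_metabolites: int = 52
    n_informative: int = 5
    effect_size: float = 2.0       # class shift, in marginal log-SD units
    latent_rank: int = 2
    factor_scale: float = 0.7      # loading SD of the shared factors
    noise_sd: float = 1.0          # independent log-scale noise SD
    missing_rate: float = 0.0
    missing_mode: str = "mcar"     # "mcar" or "censor" (left-censored)
    qc_rsd_range: Tuple[float, float] = (2.0, 15.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_metabolites:
            raise ValueError("n_informative exceeds n_metabolites")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.missing_mode not in ("mcar", "censor"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if min(self.n_per_class) < 2:
            raise ValueError("need at least 2 samples per class")


@dataclass
class GroundTruth:
    informative_idx: np.ndarray     # indices of the discriminating metabolites
    log_shift: np.ndarray           # per-metabolite class-1 shift on log scale
    loadings: np.ndarray            # M x latent_rank factor loadings
    marginal_log_sd: np.ndarray     # per-metabolite log-scale SD


def generate(spec: SynthSpec) -> Tuple[PeakTable, GroundTruth]:
    """Draw one peak table from the generative model described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_class
    n, m, r = n0 + n1, spec.n_metabolites, spec.latent_rank

    baseline = rng.uniform(2.0, 6.0, m)
    loadings = rng.normal(0.0, spec.factor_scale, (m, r))
    marginal_sd = np.sqrt((loadings**2).sum(axis=1) + spec.noise_sd**2)

    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    factors = rng.normal(0.0, 1.0, (n, r))
    eps = rng.normal(0.0, spec.noise_sd, (n, m))
    logz = baseline + factors @ loadings.T + eps

    informative = rng.choice(m, spec.n_informative, replace=False)
    informative.sort()
    shift = np.zeros(m)
    shift[informative] = spec.effect_size * marginal_sd[informative]
    logz[y == 1] += shift

    x = np.exp(logz)
    if spec.missing_rate > 0:
        if spec.missing_mode == "mcar":
            mask = rng.random((n, m)) < spec.missing_rate
        else:
            # left-censor: the lowest-intensity fraction of each metabolite
            # is lost, emulating abundance-dependent missingness
            thresh = np.quantile(x, spec.missing_rate, axis=0)
            mask = x < thresh
        # never blank out a whole sample or metabolite
        for axis, size in ((1, n), (0, m)):
            full = mask.all(axis=axis)
            if full.any():
                idx = np.nonzero(full)[0]
                if axis == 1:
                    mask[idx, rng.integers(0, m, idx.size)] = False
                else:
                    mask[rng.integers(0, n, idx.size), idx] = False
        x = np.where(mask, np.nan, x)

    pt = PeakTable(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        class_labels=y,
        X=x,
        metabolite_names=[f"M{j + 1:03d}" for j in range(m)],
        qc_rsd=rng.uniform(*spec.qc_rsd_range, m),
        perc_missing=100.0 * np.isnan(x).mean(axis=0),
    )
    truth = GroundTruth(
        informative_idx=informative,
        log_shift=shift,
        loadings=loadings,
        marginal_log_sd=marginal_sd,
    )
    return pt, truth
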