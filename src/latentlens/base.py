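"""Shared model-family dispatch.

Both model families satisfy the same projection contract: ``fit`` on a
scaled (X, y) returns a results object exposing ``x_weights`` (M x K
input-side weight columns), ``scores`` (N x K training projections),
``predict(X) -> (scores, y_star)`` and ``n_components``.
"""

from __future__ import annotations

from .ann import NeuralNet
from .pls import PLSDA

FAMILIES = ("pls", "ann")


def fit_model(family: str, X, y, hyper: dict, seed: int = 0):
    """Fit one model of the given family with the given hyperparameters.

    ``hyper`` for "pls" holds ``n_components``; for "ann" any of
    ``n_hidden``, ``learning_rate``, ``momentum``, ``decay``, ``epochs``,
    ``loss``.  ``seed`` only affects the (stochastic) network fit.
    """
    if family == "pls":
        return PLSDA(X, y, **hyper).fit()
    if family == "ann":
        return NeuralNet(X, y, seed=seed, **hyper).fit()
    raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
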