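"""Two-layer feed-forward neural network trained by back-propagation.

The network has one hidden layer of K neurons and a single output neuron,
logistic activations in both layers by default.  Each hidden neuron computes
t_j = f(w_0j + x'w_j), a weighted sum of the inputs through an activation f
-- with logistic f this is exactly a multivariate logistic regression, and
with linear activations the whole network collapses to a multiple linear
regression, making the hidden layer a learned projection directly comparable
to PLS latent variables.  The "neuron scores" exposed for visualisation are
the pre-activation weighted sums, the analogue of PLS projection scores.

Training is full-batch gradient descent with classical momentum and an
optional hyperbolic learning-rate decay lr_t = lr / (1 + decay * epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _logistic(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def loss_and_gradients(W1, b1, w2, b2, X, y, loss="cross_entropy",
                       activation="logistic"):
    """Loss and analytic gradients of the two-layer network.

    Returns ``(loss_value, (gW1, gb1, gw2, gb2))``.  Kept as a standalone
    function so the back-propagation gradient can be verified against finite
    differences independently of the training loop.
    """
    n = X.shape[0]
    z1 = X @ W1 + b1
    if activation == "logistic":
        h = _logistic(z1)
        dh = h * (1.0 - h)
    elif activation == "linear":
        h = z1
        dh = np.ones_like(z1)
    else:
        raise ValueError(f"unknown activation {activation!r}")
    z2 = h @ w2 + b2

    if activation == "logistic":
        p = _logistic(z2)
    else:
        p = z2

    if loss == "cross_entropy":
        if activation != "logistic":
            raise ValueError("cross_entropy requires a logistic output")
        eps = 1e-12
        value = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        d2 = (p - y) / n                    # logistic + CE: gradient wrt z2
    elif loss == "mse":
        value = np.mean((p - y) ** 2)
        d2 = 2.0 * (p - y) / n
        if activation == "logistic":
            d2 = d2 * p * (1.0 - p)
    else:
        raise ValueError(f"unknown loss {loss!r}")

    gw2 = h.T @ d2
    gb2 = d2.sum()
    d1 = np.outer(d2, w2) * dh
    gW1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return value, (gW1, gb1, gw2, gb2)


class NeuralNet:
    """Model specification for the two-layer classifier.

    Parameters
    ----------
    X, y : training matrix (complete, scaled) and binary labels in {0, 1}.
    n_hidden : number of hidden neurons K.
    learning_rate : gradient-descent step size (> 0).
    momentum, decay, epochs : remaining training hyperparameters; the
        defaults 0.5, 0 and 400 are fixed working values for peak-table
        classification, leaving K and the learning rate as the ones to tune.
    loss : "cross_entropy" (default) or "mse".
    activation : "logistic" (default) or "linear" for the regression-
        equivalent network.
    seed : controls weight initialisation; fits are bit-reproducible.
    """

    def __init__(self, X, y, n_hidden: int = 2, learning_rate: float = 0.03,
                 momentum: float = 0.5, decay: float = 0.0, epochs: int = 400,
                 loss: str = "cross_entropy", activation: str = "logistic",
                 seed: int = 0):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be 2-D with one y label per row")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; impute before fitting")
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.decay = decay
        self.epochs = epochs
        self.loss = loss
        self.activation = activation
        self.seed = seed

    def _init_weights(self, rng):
        m, k = self.X.shape[1], self.n_hidden
        lim1 = np.sqrt(6.0 / (m + k))
        lim2 = np.sqrt(6.0 / (k + 1))
        return (rng.uniform(-lim1, lim1, (m, k)), np.zeros(k),
                rng.uniform(-lim2, lim2, k), 0.0)

    def fit(self) -> "NeuralNetResults":
        rng = np.random.default_rng(self.seed)
        W1, b1, w2, b2 = self._init_weights(rng)
        vW1 = np.zeros_like(W1)
        vb1 = np.zeros_like(b1)
        vw2 = np.zeros_like(w2)
        vb2 = 0.0
        curve = np.empty(self.epochs)
        for epoch in range(self.epochs):
            value, (gW1, gb1, gw2, gb2) = loss_and_gradients(
                W1, b1, w2, b2, self.X, self.y, self.loss, self.activation
            )
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss not finite); "
                    f"try a smaller learning rate than {self.learning_rate}"
                )
            curve[epoch] = value
            lr = self.learning_rate / (1.0 + self.decay * epoch)
            vW1 = self.momentum * vW1 - lr * gW1
            vb1 = self.momentum * vb1 - lr * gb1
            vw2 = self.momentum * vw2 - lr * gw2
            vb2 = self.momentum * vb2 - lr * gb2
            W1 = W1 + vW1
            b1 = b1 + vb1
            w2 = w2 + vw2
            b2 = b2 + vb2
        if not all(np.all(np.isfinite(a)) for a in (W1, b1, w2, [b2])):
            raise RuntimeError(
                f"training diverged (non-finite weights after {self.epochs} "
                f"epochs); try a smaller learning rate than {self.learning_rate}"
            )
        W1, b1, w2, b2 = self._canonicalise(W1, b1, w2, b2)
        return NeuralNetResults(model=self, W1=W1, b1=b1, w2=w2, b2=float(b2),
                                loss_curve=curve)

    def _canonicalise(self, W1, b1, w2, b2):
        """Order neurons by descending |w2| and orient each so w2 >= 0.

        Hidden neurons are exchangeable and sign-symmetric, so the network
        function is preserved: for a logistic hidden unit, sigma(-z) =
        1 - sigma(z), hence negating (w_j, b_j, c_j) and adding the old c_j
        to the output offset leaves every prediction unchanged.
        """
        order = np.argsort(-np.abs(w2), kind="stable")
        W1, b1, w2 = W1[:, order], b1[order], w2[order]
        for j in np.nonzero(w2 < 0)[0]:
            if self.activation == "logistic":
                b2 = b2 + w2[j]
            W1[:, j] = -W1[:, j]
            b1[j] = -b1[j]
            w2[j] = -w2[j]
        return W1, b1, w2, b2


@dataclass
class NeuralNetResults:
    """Fitted network weights and prediction/projection interface."""

    model: NeuralNet
    W1: np.ndarray          # M x K input-to-hidden weights
    b1: np.ndarray          # K hidden offsets
    w2: np.ndarray          # K hidden-to-output weights (non-negative)
    b2: float
    loss_curve: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W1.shape[1]

    # the visualisation contract shared with PLS: projection scores are the
    # hidden pre-activations, input-side weights are the W1 columns
    @property
    def x_weights(self) -> np.ndarray:
        return self.W1

    @property
    def scores(self) -> np.ndarray:
        return self.predict(self.model.X)[0]

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)[1]

    def predict(self, X_new):
        """Returns ``(neuron_scores, y_star)``.

        ``neuron_scores`` are the hidden-layer weighted sums *before* the
        activation (the projection analogue of PLS scores); ``y_star`` is
        the output probability, strictly inside (0, 1) for finite input.
        """
        X_new = np.asarray(X_new, float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"expected {self.W1.shape[0]} columns, got {X_new.shape[1]}"
            )
        z1 = X_new @ self.W1 + self.b1
        h = _logistic(z1) if self.model.activation == "logistic" else z1
        z2 = h @ self.w2 + self.b2
        y_star = _logistic(z2) if self.model.activation == "logistic" else z2
        return z1, y_star

    def summary(self) -> str:
        m = self.model
        lines = [
            "Two-layer feed-forward network results",
            "=" * 45,
            f"samples:        {m.X.shape[0]}",
            f"metabolites:    {m.X.shape[1]}",
            f"hidden neurons: {self.n_components}",
            f"learning rate:  {m.learning_rate}  momentum: {m.momentum}"
            f"  decay: {m.decay}  epochs: {m.epochs}",
            f"loss ({m.loss}): {self.loss_curve[-1]:.6f} (final)",
            f"|w2| by neuron: " + ", ".join(f"{v:.4f}" for v in np.abs(self.w2)),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "ann",
            "n_hidden": self.n_components,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "hyper": {
                "learning_rate": self.model.learning_rate,
                "momentum": self.model.momentum,
                "decay": self.model.decay,
                "epochs": self.model.epochs,
                "loss": self.model.loss,
                "seed": self.model.seed,
            },
        }
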