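"""Partial least squares discriminant analysis fitted with SIMPLS.

The model projects an N x M concentration matrix X onto K latent variables
T = XW chosen to maximise covariance with the binary class vector y, then
predicts the class score as y* = TC' = XB with B = WC'.  SIMPLS computes the
weight vectors directly on the successively deflated cross-covariance X'y,
which makes the training score vectors mutually orthogonal.

The class vector is mean-centred internally and the continuous predicted
score is returned un-thresholded; classification metrics such as the AUC
operate on that continuous score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PLSDA:
    """PLS-DA model specification: data plus number of latent variables.

    Parameters
    ----------
    X : ndarray, shape (N, M)
        Complete (imputed), column-scaled training matrix.
    y : ndarray, shape (N,)
        Binary class labels in {0, 1}; centred internally.
    n_components : int
        Number of latent variables K, 1 <= K <= min(N-1, M).
    """

    def __init__(self, X, y, n_components: int = 2):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be 2-D with one y label per row")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; impute before fitting")
        n, m = self.X.shape
        if not 1 <= n_components <= min(n - 1, m):
            raise ValueError(
                f"n_components={n_components} outside [1, {min(n - 1, m)}]"
            )
        self.n_components = n_components

    def fit(self) -> "PLSDAResults":
        """Run SIMPLS and return the fitted results."""
        X, y, K = self.X, self.y, self.n_components
        n, m = X.shape
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xc = X - x_mean
        yc = y - y_mean

        W = np.zeros((m, K))            # x-weights: T = Xc W
        T = np.zeros((n, K))            # orthonormal scores
        P = np.zeros((m, K))            # x-loadings
        C = np.zeros(K)                 # y-weights
        V = np.zeros((m, K))            # orthonormal basis for deflation
        s = Xc.T @ yc                   # cross-covariance, deflated in place
        tol = 1e-12 * max(1.0, np.linalg.norm(Xc.T @ yc))

        for k in range(K):
            r = s.copy()                # univariate y: weight is the deflated X'y
            t = Xc @ r
            t -= t.mean()
            norm_t = np.linalg.norm(t)
            if norm_t <= tol:
                raise np.linalg.LinAlgError(
                    f"residual covariance vanished at component {k + 1}; "
                    f"use a smaller n_components"
                )
            t /= norm_t
            r /= norm_t
            p = Xc.T @ t
            c = float(yc @ t)
            if c < 0:                   # orient each LV so its y-weight is positive
                r, t, p, c = -r, -t, -p, -c
            v = p.copy()
            if k > 0:
                v -= V[:, :k] @ (V[:, :k].T @ p)
            norm_v = np.linalg.norm(v)
            if norm_v <= tol:
                raise np.linalg.LinAlgError(
                    f"deflation basis degenerate at component {k + 1}; "
                    f"use a smaller n_components"
                )
            v /= norm_v
            s = s - v * (v @ s)
            W[:, k], T[:, k], P[:, k], C[k], V[:, k] = r, t, p, c, v

        coef = W @ C
        return PLSDAResults(
            model=self,
            x_weights=W,
            y_weights=C,
            scores=T,
            x_loadings=P,
            coef=coef,
            intercept=float(y_mean - x_mean @ coef),
            x_mean=x_mean,
            y_mean=float(y_mean),
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA model: weights, scores, coefficients, and prediction."""

    model: PLSDA
    x_weights: np.ndarray       # M x K, columns w_k with T = (X - x_mean) W
    y_weights: np.ndarray       # length K, entries c_k (all positive)
    scores: np.ndarray          # N x K orthonormal training scores
    x_loadings: np.ndarray      # M x K
    coef: np.ndarray            # B = W C', length M
    intercept: float
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    @property
    def y_ss_per_component(self) -> np.ndarray:
        """Sum of squares of y explained by each latent variable.

        With orthonormal scores the fitted contribution of component k is
        t_k c_k, so its explained sum of squares is c_k**2.
        """
        return self.y_weights**2

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)[1]

    def predict(self, X_new):
        """Project new samples; returns ``(scores, y_star)``.

        ``scores`` is the N' x K latent projection and ``y_star`` the
        continuous predicted class score X B + intercept.
        """
        X_new = np.asarray(X_new, float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.coef.size:
            raise ValueError(
                f"expected {self.coef.size} columns, got {X_new.shape[1]}"
            )
        scores = (X_new - self.x_mean) @ self.x_weights
        y_star = X_new @ self.coef + self.intercept
        return scores, y_star

    def summary(self) -> str:
        n, m = self.model.X.shape
        yhat = self.fittedvalues
        ss_tot = np.sum((self.model.y - self.model.y.mean()) ** 2)
        r2 = 1.0 - np.sum((self.model.y - yhat) ** 2) / ss_tot
        lines = [
            "PLS-DA (SIMPLS) results",
            "=" * 45,
            f"samples:            {n}",
            f"metabolites:        {m}",
            f"latent variables:   {self.n_components}",
            f"R2 (train):         {r2:.4f}",
            "explained SSY by LV: "
            + ", ".join(f"{v:.4f}" for v in self.y_ss_per_component),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Portable JSON-serialisable form of the fitted parameters."""
        return {
            "kind": "plsda",
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "y_weights": self.y_weights.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
        }
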