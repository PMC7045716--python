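"""Weighted single-hidden-layer multinomial classifier.

A minimal feed-forward network (logistic hidden units, softmax output,
L2 penalty) trained by L-BFGS on a weighted cross-entropy loss.  Sample
weights are first-class because ABC categorical regression weights the
accepted simulations by an Epanechnikov kernel of their distance to the
observation.  Replicate fits with random initial weights are averaged
by the caller.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, softmax


def _unpack(theta, p, h, k):
    i = 0
    W1 = theta[i:i + p * h].reshape(p, h); i += p * h
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + h * k].reshape(h, k); i += h * k
    b2 = theta[i:i + k]
    return W1, b1, W2, b2


class WeightedNNet:
    """Fit with (X, y, sample_weight); predict class probabilities."""

    def __init__(self, n_hidden: int = 4, l2: float = 1e-4,
                 max_iter: int = 150):
        self.n_hidden = n_hidden
        self.l2 = l2
        self.max_iter = max_iter
        self._theta = None
        self.classes_ = None

    def fit(self, X, y, sample_weight=None, rng=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng() if rng is None else rng
        self.classes_, yi = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = self.classes_.size
        h = self.n_hidden
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight,
                                                                dtype=float)
        w = w / w.sum()
        Y = np.zeros((n, k))
        Y[np.arange(n), yi] = 1.0
        lam = self.l2

        def loss_grad(theta):
            W1, b1, W2, b2 = _unpack(theta, p, h, k)
            H = expit(X @ W1 + b1)
            P = softmax(H @ W2 + b2, axis=1)
            ll = -np.sum(w * np.sum(Y * np.log(P + 1e-300), axis=1))
            ll += lam * (np.sum(W1 ** 2) + np.sum(W2 ** 2))
            dZ2 = (P - Y) * w[:, None]
            gW2 = H.T @ dZ2 + 2 * lam * W2
            gb2 = dZ2.sum(axis=0)
            dH = dZ2 @ W2.T * H * (1 - H)
            gW1 = X.T @ dH + 2 * lam * W1
            gb1 = dH.sum(axis=0)
            return ll, np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])

        theta0 = rng.normal(scale=0.5, size=p * h + h + h * k + k)
        res = minimize(loss_grad, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter})
        self._theta = res.x
        self._shape = (p, h, k)
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p, h, k = self._shape
        W1, b1, W2, b2 = _unpack(self._theta, p, h, k)
        H = expit(X @ W1 + b1)
        return softmax(H @ W2 + b2, axis=1)
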