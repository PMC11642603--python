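"""Closed-form binary LDA with Ledoit-Wolf shrinkage.

Implements the least-squares discriminant contract: the pooled
within-class covariance is the prior-weighted average of per-class
Ledoit-Wolf-shrunk covariances (each estimated on standardised features
and rescaled), and the discriminant weights solve ``S w = mu_1 - mu_0``.
Deterministic given input order; written as plain vectorised numpy because
the permutation pipelines perform ~10^5 fits per run.
"""

from __future__ import annotations

import numpy as np


def ledoit_wolf_shrinkage(X: np.ndarray) -> float:
    """Ledoit-Wolf optimal shrinkage intensity toward a scaled identity.

    ``X`` is an (n, p) sample; the data are centered internally.  Returns
    the shrinkage coefficient in [0, 1] minimising expected Frobenius risk
    (Ledoit & Wolf 2004 lemma).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p == 1:
        return 0.0
    X = X - X.mean(axis=0)
    X2 = X**2
    emp_cov_trace = X2.sum(axis=0) / n
    mu = emp_cov_trace.sum() / p
    beta_ = float(np.sum(X2.T @ X2))
    delta_ = float(np.sum((X.T @ X) ** 2)) / n**2
    beta = (beta_ / n - delta_) / (p * n)
    delta = (delta_ - 2.0 * mu * emp_cov_trace.sum() + p * mu**2) / p
    beta = min(beta, delta)
    return 0.0 if beta == 0 else float(beta / delta)


def lw_covariance(X: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf-shrunk covariance on standardised features, rescaled.

    Features are standardised (unit variance) before estimating the
    shrinkage intensity, and the shrunk covariance is mapped back to the
    original scale; zero-variance features keep unit scale.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = np.sqrt((Xc**2).mean(axis=0))
    scale[scale == 0] = 1.0
    Xs = Xc / scale
    s = ledoit_wolf_shrinkage(Xs)
    emp = (Xs.T @ Xs) / n
    mu = np.trace(emp) / p
    shrunk = (1.0 - s) * emp
    shrunk.flat[:: p + 1] += s * mu
    return scale[:, None] * shrunk * scale[None, :]


class ShrinkageLDA:
    """Binary linear discriminant with automatic Ledoit-Wolf shrinkage.

    Equivalent to the least-squares LDA solver with ``shrinkage="auto"``:
    ``coef = S^+ (mu_1 - mu_0)`` with ``S`` the prior-weighted pooled
    shrunk covariance, and intercept ``-(mu_1+mu_0)/2 . coef + log(p1/p0)``.
    """

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {len(classes)}")
        n = len(y)
        means = []
        cov = np.zeros((X.shape[1], X.shape[1]))
        priors = []
        for c in classes:
            Xg = X[y == c]
            if len(Xg) < 2:
                raise ValueError("need >= 2 samples per class")
            prior = len(Xg) / n
            priors.append(prior)
            means.append(Xg.mean(axis=0))
            cov += prior * lw_covariance(Xg)
        m0, m1 = means
        rhs = np.column_stack([m0, m1])
        try:
            sol = np.linalg.solve(cov, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(cov, rhs, rcond=None)[0]
        w0, w1 = sol[:, 0], sol[:, 1]
        self.coef_ = w1 - w0
        self.intercept_ = float(
            (-0.5 * m1 @ w1 + np.log(priors[1]))
            - (-0.5 * m0 @ w0 + np.log(priors[0]))
        )
        self.classes_ = classes
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit first")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        return self.classes_[(d > 0).astype(int)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
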