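"""Second-order Gaussian model-X knockoffs.

A knockoff copy of a feature matrix ``X`` is a synthetic matrix ``X~`` drawn
without looking at the response, constructed so that swapping any original
feature with its knockoff leaves the joint distribution (to second order)
unchanged.  Under a Gaussian working model ``X ~ N(mu, Sigma)`` the knockoffs
are sampled from the conditional normal

    X~ | X  ~  N( X - (X - mu) Sigma^{-1} diag(s),
                  2 diag(s) - diag(s) Sigma^{-1} diag(s) )

where ``s >= 0`` is the decorrelation vector: ``cov(X_j, X~_j) = Sigma_jj -
s_j`` while every cross-feature covariance is preserved.  The knockoffs then
act as per-feature negative controls for any importance measure computed on
the augmented matrix ``[X, X~]``.

The covariance is estimated with Ledoit-Wolf shrinkage toward the identity,
which keeps ``Sigma`` well conditioned when the number of metabolites
approaches the number of samples, and ``s`` is chosen by the equi-correlated
rule ``s_j = min(2 lambda_min(corr(Sigma)), 1)`` on the correlation scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.covariance import LedoitWolf, empirical_covariance
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = ["GaussianKnockoffs", "KnockoffDraws", "equicorrelated_s"]

_PSD_WARN_FRACTION = 1e-8


@dataclass
class KnockoffDraws:
    """B independent knockoff copies of one feature matrix."""

    copies: list[np.ndarray] = field(repr=False)
    seeds: list[int]

    @property
    def B(self) -> int:
        return len(self.copies)


def equicorrelated_s(sigma: np.ndarray) -> np.ndarray:
    """Equi-correlated decorrelation vector on the covariance scale.

    On the correlation scale every feature receives ``min(2 lambda_min, 1)``;
    the result is mapped back through the per-feature variances.
    """
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    lam_min = float(np.linalg.eigvalsh(corr)[0])
    s_corr = max(min(2.0 * lam_min, 1.0), 0.0)
    return s_corr * np.diag(sigma)


class GaussianKnockoffs(BaseEstimator):
    """Fit the Gaussian working model of X and sample knockoff copies.

    Parameters
    ----------
    shrinkage : "lw", float or None
        Covariance regularization: ``"lw"`` (default) uses the Ledoit-Wolf
        automatic shrinkage toward the identity; a float in ``[0, 1]`` fixes
        the shrinkage intensity; ``None`` (or 0) uses the raw empirical
        covariance.

    Attributes
    ----------
    mu_ : ndarray of shape (p,)
        Column means.
    sigma_ : ndarray of shape (p, p)
        Regularized covariance estimate (symmetric positive definite).
    s_ : ndarray of shape (p,)
        Decorrelation vector; ``cov(X_j, X~_j) = sigma_[j, j] - s_[j]``.
    conditional_coef_ : ndarray of shape (p, p)
        ``Sigma^{-1} diag(s)``, the coefficient matrix of the conditional
        mean ``m(X) = X - (X - mu) @ conditional_coef_``.
    conditional_cov_ : ndarray of shape (p, p)
        ``V = 2 diag(s) - diag(s) Sigma^{-1} diag(s)``, floored to be PSD.
    """

    def __init__(self, shrinkage: str | float | None = "lw"):
        self.shrinkage = shrinkage

    # -- model fitting ------------------------------------------------------

    def _estimate_covariance(self, X: np.ndarray) -> np.ndarray:
        if self.shrinkage == "lw":
            return LedoitWolf(assume_centered=False).fit(X).covariance_
        if self.shrinkage in (None, 0, 0.0):
            return empirical_covariance(X, assume_centered=False)
        a = float(self.shrinkage)
        if not 0 <= a <= 1:
            raise ValueError("shrinkage must be 'lw', None, or a float in [0, 1]")
        emp = empirical_covariance(X, assume_centered=False)
        target = np.trace(emp) / emp.shape[0] * np.eye(emp.shape[0])
        return (1 - a) * emp + a * target

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be a 2-D matrix with at least one feature")
        n, p = X.shape
        if n <= 2:
            raise ValueError("need more than 2 samples to estimate the model")

        self.mu_ = X.mean(axis=0)
        sigma = self._estimate_covariance(X)
        sigma = (sigma + sigma.T) / 2.0
        # covariance itself must be PD for the conditional formulas
        min_eig = float(np.linalg.eigvalsh(sigma)[0])
        if min_eig <= 1e-12 * max(1.0, float(np.trace(sigma)) / p):
            raise ValueError(
                "estimated covariance is numerically singular; increase the "
                "shrinkage intensity"
            )
        self.sigma_ = sigma
        self.s_ = equicorrelated_s(sigma)

        ds = np.diag(self.s_)
        coef = np.linalg.solve(sigma, ds)  # Sigma^{-1} diag(s)
        V = 2.0 * ds - ds @ coef
        V = (V + V.T) / 2.0
        evals, evecs = np.linalg.eigh(V)
        floored = np.clip(evals, 0.0, None)
        lost = float(-evals[evals < 0].sum()) if (evals < 0).any() else 0.0
        if lost > _PSD_WARN_FRACTION * max(float(floored.sum()), 1e-300):
            warnings.warn(
                f"conditional knockoff covariance needed eigenvalue flooring "
                f"({lost:.3e} of trace removed)",
                RuntimeWarning,
            )
        self.conditional_coef_ = coef
        self.conditional_cov_ = (evecs * floored) @ evecs.T
        self._cov_factor = evecs * np.sqrt(floored)  # L with L @ L.T = V
        self.n_features_in_ = p
        return self

    @classmethod
    def from_moments(cls, mu: np.ndarray, sigma: np.ndarray) -> "GaussianKnockoffs":
        """Build a model directly from known moments (no estimation)."""
        mu = np.asarray(mu, dtype=float)
        model = cls(shrinkage=None)
        # reuse fit's algebra on a fabricated instance
        model.mu_ = mu
        sigma = np.asarray(sigma, dtype=float)
        model.sigma_ = (sigma + sigma.T) / 2.0
        model.s_ = equicorrelated_s(model.sigma_)
        ds = np.diag(model.s_)
        coef = np.linalg.solve(model.sigma_, ds)
        V = 2.0 * ds - ds @ coef
        V = (V + V.T) / 2.0
        evals, evecs = np.linalg.eigh(V)
        floored = np.clip(evals, 0.0, None)
        model.conditional_coef_ = coef
        model.conditional_cov_ = (evecs * floored) @ evecs.T
        model._cov_factor = evecs * np.sqrt(floored)
        model.n_features_in_ = mu.shape[0]
        return model

    # -- sampling -----------------------------------------------------------

    def conditional_mean(self, X) -> np.ndarray:
        """m(X) = X - (X - mu) Sigma^{-1} diag(s)."""
        check_is_fitted(self, "conditional_coef_")
        X = np.asarray(X, dtype=float)
        return X - (X - self.mu_) @ self.conditional_coef_

    def sample(self, X, B: int = 1, random_state=None) -> KnockoffDraws:
        """Draw ``B`` mutually independent knockoff copies of ``X``.

        Copies are reproducible individually: copy ``b`` uses an RNG stream
        spawned deterministically from ``random_state`` and ``b``, so the
        draws are independent and auditable.  The response never enters.
        """
        check_is_fitted(self, "conditional_coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        if B < 1:
            raise ValueError("B must be at least 1")
        m = self.conditional_mean(X)
        if isinstance(random_state, np.random.SeedSequence):
            root = random_state
        else:
            root = np.random.SeedSequence(random_state)
        children = root.spawn(B)
        copies, seeds = [], []
        for child in children:
            rng = np.random.default_rng(child)
            noise = rng.standard_normal(X.shape)
            copies.append(m + noise @ self._cov_factor.T)
            seeds.append(int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)))
        return KnockoffDraws(copies=copies, seeds=seeds)
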