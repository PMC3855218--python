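"""Single-random-effect REML and GBLUP prediction.

Model:  y = 1*mu + g + e,  g ~ N(0, G*sigma2_g),  e ~ N(0, I*sigma2_e),
with G a genomic relationship matrix.  Variance components are estimated by
restricted maximum likelihood; after the eigendecomposition G = U D U' the
restricted log-likelihood is a one-dimensional function of the variance
ratio lambda = sigma2_e / sigma2_g, which is maximised numerically on the
log scale.  Prediction for an arbitrary individual set P uses

    mu_hat = (1' V^-1 y) / (1' V^-1 1),        V = G_TT s2g + I s2e,
    g_hat_P = s2g * G_PT V^-1 (y_T - 1 mu_hat),

which coincides with the solution of Henderson's mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar

from .relmat import GRM, InputError

__all__ = ["VarianceComponents", "GBLUPFit", "reml_estimate", "gblup_predict"]


class NumericalError(RuntimeError):
    """Linear-algebra failure (singular or indefinite system)."""


@dataclass
class VarianceComponents:
    """Genomic and residual variance with the ratio lambda = s2e/s2g."""

    sigma2_g: float
    sigma2_e: float
    log_likelihood: float | None = None
    converged: bool = True

    def __post_init__(self):
        if not (np.isfinite(self.sigma2_g) and np.isfinite(self.sigma2_e)):
            raise InputError("variance components must be finite")
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise InputError("variance components must be non-negative")

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else np.inf

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class GBLUPFit:
    """Overall mean and predicted genomic breeding values."""

    mu_hat: float
    gbv: np.ndarray
    predict_ids: np.ndarray = None


def _jittered_eigh(g: np.ndarray):
    """Eigendecompose G, adding diagonal jitter if it is indefinite."""
    d, u = linalg.eigh(g)
    tol = 1e-8 * max(1.0, float(np.mean(np.diag(g))))
    if d.min() < -tol:
        jitter = 1e-8 * float(np.mean(np.diag(g)))
        d, u = linalg.eigh(g + (jitter - d.min()) * np.eye(g.shape[0]))
    d = np.clip(d, 0.0, None)
    return d, u


def restricted_loglik(lam: float, d: np.ndarray, xt: np.ndarray, yt: np.ndarray):
    """Profiled REML log-likelihood of the variance ratio lambda.

    ``d`` are the eigenvalues of G and ``xt``, ``yt`` the rotated design
    column (of ones) and response.  Returns (loglik, mu_hat, sigma2_g_hat).
    """
    n = len(yt)
    v = d + lam
    xvx = np.sum(xt ** 2 / v)
    xvy = np.sum(xt * yt / v)
    mu = xvy / xvx
    r = yt - mu * xt
    quad = np.sum(r ** 2 / v)
    s2g = quad / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(s2g) + np.sum(np.log(v)) + np.log(xvx) + (n - 1))
    return ll, mu, s2g


def reml_estimate(y: np.ndarray, grm: GRM) -> VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) for y = 1*mu + g + e.

    The search is a bounded 1-D optimisation of the restricted likelihood
    over log(lambda) in [-10, 10]; estimates are invariant to permutation
    of the individuals and scale with var(y).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != grm.n_individuals:
        raise InputError("phenotype length must match GRM dimension")
    if y.std() == 0:
        raise InputError("phenotype has zero variance")
    d, u = _jittered_eigh(grm.matrix)
    yt = u.T @ y
    xt = u.T @ np.ones(len(y))

    def neg(loglam):
        return -restricted_loglik(np.exp(loglam), d, xt, yt)[0]

    res = minimize_scalar(neg, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    ll, _mu, s2g = restricted_loglik(lam, d, xt, yt)
    return VarianceComponents(
        sigma2_g=float(s2g),
        sigma2_e=float(s2g * lam),
        log_likelihood=float(ll),
        converged=bool(res.success),
    )


def gblup_predict(
    y_train: np.ndarray,
    grm: GRM,
    train_ids,
    predict_ids,
    vc: VarianceComponents,
) -> GBLUPFit:
    """BLUP of genomic breeding values for ``predict_ids`` given training data.

    ``train_ids``/``predict_ids`` are integer row indices into the GRM; the
    two sets may overlap or be disjoint.
    """
    t = np.asarray(train_ids, dtype=int)
    p = np.asarray(predict_ids, dtype=int)
    y = np.asarray(y_train, dtype=float)
    if len(y) != len(t):
        raise InputError("y_train length must match train_ids")
    g_tt = grm.matrix[np.ix_(t, t)]
    g_pt = grm.matrix[np.ix_(p, t)]
    v = vc.sigma2_g * g_tt + vc.sigma2_e * np.eye(len(t))
    try:
        cho = linalg.cho_factor(v)
    except linalg.LinAlgError as err:
        raise NumericalError(
            "training-set covariance V is singular; consider adding diagonal "
            "jitter to G or a small residual variance"
        ) from err
    ones = np.ones(len(t))
    vi_y = linalg.cho_solve(cho, y)
    vi_1 = linalg.cho_solve(cho, ones)
    denom = ones @ vi_1
    if denom <= 0:
        raise NumericalError("degenerate GLS system for the overall mean")
    mu = float(ones @ vi_y) / float(denom)
    resid = linalg.cho_solve(cho, y - mu * ones)
    gbv = vc.sigma2_g * (g_pt @ resid)
    return GBLUPFit(mu_hat=mu, gbv=gbv, predict_ids=p)
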