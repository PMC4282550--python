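"""Maximum-likelihood fit of the bivariate normal tumour-shrinkage model.

The log size ratios ``(y1, y2)`` of a patient are modelled as bivariate
normal with means linear in baseline size (and, in comparative trials, in the
treatment indicator)::

    single-arm:    mu1 = alpha + gamma*z0          mu2 = beta + gamma*z0
    comparative:   mu1 = mu + beta1*t + gamma*z0   mu2 = mu + delta + beta2*t + gamma*z0

with an unstructured 2x2 covariance Sigma.  Sizes missing because of
non-shrinkage failure or dropout are treated as missing at random, so the fit
maximises the observed-data likelihood directly: a patient with both ratios
contributes the bivariate density, a patient with only the interim ratio the
univariate marginal, and a patient with no post-baseline ratio nothing.

Sigma is parameterised during optimisation as (log sd1, log sd2, atanh rho)
so the search is smooth and unconstrained; the parameter covariance matrix is
reported on that same internal scale (which is also the scale on which the
downstream delta method differentiates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import approx_fprime, minimize

from .data import TrialData

__all__ = ["LongitudinalFit", "LongitudinalFitError", "fit_longitudinal", "marginal_final"]

PARAM_NAMES_SINGLE = ["alpha", "beta", "gamma", "log_sd1", "log_sd2", "atanh_rho"]
PARAM_NAMES_COMPARATIVE = [
    "mu", "delta", "beta1", "beta2", "gamma", "log_sd1", "log_sd2", "atanh_rho",
]


class LongitudinalFitError(RuntimeError):
    """Unidentifiable data or a failed likelihood maximisation."""


@dataclass
class LongitudinalFit:
    """ML estimates of the shrinkage model.

    ``x`` is the internal parameter vector (mean parameters followed by
    ``log_sd1, log_sd2, atanh_rho``); ``vcov`` is the inverse observed
    information on that scale.  ``sigma`` is the 2x2 covariance on the
    natural scale.
    """

    comparative: bool
    param_names: list[str]
    x: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_pairs: int
    n_interim_only: int
    converged: bool = True

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.x))

    @property
    def sigma(self) -> np.ndarray:
        s1, s2 = np.exp(self.x[-3]), np.exp(self.x[-2])
        rho = np.tanh(self.x[-1])
        return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])

    def mean_final(self, z0, t=0):
        """mu2 for baseline size(s) z0 on arm t."""
        z0 = np.asarray(z0, float)
        p = self.params
        if self.comparative:
            return p["mu"] + p["delta"] + p["beta2"] * t + p["gamma"] * z0
        return p["beta"] + p["gamma"] * z0

    def to_dict(self) -> dict:
        return {
            "model": "bivariate_normal_mar",
            "comparative": self.comparative,
            "params": self.params,
            "sigma": self.sigma,
            "vcov": self.vcov,
            "loglik": self.loglik,
            "n_pairs": self.n_pairs,
            "n_interim_only": self.n_interim_only,
            "converged": self.converged,
        }


def _neg_loglik(x, z0, t, y1, y2, both, only1, only2, comparative):
    if comparative:
        mu, delta, b1, b2, gamma = x[:5]
        mu1 = mu + b1 * t + gamma * z0
        mu2 = mu + delta + b2 * t + gamma * z0
    else:
        alpha, beta, gamma = x[:3]
        mu1 = alpha + gamma * z0
        mu2 = beta + gamma * z0
    ls1, ls2, za = x[-3:]
    s1, s2 = np.exp(ls1), np.exp(ls2)
    rho = np.tanh(za)
    omr2 = 1.0 - rho * rho

    ll = 0.0
    if both.any():
        u1 = (y1[both] - mu1[both]) / s1
        u2 = (y2[both] - mu2[both]) / s2
        q = (u1 * u1 - 2.0 * rho * u1 * u2 + u2 * u2) / omr2
        ll += np.sum(
            -np.log(2.0 * np.pi) - ls1 - ls2 - 0.5 * np.log(omr2) - 0.5 * q
        )
    if only1.any():
        u1 = (y1[only1] - mu1[only1]) / s1
        ll += np.sum(-0.5 * np.log(2.0 * np.pi) - ls1 - 0.5 * u1 * u1)
    if only2.any():
        # cannot arise under monotone missingness, kept for generality
        u2 = (y2[only2] - mu2[only2]) / s2
        ll += np.sum(-0.5 * np.log(2.0 * np.pi) - ls2 - 0.5 * u2 * u2)
    return -ll


def numerical_hessian(f, x, rel_step=1e-5):
    """Central-difference Hessian with step ``rel_step * max(1, |x_j|)``."""
    x = np.asarray(x, float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        f_pp = f(x + 2 * ei)
        f_mm = f(x - 2 * ei)
        f0 = f(x)
        H[i, i] = (f_pp - 2 * f0 + f_mm) / (4 * h[i] * h[i])
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _start_values(z0, t, y1, y2, both, comparative):
    # complete-case moment estimates; near the optimum and deterministic
    yb1, yb2 = y1[both], y2[both]
    if comparative:
        tb = t[both]
        m10 = yb1[tb == 0].mean() if (tb == 0).any() else yb1.mean()
        m11 = yb1[tb == 1].mean() if (tb == 1).any() else yb1.mean()
        m20 = yb2[tb == 0].mean() if (tb == 0).any() else yb2.mean()
        m21 = yb2[tb == 1].mean() if (tb == 1).any() else yb2.mean()
        mean = [m10, m20 - m10, m11 - m10, m21 - m20, 0.0]
        r1 = yb1 - np.where(tb == 1, m11, m10)
        r2 = yb2 - np.where(tb == 1, m21, m20)
    else:
        mean = [yb1.mean(), yb2.mean(), 0.0]
        r1, r2 = yb1 - yb1.mean(), yb2 - yb2.mean()
    s1 = max(np.std(r1), 1e-3)
    s2 = max(np.std(r2), 1e-3)
    rho = float(np.clip(np.mean(r1 * r2) / (s1 * s2), -0.95, 0.95))
    return np.array(mean + [np.log(s1), np.log(s2), np.arctanh(rho)])


def fit_longitudinal(data: TrialData, comparative: bool | None = None) -> LongitudinalFit:
    """Fit the shrinkage model by direct maximum likelihood under MAR.

    Raises :class:`LongitudinalFitError` when fewer than two complete
    ``(y1, y2)`` pairs are available (Sigma unidentifiable) or the optimiser
    fails to reach a stationary point.
    """
    if comparative is None:
        comparative = data.comparative
    z0 = data.z0
    t = data.arm.astype(float)
    y1, y2 = data.y1, data.y2
    o1, o2 = ~np.isnan(y1), ~np.isnan(y2)
    both = o1 & o2
    only1 = o1 & ~o2
    only2 = o2 & ~o1
    if both.sum() < 2:
        raise LongitudinalFitError(
            f"need >= 2 complete (y1, y2) pairs to identify Sigma, got {both.sum()}"
        )
    if comparative and (len(set(t)) < 2):
        raise LongitudinalFitError("comparative fit requires both arms")

    args = (z0, t, np.nan_to_num(y1), np.nan_to_num(y2), both, only1, only2, comparative)
    x0 = _start_values(z0, t, y1, y2, both, comparative)
    res = minimize(_neg_loglik, x0, args=args, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    if not res.success:
        # one polishing restart; BFGS often reports precision loss after
        # having effectively converged
        res = minimize(_neg_loglik, res.x, args=args, method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 500})
    grad = approx_fprime(res.x, _neg_loglik, 1e-8, *args)
    if not res.success and np.max(np.abs(grad)) > 1e-4 * max(1.0, abs(res.fun)):
        raise LongitudinalFitError(
            f"likelihood maximisation failed: {res.message} "
            f"(max |grad| = {np.max(np.abs(grad)):.2e})"
        )
    H = numerical_hessian(lambda x: _neg_loglik(x, *args), res.x)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
        raise LongitudinalFitError(f"observed information not invertible: {exc}")
    names = PARAM_NAMES_COMPARATIVE if comparative else PARAM_NAMES_SINGLE
    return LongitudinalFit(
        comparative=comparative,
        param_names=list(names),
        x=res.x,
        vcov=vcov,
        loglik=-res.fun,
        n_pairs=int(both.sum()),
        n_interim_only=int(only1.sum()),
        converged=bool(res.success),
    )


def marginal_final(fit: LongitudinalFit, z0, t=0):
    """Marginal mean and SD of the final log ratio ``y2`` at baseline size z0."""
    return fit.mean_final(z0, t), float(np.sqrt(fit.sigma[1, 1]))
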