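"""The augmented binary estimator and two-arm Wald comparison.

The composite success probability of a patient with baseline size ``z0`` on
arm ``t`` is

    p(z0, t) = (1 - pi1(z0, t)) *
               E_{y1}[ (1 - pi2(z1(y1), t)) * Phi((log c - mu_{2|1}) / sd_{2|1}) ]

where ``pi1``/``pi2`` are the fitted interval failure probabilities, the
expectation is over the fitted marginal normal law of the interim log ratio
``y1`` (with ``z1 = z0 * exp(y1)`` the implied interim size), and the inner
normal CDF integrates the conditional law of the final log ratio below the
dichotomisation threshold ``c`` in closed form.  The remaining 1-D integral
over ``y1`` is evaluated by quadrature.  With the optional interim threshold
(case-study variant) the ``y1`` integral is truncated at ``log`` of that
threshold.

Uncertainty comes from the delta method: the three model fits supply a
block-diagonal parameter covariance (their parameter sets are distinct), the
gradient of ``logit(mean success)`` — or of the two-arm mean difference — is
taken by central finite differences, and a Wald interval/test follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad
from scipy.linalg import block_diag
from scipy.special import expit, logit, ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .data import TrialData
from .failure import FailureFit, fit_failure
from .longitudinal import LongitudinalFit, fit_longitudinal

__all__ = [
    "Theta",
    "SuccessEstimate",
    "ComparisonResult",
    "AugmentedBinarySuccess",
    "AugmentedBinaryComparison",
    "success_prob_patient",
    "mean_success",
    "estimate_with_ci",
    "compare_arms",
]

_TAIL_SDS = 8.0  # y1 integral spans +/- 8 conditional SDs; beyond is < 1e-14
_FD_REL_STEP = 1e-5
_GL_NODES = 48


class Theta:
    """Concatenated parameters of the three fitted models.

    Layout: longitudinal internal vector (mean parameters, log sd1, log sd2,
    atanh rho), then interval-1 and interval-2 logistic coefficients — length
    10 single-arm, 14 comparative.  The covariance is block-diagonal because
    the three likelihoods share no parameters.
    """

    def __init__(
        self,
        longitudinal: LongitudinalFit,
        failure1: FailureFit,
        failure2: FailureFit,
        vcov: np.ndarray | None = None,
    ):
        self.longitudinal = longitudinal
        self.failure1 = failure1
        self.failure2 = failure2
        self.comparative = longitudinal.comparative
        self.vector = np.concatenate(
            [longitudinal.x, failure1.coef, failure2.coef]
        )
        if vcov is None:
            vcov = block_diag(longitudinal.vcov, failure1.vcov, failure2.vcov)
        self.vcov = np.asarray(vcov, float)
        self.interval2_covariate = failure2.interval2_covariate

    def __len__(self) -> int:
        return self.vector.size

    @property
    def param_names(self) -> list[str]:
        return (
            self.longitudinal.param_names
            + self.failure1.coef_names
            + self.failure2.coef_names
        )


def _split(vec: np.ndarray, comparative: bool):
    """(mean params, (s1, s2, rho), f1 coefs, f2 coefs) from a theta vector."""
    k = 5 if comparative else 3
    mean = vec[:k]
    s1, s2 = np.exp(vec[k]), np.exp(vec[k + 1])
    rho = np.tanh(vec[k + 2])
    nf = 3 if comparative else 2
    f1 = vec[k + 3 : k + 3 + nf]
    f2 = vec[k + 3 + nf : k + 3 + 2 * nf]
    return mean, (s1, s2, rho), f1, f2


def _means(mean, z0, t, comparative):
    if comparative:
        mu, delta, b1, b2, gamma = mean
        return mu + b1 * t + gamma * z0, mu + delta + b2 * t + gamma * z0
    alpha, beta, gamma = mean
    return alpha + gamma * z0, beta + gamma * z0


def _logistic_p(coef, size_prev, t, comparative):
    lp = coef[0] + coef[1] * size_prev
    if comparative:
        lp = lp + coef[2] * t
    return expit(lp)


def _success_prob_vec(
    vec,
    z0,
    t,
    comparative,
    final_threshold,
    interim_threshold=None,
    interval2_covariate="size",
    nodes=None,
):
    """Vectorised Gauss–Legendre evaluation of p(z0, t) over an array of z0."""
    z0 = np.atleast_1d(np.asarray(z0, float))
    mean, (s1, s2, rho), f1, f2 = _split(np.asarray(vec, float), comparative)
    sd_cond = s2 * np.sqrt(max(1.0 - rho * rho, 0.0))
    if not (s1 > 0 and sd_cond > 0):
        raise ValueError("covariance matrix is not positive definite")
    slope = rho * s2 / s1
    mu1, mu2 = _means(mean, z0, t, comparative)
    lc = np.log(final_threshold)

    lo = mu1 - _TAIL_SDS * s1
    hi = mu1 + _TAIL_SDS * s1
    if interim_threshold is not None:
        hi = np.minimum(hi, np.log(interim_threshold))
    if nodes is None:
        nodes = leggauss(_GL_NODES)
    xg, wg = nodes
    half = 0.5 * (hi - lo)
    y1 = 0.5 * (hi + lo)[:, None] + half[:, None] * xg
    pdf = np.exp(-0.5 * ((y1 - mu1[:, None]) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    cov2 = z0[:, None] * np.exp(y1) if interval2_covariate == "size" else y1
    p2 = _logistic_p(f2, cov2, t, comparative)
    mu_cond = mu2[:, None] + slope * (y1 - mu1[:, None])
    inner = np.sum(wg * pdf * (1.0 - p2) * ndtr((lc - mu_cond) / sd_cond), axis=1)
    p1 = _logistic_p(f1, z0, t, comparative)
    out = (1.0 - p1) * np.maximum(half, 0.0) * inner
    return np.clip(out, 0.0, 1.0)


def success_prob_patient(
    theta: Theta,
    z0: float,
    t: int = 0,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
) -> float:
    """Per-patient success probability by adaptive quadrature (abs tol 1e-8).

    The final-ratio dimension is integrated in closed form through the
    conditional normal CDF; only the interim-ratio dimension is quadratured.
    """
    vec = theta.vector
    comparative = theta.comparative
    mean, (s1, s2, rho), f1, f2 = _split(vec, comparative)
    sd_cond = s2 * np.sqrt(max(1.0 - rho * rho, 0.0))
    if not (s1 > 0 and sd_cond > 0):
        raise ValueError("covariance matrix is not positive definite")
    slope = rho * s2 / s1
    mu1, mu2 = _means(mean, float(z0), t, comparative)
    lc = np.log(final_threshold)

    def integrand(y1):
        cov2 = z0 * np.exp(y1) if theta.interval2_covariate == "size" else y1
        p2 = _logistic_p(f2, cov2, t, comparative)
        mu_cond = mu2 + slope * (y1 - mu1)
        return norm.pdf(y1, mu1, s1) * (1.0 - p2) * ndtr((lc - mu_cond) / sd_cond)

    lo, hi = mu1 - _TAIL_SDS * s1, mu1 + _TAIL_SDS * s1
    if interim_threshold is not None:
        hi = min(hi, np.log(interim_threshold))
    if hi <= lo:
        return 0.0
    integral, _ = quad(integrand, lo, hi, epsabs=1e-8, limit=200)
    p1 = _logistic_p(f1, float(z0), t, comparative)
    return float((1.0 - p1) * integral)


def mean_success(
    theta: Theta,
    baselines,
    t: int = 0,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
) -> float:
    """Mean success probability over the supplied baseline sizes at arm ``t``."""
    baselines = np.asarray(baselines, float)
    if baselines.size == 0:
        raise ValueError("baselines must be non-empty")
    return float(
        _success_prob_vec(
            theta.vector, baselines, t, theta.comparative,
            final_threshold, interim_threshold, theta.interval2_covariate,
        ).mean()
    )


def _fd_gradient(f, x, rel_step=_FD_REL_STEP):
    """Central finite-difference gradient with step rel_step * max(1, |x_j|)."""
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for j in range(x.size):
        h = rel_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        g[j] = (f(xp) - f(xm)) / (2.0 * h)
    return g


@dataclass
class SuccessEstimate:
    """Mean success probability with a logit-scale delta-method Wald CI."""

    p_hat: float
    logit_p: float
    se_logit: float
    ci: tuple[float, float]
    level: float
    n: int

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "logit_p": self.logit_p,
            "se_logit": self.se_logit,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "level": self.level,
            "n": self.n,
        }


@dataclass
class ComparisonResult:
    """Two-arm mean difference in success probability with its Wald test."""

    diff_hat: float
    se_diff: float
    z_stat: float
    p_value: float
    method: str = "augbin"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "diff_hat": self.diff_hat,
            "se_diff": self.se_diff,
            "z_stat": self.z_stat,
            "p_value": self.p_value,
        }


def _fit_theta(data: TrialData, comparative: bool, interval2_covariate: str) -> Theta:
    longitudinal = fit_longitudinal(data, comparative=comparative)
    f1 = fit_failure(data, 1, comparative=comparative)
    f2 = fit_failure(
        data, 2, comparative=comparative, interval2_covariate=interval2_covariate
    )
    return Theta(longitudinal, f1, f2)


class AugmentedBinarySuccess(BaseEstimator):
    """Single-arm augmented binary estimator of the success probability.

    Fits the bivariate normal shrinkage model and the two interval failure
    models, averages the implied per-patient success probability over the
    observed baseline sizes, and attaches a delta-method confidence interval
    on the logit scale.

    Parameters
    ----------
    final_threshold : float
        Dichotomisation ratio ``c``: success needs ``y2 < log(c)`` (0.7 for
        ORR-like response, 1.2 for DCR-like disease control).
    interim_threshold : float or None
        Optional interim ratio criterion (case-study variant): success also
        needs ``y1 < log(interim_threshold)``.
    level : float
        Confidence level of the Wald interval.
    interval2_covariate : {"size", "log_ratio"}
        Covariate carried by the interval-2 failure model.

    Attributes
    ----------
    theta_ : Theta
    p_hat_, logit_p_, se_logit_, ci_ : fitted estimate and interval
    estimate_ : SuccessEstimate
    """

    def __init__(
        self,
        final_threshold: float = 0.7,
        interim_threshold: float | None = None,
        level: float = 0.95,
        interval2_covariate: str = "size",
    ):
        self.final_threshold = final_threshold
        self.interim_threshold = interim_threshold
        self.level = level
        self.interval2_covariate = interval2_covariate

    def fit(self, X, y=None):
        data = X if isinstance(X, TrialData) else TrialData(X)
        if data.comparative:
            raise ValueError(
                "dataset has two arms; fit each arm separately or use "
                "AugmentedBinaryComparison"
            )
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        theta = _fit_theta(data, False, self.interval2_covariate)
        baselines = data.z0

        def l_of(vec):
            p = _success_prob_vec(
                vec, baselines, 0, False,
                self.final_threshold, self.interim_threshold,
                self.interval2_covariate,
            ).mean()
            return logit(p)

        p_hat = mean_success(
            theta, baselines, 0, self.final_threshold, self.interim_threshold
        )
        if not 0.0 < p_hat < 1.0:
            raise ValueError(
                f"estimated success probability {p_hat} is degenerate; the "
                "logit-scale interval is undefined"
            )
        lhat = logit(p_hat)
        grad = _fd_gradient(l_of, theta.vector)
        se = float(np.sqrt(grad @ theta.vcov @ grad))
        zq = norm.ppf(0.5 + self.level / 2.0)
        ci = (float(expit(lhat - zq * se)), float(expit(lhat + zq * se)))

        self.theta_ = theta
        self.p_hat_ = float(p_hat)
        self.logit_p_ = float(lhat)
        self.se_logit_ = se
        self.ci_ = ci
        self.n_ = data.n
        self.estimate_ = SuccessEstimate(
            self.p_hat_, self.logit_p_, se, ci, self.level, data.n
        )
        return self

    def predict_proba(self, z0):
        """Per-patient success probabilities for baseline sizes ``z0``."""
        return _success_prob_vec(
            self.theta_.vector, np.asarray(z0, float), 0, False,
            self.final_threshold, self.interim_threshold,
            self.interval2_covariate,
        )


class AugmentedBinaryComparison(BaseEstimator):
    """Two-arm augmented binary Wald test on the mean success difference.

    The mean difference averages ``p(z0, t=1) - p(z0, t=0)`` over the pooled
    empirical baseline sizes of both arms (adjusting for chance imbalance in
    baseline size); per-arm averaging is available via ``baseline_average``.
    """

    def __init__(
        self,
        final_threshold: float = 0.7,
        interim_threshold: float | None = None,
        interval2_covariate: str = "size",
        baseline_average: str = "pooled",
    ):
        self.final_threshold = final_threshold
        self.interim_threshold = interim_threshold
        self.interval2_covariate = interval2_covariate
        self.baseline_average = baseline_average

    def _diff(self, vec, z0_1, z0_0):
        p1 = _success_prob_vec(
            vec, z0_1, 1, True, self.final_threshold,
            self.interim_threshold, self.interval2_covariate,
        ).mean()
        p0 = _success_prob_vec(
            vec, z0_0, 0, True, self.final_threshold,
            self.interim_threshold, self.interval2_covariate,
        ).mean()
        return p1 - p0

    def fit(self, X, y=None):
        data = X if isinstance(X, TrialData) else TrialData(X)
        if not data.comparative:
            raise ValueError("comparative analysis needs both arms present")
        if self.baseline_average not in ("pooled", "per-arm"):
            raise ValueError("baseline_average must be 'pooled' or 'per-arm'")
        theta = _fit_theta(data, True, self.interval2_covariate)
        if self.baseline_average == "pooled":
            z0_1 = z0_0 = data.z0
        else:
            z0_1 = data.z0[data.arm == 1]
            z0_0 = data.z0[data.arm == 0]

        diff = self._diff(theta.vector, z0_1, z0_0)
        grad = _fd_gradient(lambda v: self._diff(v, z0_1, z0_0), theta.vector)
        se = float(np.sqrt(grad @ theta.vcov @ grad))
        z = diff / se if se > 0 else np.inf * np.sign(diff) if diff else 0.0
        p_value = float(2.0 * (1.0 - ndtr(abs(z))))

        self.theta_ = theta
        self.diff_ = float(diff)
        self.se_diff_ = se
        self.z_ = float(z)
        self.p_value_ = p_value
        self.result_ = ComparisonResult(self.diff_, se, self.z_, p_value, "augbin")
        return self


# -- thin functional wrappers ------------------------------------------------

def estimate_with_ci(
    data,
    level: float = 0.95,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
    interval2_covariate: str = "size",
) -> SuccessEstimate:
    """Augmented binary estimate + CI for a single-arm dataset."""
    est = AugmentedBinarySuccess(
        final_threshold, interim_threshold, level, interval2_covariate
    ).fit(data)
    return est.estimate_


def compare_arms(
    data,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
    interval2_covariate: str = "size",
    baseline_average: str = "pooled",
) -> ComparisonResult:
    """Augmented binary two-arm Wald test on the success-probability difference."""
    est = AugmentedBinaryComparison(
        final_threshold, interim_threshold, interval2_covariate, baseline_average
    ).fit(data)
    return est.result_
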