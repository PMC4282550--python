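"""Trial simulator and generating-model truths for operating characteristics.

A simulated patient has a baseline size ``z0 ~ U(5, 10)`` cm and log size
ratios ``(y1, y2)`` drawn from a bivariate normal with mean ``(delta/2,
delta)`` and covariance

    Sigma_sim = sigma^2 * [[f,          rho*sqrt(f)],
                           [rho*sqrt(f), 1         ]]

where ``f`` is the interim variance fraction.  The defaults ``f = 0.5`` and
``rho = 1/sqrt(2)`` correspond to Sigma_sim = sigma^2 * [[0.5, 0.5], [0.5, 1]],
the covariance that reproduces the published truth values of the simulation
scenarios this generator emulates.

Non-shrinkage failure in interval 1 occurs with probability
``expit(alpha_D + gamma_D*z0 + beta_D*t)``; in interval 2 (given survival to
interim) with the interim size ``z1 = z0*exp(y1)`` as covariate.  An
analogous independent logistic process drives non-failure dropout
(``alpha_O = -inf`` disables it); a patient simulated to both fail and drop
out in the same interval is recorded as a dropout.  Failure or dropout
censors all later sizes and statuses.

In comparative trials the arm means are ``delta0 = log(0.7) + psi + x``
(control) and ``delta1 = log(0.7) + psi - x`` (experimental): ``2x`` is the
mean difference and ``psi`` shifts both arms relative to the 30%-shrinkage
point, with positive ``x`` favouring the experimental arm (more shrinkage is
a more negative log ratio).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.special import expit, ndtr

from .data import TrialData

__all__ = ["Scenario", "arm_means", "simulate_trial", "true_success_prob"]

LOG_07 = math.log(0.7)


def arm_means(x: float, psi: float) -> tuple[float, float]:
    """Mean final log ratios (control, experimental) for a comparative scenario."""
    return LOG_07 + psi + x, LOG_07 + psi - x


@dataclass
class Scenario:
    """Data-generating parameters of one simulation scenario.

    Single-arm scenarios set ``delta1`` (mean final log ratio); comparative
    scenarios set ``comparative=True`` with ``x`` and ``psi``.  Failure and
    dropout parameters are shared nuisance parameters between arms.
    """

    n_per_arm: int
    delta1: float | None = None
    comparative: bool = False
    x: float | None = None
    psi: float | None = None
    sigma: float = 1.0
    rho: float = 1.0 / math.sqrt(2.0)
    interim_var_frac: float = 0.5
    alpha_D: float = -1.5
    gamma_D: float = 0.0
    beta_D: float = 0.0
    alpha_O: float = -math.inf
    gamma_O: float = 0.0
    beta_O: float = 0.0
    final_threshold: float = 0.7
    seed: int | None = None

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.comparative:
            if self.x is None or self.psi is None:
                raise ValueError("comparative scenarios need x and psi")
        elif self.delta1 is None:
            raise ValueError("single-arm scenarios need delta1")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not self.interim_var_frac > 0:
            raise ValueError("interim_var_frac must be > 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.final_threshold > 0:
            raise ValueError("final_threshold must be > 0")

    def arm_delta(self, t: int) -> float:
        """Mean final log ratio on arm ``t``."""
        if self.comparative:
            return arm_means(self.x, self.psi)[t]
        return self.delta1

    @property
    def sigma_sim(self) -> np.ndarray:
        """2x2 covariance of (y1, y2)."""
        f = self.interim_var_frac
        s2 = self.sigma**2
        off = self.rho * math.sqrt(f) * s2
        return np.array([[f * s2, off], [off, s2]])

    def to_dict(self) -> dict:
        return asdict(self)


def _simulate_arm(scenario: Scenario, t: int, rng: np.random.Generator) -> pd.DataFrame:
    n = scenario.n_per_arm
    delta = scenario.arm_delta(t)
    z0 = rng.uniform(5.0, 10.0, n)
    y = rng.multivariate_normal(
        [0.5 * delta, delta], scenario.sigma_sim, size=n, method="cholesky"
    )
    y1, y2 = y[:, 0], y[:, 1]
    u = rng.uniform(size=(n, 4))  # fail1, drop1, fail2, drop2

    z1 = z0 * np.exp(y1)
    p_f1 = expit(scenario.alpha_D + scenario.gamma_D * z0 + scenario.beta_D * t)
    p_o1 = expit(scenario.alpha_O + scenario.gamma_O * z0 + scenario.beta_O * t)
    p_f2 = expit(scenario.alpha_D + scenario.gamma_D * z1 + scenario.beta_D * t)
    p_o2 = expit(scenario.alpha_O + scenario.gamma_O * z1 + scenario.beta_O * t)
    f1, o1 = u[:, 0] < p_f1, u[:, 1] < p_o1
    f2, o2 = u[:, 2] < p_f2, u[:, 3] < p_o2

    nan = np.nan
    df = pd.DataFrame(
        {
            "arm": t,
            "z0": z0,
            "z1": z1,
            "z2": z0 * np.exp(y2),
            "d1": 0.0,
            "d2": 0.0,
            "drop1": 0.0,
            "drop2": 0.0,
        }
    )
    # interval 1: dropout overrides failure, either censors everything later
    gone1 = o1 | f1
    df.loc[o1, "drop1"] = 1.0
    df.loc[f1 & ~o1, "d1"] = 1.0
    df.loc[o1, "d1"] = nan
    df.loc[gone1, ["z1", "z2", "d2", "drop2"]] = nan
    # interval 2, among those still on study
    at_risk = ~gone1
    o2 &= at_risk
    f2 &= at_risk
    df.loc[o2, "drop2"] = 1.0
    df.loc[f2 & ~o2, "d2"] = 1.0
    df.loc[o2, "d2"] = nan
    df.loc[o2 | f2, "z2"] = nan
    return df


def simulate_trial(scenario: Scenario, rng=None) -> TrialData:
    """Draw one trial dataset; deterministic given the scenario and rng/seed."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    frames = [_simulate_arm(scenario, 0, rng)]
    if scenario.comparative:
        frames.append(_simulate_arm(scenario, 1, rng))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"P{i + 1:04d}" for i in range(len(df))])
    return TrialData(df)


def true_success_prob(
    scenario: Scenario,
    arm: int = 0,
    final_threshold: float | None = None,
    n_nodes: int = 64,
) -> float:
    """True composite success probability implied by the generating model.

    Integrates ``P(no failure in both intervals and y2 < log c)`` over the
    uniform baseline-size law and the normal marginal of the interim log
    ratio, with the conditional normal CDF closing the final-ratio dimension.
    With ``gamma_D = 0`` this collapses to
    ``(1 - expit(a))^2 * Phi((log c - delta)/sigma)`` with
    ``a = alpha_D + beta_D * arm``.
    """
    c = scenario.final_threshold if final_threshold is None else final_threshold
    lc = math.log(c)
    delta = scenario.arm_delta(arm)
    sig = scenario.sigma
    f = scenario.interim_var_frac
    s1 = sig * math.sqrt(f)
    mu1 = 0.5 * delta
    slope = scenario.rho * sig / s1
    sd_cond = sig * math.sqrt(1.0 - scenario.rho**2)
    aD = scenario.alpha_D + scenario.beta_D * arm

    xg, wg = leggauss(n_nodes)
    z0 = 7.5 + 2.5 * xg
    wz = 0.5 * wg  # uniform(5,10) weights
    lo, hi = mu1 - 8.0 * s1, mu1 + 8.0 * s1
    y1 = 0.5 * (hi + lo) + 0.5 * (hi - lo) * xg
    wy = 0.5 * (hi - lo) * wg
    pdf = np.exp(-0.5 * ((y1 - mu1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    cdf_cond = ndtr((lc - (delta + slope * (y1 - mu1))) / sd_cond)

    p1 = expit(aD + scenario.gamma_D * z0)  # (n_z0,)
    z1 = z0[:, None] * np.exp(y1)  # (n_z0, n_y1)
    p2 = expit(aD + scenario.gamma_D * z1)
    inner = np.sum(wy * pdf * (1.0 - p2) * cdf_cond, axis=1)
    return float(np.sum(wz * (1.0 - p1) * inner))
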