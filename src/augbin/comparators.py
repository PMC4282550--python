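"""Reference methods: binary (Wilson) estimate, logistic test, Karrison test.

These are the standard analyses the augmented binary method is benchmarked
against: the complete-case proportion of successes with a Wilson score
interval, a logistic regression of the binary success label on baseline size
and treatment with a Wald test of the treatment effect, and Karrison's
worst-value strategy — compare the final log size ratios between arms by
Wilcoxon rank-sum after imputing the worst (largest) observed ratio for
non-shrinkage failures and excluding non-failure dropouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import ndtr
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from .data import TrialData, label_success
from .inference import ComparisonResult

__all__ = [
    "BinaryEstimate",
    "BinarySuccess",
    "LogisticComparison",
    "KarrisonComparison",
    "wilson_interval",
    "binary_method",
    "logistic_method",
    "karrison_method",
]


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


@dataclass
class BinaryEstimate:
    """Complete-case success proportion with its Wilson interval."""

    p_hat: float
    ci: tuple[float, float]
    n_used: int
    successes: int
    level: float

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "n_used": self.n_used,
            "successes": self.successes,
            "level": self.level,
        }


class BinarySuccess(BaseEstimator):
    """Binary comparator: proportion of successes among determinable cases.

    Patients whose composite status cannot be determined because of dropout
    are excluded; no imputation is attempted.
    """

    def __init__(
        self,
        final_threshold: float = 0.7,
        interim_threshold: float | None = None,
        level: float = 0.95,
    ):
        self.final_threshold = final_threshold
        self.interim_threshold = interim_threshold
        self.level = level

    def fit(self, X, y=None):
        data = X if isinstance(X, TrialData) else TrialData(X)
        s = label_success(data, self.final_threshold, self.interim_threshold)
        used = ~np.isnan(s)
        if used.sum() == 0:
            raise ValueError("every success label is missing")
        successes = int(np.nansum(s))
        n_used = int(used.sum())
        self.p_hat_ = successes / n_used
        self.ci_ = wilson_interval(successes, n_used, self.level)
        self.n_used_ = n_used
        self.successes_ = successes
        self.estimate_ = BinaryEstimate(
            self.p_hat_, self.ci_, n_used, successes, self.level
        )
        return self


class LogisticComparison(BaseEstimator):
    """Logistic-regression comparator for two-arm trials.

    Fits ``S ~ 1 + z0 + t`` to the complete cases and reports the Wald test
    of the treatment coefficient.
    """

    def __init__(
        self,
        final_threshold: float = 0.7,
        interim_threshold: float | None = None,
    ):
        self.final_threshold = final_threshold
        self.interim_threshold = interim_threshold

    def fit(self, X, y=None):
        data = X if isinstance(X, TrialData) else TrialData(X)
        if not data.comparative:
            raise ValueError("comparative analysis needs both arms present")
        s = label_success(data, self.final_threshold, self.interim_threshold)
        used = ~np.isnan(s)
        yv = s[used]
        if yv.sum() == 0 or yv.sum() == yv.size:
            raise ValueError("success labels are all one class among complete cases")
        Xm = np.column_stack(
            [np.ones(used.sum()), data.z0[used], data.arm[used].astype(float)]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # divergence is checked below
                res = sm.Logit(yv, Xm).fit(disp=0, method="newton", maxiter=100)
        except Exception as exc:
            raise ValueError(f"logistic comparator failed ({exc})") from exc
        if np.max(np.abs(res.params)) > 50:
            raise ValueError("logistic comparator diverged: likely separation")
        z = float(res.params[2] / res.bse[2])
        self.coef_ = np.asarray(res.params, float)
        self.z_ = z
        self.p_value_ = float(2.0 * (1.0 - ndtr(abs(z))))
        self.n_used_ = int(used.sum())
        self.result_ = ComparisonResult(
            float(res.params[2]), float(res.bse[2]), z, self.p_value_, "logistic"
        )
        return self


class KarrisonComparison(BaseEstimator):
    """Worst-value rank-sum comparator for two-arm trials.

    Final log size ratios are compared between arms with the Wilcoxon
    rank-sum test.  Non-shrinkage failures are imputed to the worst (largest)
    log ratio observed among all patients; dropouts for non-failure reasons
    are excluded.  An exact null distribution is used for combined samples of
    at most 20 without ties, otherwise the normal approximation with tie
    correction.
    """

    def __init__(self, exact_max_n: int = 20):
        self.exact_max_n = exact_max_n

    def fit(self, X, y=None):
        data = X if isinstance(X, TrialData) else TrialData(X)
        if not data.comparative:
            raise ValueError("comparative analysis needs both arms present")
        drop1, drop2 = data.col("drop1"), data.col("drop2")
        d1, d2 = data.col("d1"), data.col("d2")
        y2 = data.y2
        dropped = (drop1 == 1) | (drop2 == 1)
        failed = (d1 == 1) | (d2 == 1)
        observed = ~np.isnan(y2)
        use = ~dropped & (observed | failed)
        if not observed.any():
            raise ValueError("no observed final log ratio to impute from")
        worst = float(np.max(y2[observed]))
        values = np.where(failed, worst, y2)[use]
        arm = data.arm[use]
        x1, x0 = values[arm == 1], values[arm == 0]
        if x1.size == 0 or x0.size == 0:
            raise ValueError("one arm is empty after exclusions")
        n_tot = x1.size + x0.size
        ties = np.unique(values).size < values.size
        method = "exact" if (n_tot <= self.exact_max_n and not ties) else "asymptotic"
        res = mannwhitneyu(x1, x0, alternative="two-sided", method=method)
        self.statistic_ = float(res.statistic)
        self.p_value_ = float(res.pvalue)
        self.n_used_ = int(use.sum())
        self.imputed_value_ = worst
        self.method_ = method
        self.result_ = ComparisonResult(
            np.nan, np.nan, self.statistic_, self.p_value_, "karrison"
        )
        return self


# -- thin functional wrappers ------------------------------------------------

def binary_method(
    data,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
    level: float = 0.95,
) -> BinaryEstimate:
    """Complete-case proportion with Wilson interval."""
    return BinarySuccess(final_threshold, interim_threshold, level).fit(data).estimate_


def logistic_method(
    data,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
) -> ComparisonResult:
    """Wald test of the treatment effect in a complete-case logistic model."""
    return LogisticComparison(final_threshold, interim_threshold).fit(data).result_


def karrison_method(data) -> ComparisonResult:
    """Worst-value-imputation Wilcoxon rank-sum comparison of final log ratios."""
    return KarrisonComparison().fit(data).result_
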