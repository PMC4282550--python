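"""Logistic models for non-shrinkage failure in each inter-visit interval.

Interval 1 models ``P(D1 = 1)`` on the baseline size; interval 2 models the
conditional probability ``P(D2 = 1 | D1 = 0)`` among patients who reached the
interim visit without failing, on the most recently observed tumour size (the
interim size in cm by default; the interim log ratio is available as an
alternative covariate).  Comparative fits add a treatment-effect term.  The
two intervals use disjoint outcome variables, so their estimates are treated
as independent blocks downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .data import TrialData

__all__ = ["FailureFit", "FailureFitError", "fit_failure", "failure_prob"]


class FailureFitError(RuntimeError):
    """Empty risk set, one-class outcome, or (quasi-)complete separation."""


@dataclass
class FailureFit:
    """Logistic coefficients for one failure interval.

    ``coef`` is ordered (intercept, size slope[, treatment effect]); ``vcov``
    is the inverse observed information from the ML fit.
    """

    interval: int
    comparative: bool
    coef: np.ndarray
    coef_names: list[str]
    vcov: np.ndarray
    n_used: int
    n_events: int
    interval2_covariate: str = "size"

    def linear_predictor(self, size_prev, t=0):
        size_prev = np.asarray(size_prev, float)
        lp = self.coef[0] + self.coef[1] * size_prev
        if self.comparative:
            lp = lp + self.coef[2] * t
        return lp

    def to_dict(self) -> dict:
        return {
            "model": f"logistic_failure_interval{self.interval}",
            "comparative": self.comparative,
            "coef": dict(zip(self.coef_names, self.coef)),
            "vcov": self.vcov,
            "n_used": self.n_used,
            "n_events": self.n_events,
            "interval2_covariate": self.interval2_covariate,
        }


def fit_failure(
    data: TrialData,
    interval: int,
    comparative: bool | None = None,
    interval2_covariate: str = "size",
) -> FailureFit:
    """ML logistic fit of the interval's failure indicator.

    Parameters
    ----------
    interval : 1 or 2
        Interval 1 uses every patient whose ``d1`` is observed; interval 2
        uses only patients with ``d1 = 0`` and ``d2`` observed.
    interval2_covariate : {"size", "log_ratio"}
        Covariate for interval 2: interim size in cm (default) or the interim
        log size ratio.
    """
    if interval not in (1, 2):
        raise ValueError("interval must be 1 or 2")
    if interval2_covariate not in ("size", "log_ratio"):
        raise ValueError("interval2_covariate must be 'size' or 'log_ratio'")
    if comparative is None:
        comparative = data.comparative

    d1 = data.col("d1")
    if interval == 1:
        mask = ~np.isnan(d1)
        y = d1[mask]
        size_prev = data.z0[mask]
    else:
        d2 = data.col("d2")
        mask = (d1 == 0) & ~np.isnan(d2)
        y = d2[mask]
        size_prev = (data.col("z1") if interval2_covariate == "size" else data.y1)[mask]
    if mask.sum() == 0:
        raise FailureFitError(f"interval-{interval} risk set is empty")
    if np.isnan(size_prev).any():
        raise FailureFitError(
            f"interval-{interval} risk set has missing covariate values"
        )
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise FailureFitError(
            f"interval-{interval} outcome is all-{int(y[0])}; the failure "
            "probability is not estimable by logistic regression — consider "
            "a simpler model without the size slope"
        )

    cols = [np.ones(mask.sum()), size_prev]
    names = [f"alpha_D{interval}", f"gamma_D{interval}"]
    if comparative:
        cols.append(data.arm[mask].astype(float))
        names.append(f"beta_D{interval}")
    X = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    except Exception as exc:
        raise FailureFitError(
            f"interval-{interval} logistic fit failed ({exc}); the data may "
            "be separated — consider dropping the size slope"
        ) from exc
    if np.max(np.abs(res.params)) > 50:
        raise FailureFitError(
            f"interval-{interval} fit diverged (|coef| > 50): likely "
            "complete separation — consider dropping the size slope"
        )
    return FailureFit(
        interval=interval,
        comparative=comparative,
        coef=np.asarray(res.params, float),
        coef_names=names,
        vcov=np.asarray(res.cov_params(), float),
        n_used=int(mask.sum()),
        n_events=n_events,
        interval2_covariate=interval2_covariate,
    )


def failure_prob(fit: FailureFit, size_prev, t=0):
    """Failure probability at the given previous size (expit of the linear predictor)."""
    return expit(fit.linear_predictor(size_prev, t))
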