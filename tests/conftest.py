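"""Shared fixtures: hand-built trial tables and synthetic Theta objects."""

import numpy as np
import pandas as pd
import pytest

from augbin.data import TrialData
from augbin.failure import FailureFit
from augbin.inference import Theta
from augbin.longitudinal import (
    PARAM_NAMES_COMPARATIVE,
    PARAM_NAMES_SINGLE,
    LongitudinalFit,
)


def make_theta(
    mu1=-0.178,
    mu2=-0.356,
    gamma=0.0,
    s1=0.707,
    s2=1.0,
    rho=0.707,
    f1=(-1.5, 0.0),
    f2=(-1.5, 0.0),
    comparative=False,
    mean_params=None,
    vcov=None,
):
    """Assemble a Theta directly from natural-scale parameters.

    ``mean_params`` overrides the single-arm (mu1, mu2, gamma) triple with an
    arbitrary mean vector (use for comparative layouts).  Failure tuples are
    (intercept, size slope[, treatment effect]).
    """
    if mean_params is None:
        mean_params = [mu1, mu2, gamma]
    x = np.array(list(mean_params) + [np.log(s1), np.log(s2), np.arctanh(rho)])
    names = PARAM_NAMES_COMPARATIVE if comparative else PARAM_NAMES_SINGLE
    lf = LongitudinalFit(
        comparative=comparative,
        param_names=list(names),
        x=x,
        vcov=np.eye(len(x)),
        loglik=0.0,
        n_pairs=0,
        n_interim_only=0,
    )
    fits = []
    for interval, coef in ((1, f1), (2, f2)):
        coef = np.asarray(coef, float)
        fits.append(
            FailureFit(
                interval=interval,
                comparative=comparative,
                coef=coef,
                coef_names=[f"c{j}" for j in range(coef.size)],
                vcov=np.eye(coef.size),
                n_used=0,
                n_events=0,
            )
        )
    return Theta(lf, fits[0], fits[1], vcov=vcov)


@pytest.fixture
def theta_factory():
    return make_theta


@pytest.fixture
def small_trial():
    """Six patients covering success, shrinkage failure, non-shrinkage failure
    and both dropout patterns."""
    rows = [
        # id, arm, z0, z1, z2, d1, d2, drop1, drop2
        ("ok", 0, 8.0, 6.0, 4.0, 0, 0, 0, 0),        # y2=log(.5) < log(.7): success
        ("flat", 0, 8.0, 8.0, 7.9, 0, 0, 0, 0),      # y2=log(.9875): shrinkage failure
        ("fail1", 0, 6.0, None, None, 1, None, 0, None),
        ("fail2", 0, 7.0, 6.5, None, 0, 1, 0, 0),
        ("gone1", 0, 9.0, None, None, None, None, 1, None),
        ("gone2", 0, 5.0, 4.0, None, 0, None, 0, 1),
    ]
    df = pd.DataFrame(rows, columns=["id", "arm", "z0", "z1", "z2", "d1", "d2", "drop1", "drop2"])
    return TrialData(df)
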