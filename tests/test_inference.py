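"""Success-probability integral, delta-method CI and two-arm Wald test."""

import math

import numpy as np
import pytest
from scipy.special import expit, ndtr
from sklearn.base import clone

from augbin.data import TrialData
from augbin.inference import (
    AugmentedBinaryComparison,
    AugmentedBinarySuccess,
    _fd_gradient,
    _success_prob_vec,
    compare_arms,
    estimate_with_ci,
    mean_success,
    success_prob_patient,
)
from augbin.simulator import Scenario, simulate_trial

LOG07 = math.log(0.7)


def mc_success_prob(theta, z0, t, final_threshold, interim_threshold, n_draws, rng):
    """Monte-Carlo evaluation of the same success integral (the oracle)."""
    vec = theta.vector
    comp = theta.comparative
    from augbin.inference import _split, _means, _logistic_p

    mean, (s1, s2, rho), f1, f2 = _split(vec, comp)
    cov = np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])
    mu1, mu2 = _means(mean, np.array([z0]), t, comp)
    y = rng.multivariate_normal([mu1[0], mu2[0]], cov, size=n_draws)
    w = np.ones(n_draws)
    if interim_threshold is not None:
        w *= y[:, 0] < np.log(interim_threshold)
    p1 = _logistic_p(f1, z0, t, comp)
    cov2 = z0 * np.exp(y[:, 0]) if theta.interval2_covariate == "size" else y[:, 0]
    p2 = _logistic_p(f2, cov2, t, comp)
    ok = y[:, 1] < np.log(final_threshold)
    return float(np.mean((1 - p1) * (1 - p2) * ok * w))


def test_theta_length(theta_factory):
    assert len(theta_factory()) == 10
    comp = theta_factory(
        mean_params=[-0.1, -0.2, 0.0, 0.1, 0.0],
        f1=(-1.5, 0.0, 0.2), f2=(-1.5, 0.0, 0.2), comparative=True,
    )
    assert len(comp) == 14


def test_success_prob_closed_form_baseline(theta_factory):
    # flat failure risk factorises out of the integral: the published truth
    # (1-expit(-1.5))^2 * Phi((log 0.7 + 0.356) / 1) = 0.334
    theta = theta_factory(mu2=-0.356, f1=(-1.5, 0.0), f2=(-1.5, 0.0))
    p = success_prob_patient(theta, z0=7.5, final_threshold=0.7)
    closed = (1 - expit(-1.5)) ** 2 * ndtr((LOG07 + 0.356) / 1.0)
    assert p == pytest.approx(closed, abs=1e-7)
    assert round(p, 3) == 0.334


def test_success_prob_median_at_threshold(theta_factory):
    # no failure risk and the median final ratio on the threshold: p = 1/2
    theta = theta_factory(mu2=LOG07, f1=(-60.0, 0.0), f2=(-60.0, 0.0))
    assert success_prob_patient(theta, 6.0) == pytest.approx(0.5, abs=1e-7)


def test_quadrature_agrees_with_adaptive_and_mc(theta_factory):
    theta = theta_factory(mu2=-0.2, gamma=0.02, f1=(-1.8, 0.05), f2=(-2.2, 0.15))
    for z0 in (5.0, 8.0):
        fast = _success_prob_vec(
            theta.vector, np.array([z0]), 0, False, 0.7, None, "size"
        )[0]
        slow = success_prob_patient(theta, z0, final_threshold=0.7)
        assert fast == pytest.approx(slow, abs=1e-8)
        mc = mc_success_prob(theta, z0, 0, 0.7, None, 400_000, np.random.default_rng(4))
        assert fast == pytest.approx(mc, abs=2e-3)


def test_interim_truncation_reduces_probability(theta_factory):
    theta = theta_factory(mu2=-0.2, f2=(-2.0, 0.1))
    full = success_prob_patient(theta, 7.0, final_threshold=1.2)
    trunc = success_prob_patient(theta, 7.0, final_threshold=1.2, interim_threshold=1.2)
    assert trunc < full
    mc = mc_success_prob(theta, 7.0, 0, 1.2, 1.2, 400_000, np.random.default_rng(5))
    assert trunc == pytest.approx(mc, abs=2e-3)


def test_success_prob_monotone_in_threshold(theta_factory):
    theta = theta_factory(mu2=-0.3)
    ps = [success_prob_patient(theta, 7.0, final_threshold=c) for c in (0.5, 0.7, 1.0, 1.2)]
    assert np.all(np.diff(ps) > 0)
    assert all(0 < p < 1 for p in ps)


def test_mean_success_is_average_of_patients(theta_factory):
    theta = theta_factory(f1=(-1.5, 0.2))
    per = [success_prob_patient(theta, z) for z in (5.0, 10.0)]
    assert mean_success(theta, [5.0, 10.0]) == pytest.approx(np.mean(per), abs=1e-7)
    # no size effect anywhere: the baseline distribution is irrelevant
    flat = theta_factory()
    assert mean_success(flat, [5.0]) == pytest.approx(
        mean_success(flat, [6.0, 9.5]), abs=1e-10
    )


def test_zero_vcov_gives_zero_delta_se(theta_factory):
    theta = theta_factory(vcov=np.zeros((10, 10)))
    from scipy.special import logit

    def l_of(vec):
        return logit(_success_prob_vec(vec, np.array([7.5]), 0, False, 0.7)[0].mean())

    g = _fd_gradient(l_of, theta.vector)
    assert float(np.sqrt(g @ theta.vcov @ g)) == 0.0


def test_estimate_with_ci_on_simulated_trial():
    data = simulate_trial(Scenario(n_per_arm=75, delta1=-0.356), 42)
    est = estimate_with_ci(data, level=0.95)
    assert 0 < est.ci[0] < est.p_hat < est.ci[1] < 1
    assert est.ci[0] == pytest.approx(
        expit(est.logit_p - 1.959964 * est.se_logit), abs=1e-9
    )
    # estimator class exposes the same numbers and sklearn plumbing
    model = AugmentedBinarySuccess().fit(data)
    assert model.p_hat_ == est.p_hat
    assert clone(model).get_params()["final_threshold"] == 0.7
    probs = model.predict_proba([5.0, 7.5, 10.0])
    assert probs.shape == (3,) and np.all((probs > 0) & (probs < 1))


def test_compare_arms_null_invariance():
    sc = Scenario(n_per_arm=60, comparative=True, x=0.15, psi=0.0, alpha_D=-1.39)
    data = simulate_trial(sc, 9)
    res = compare_arms(data)
    assert res.p_value == pytest.approx(2 * (1 - ndtr(abs(res.z_stat))), abs=1e-12)
    # swapping the arm labels negates the difference, same p-value
    df = data.df.copy()
    df["arm"] = 1 - df["arm"]
    swapped = compare_arms(TrialData(df))
    # identical up to the optimiser's numerical path on the relabelled data
    assert swapped.diff_hat == pytest.approx(-res.diff_hat, abs=1e-6)
    assert swapped.p_value == pytest.approx(res.p_value, abs=1e-5)


def test_identical_arm_parameters_give_zero_difference(theta_factory):
    theta = theta_factory(
        mean_params=[-0.18, -0.18, 0.0, 0.0, 0.01],
        f1=(-1.5, 0.05, 0.0), f2=(-1.5, 0.05, 0.0), comparative=True,
    )
    z0 = np.array([5.0, 7.5, 10.0])
    p1 = _success_prob_vec(theta.vector, z0, 1, True, 0.7)
    p0 = _success_prob_vec(theta.vector, z0, 0, True, 0.7)
    assert np.allclose(p1, p0, atol=1e-15)


def test_two_arm_dataset_rejected_by_single_arm_estimator():
    data = simulate_trial(
        Scenario(n_per_arm=40, comparative=True, x=0.0, psi=0.0, alpha_D=-1.39), 3
    )
    with pytest.raises(ValueError, match="two arms"):
        AugmentedBinarySuccess().fit(data)
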