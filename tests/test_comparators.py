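"""Binary (Wilson), logistic and worst-value rank-sum comparators."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from augbin.comparators import (
    KarrisonComparison,
    binary_method,
    karrison_method,
    logistic_method,
    wilson_interval,
)
from augbin.data import TrialData
from augbin.simulator import Scenario, simulate_trial


def _two_arm_frame(z0, y2, arm, d1=None, drop=None):
    n = len(z0)
    z0 = np.asarray(z0, float)
    y2 = np.asarray(y2, float)
    d1 = np.zeros(n) if d1 is None else np.asarray(d1, float)
    drop = np.zeros(n) if drop is None else np.asarray(drop, float)
    df = pd.DataFrame(
        {
            "arm": arm,
            "z0": z0,
            "z1": z0 * np.exp(y2 / 2.0),
            "z2": z0 * np.exp(y2),
            "d1": d1, "d2": 0.0, "drop1": drop, "drop2": 0.0,
        }
    )
    failed = d1 == 1
    df.loc[failed, ["z1", "z2", "d2", "drop2"]] = np.nan
    gone = drop == 1
    df.loc[gone, ["z1", "z2", "d1", "d2", "drop2"]] = np.nan
    return TrialData(df)


class TestWilson:
    def test_case_study_placebo_interval(self):
        lo, hi = wilson_interval(6, 41, 0.95)
        assert (round(lo, 3), round(hi, 3)) == (0.069, 0.284)

    def test_boundaries_and_symmetry(self):
        lo, hi = wilson_interval(0, 10, 0.95)
        assert lo == 0.0 and 0 < hi < 1
        lo, hi = wilson_interval(20, 40, 0.95)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)  # centred on 1/2
        with pytest.raises(ValueError):
            wilson_interval(1, 0)

    def test_interval_contains_estimate_and_narrows_with_n(self):
        for s, n in ((3, 10), (30, 100), (299, 1000)):
            lo, hi = wilson_interval(s, n)
            assert 0 <= lo <= s / n <= hi <= 1
        widths = [np.diff(wilson_interval(3 * k, 10 * k))[0] for k in (1, 4, 16)]
        assert widths[0] > widths[1] > widths[2]


class TestBinaryMethod:
    def test_complete_case_proportion(self):
        data = _two_arm_frame(
            [8, 8, 8, 8], [-0.5, 0.1, 0.2, 0.0], arm=0, drop=[0, 0, 0, 1]
        )
        est = binary_method(data)
        assert est.p_hat == pytest.approx(1 / 3)
        assert est.n_used == 3
        assert est.ci == wilson_interval(1, 3)

    def test_all_successes_hits_upper_boundary(self):
        data = _two_arm_frame([8, 8, 8], [-0.6, -0.7, -0.8], arm=0)
        est = binary_method(data)
        assert est.p_hat == 1.0 and est.ci[1] == 1.0


class TestLogistic:
    def test_identical_arms_give_null_p_value(self):
        y2 = [-0.6, -0.2, 0.1, -0.9, 0.3, -0.45]
        z0 = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        data = _two_arm_frame(z0 + z0, y2 + y2, arm=[0] * 6 + [1] * 6)
        res = logistic_method(data)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert abs(res.diff_hat) < 1e-6  # treatment log-odds ratio

    def test_single_class_errors(self):
        data = _two_arm_frame([8] * 6, [-0.6] * 6, arm=[0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="one class"):
            logistic_method(data)


class TestKarrison:
    def test_identical_multisets_no_shift(self):
        y2 = [-0.6, -0.2, 0.1, -0.9, 0.3, -0.45, 0.7, -1.2]
        data = _two_arm_frame(
            [7.0] * 16, y2 + y2, arm=[0] * 8 + [1] * 8
        )
        assert karrison_method(data).p_value > 0.9

    def test_statistic_matches_exhaustive_enumeration(self):
        # 4 vs 4 distinct values: compare against all C(8,4)=70 assignments
        vals = [-1.3, -0.8, -0.55, -0.4, -0.25, 0.05, 0.3, 0.9]
        arm = [0, 1, 0, 1, 1, 0, 0, 1]
        data = _two_arm_frame([6.0] * 8, vals, arm=arm)
        model = KarrisonComparison().fit(data)
        assert model.method_ == "exact"

        x1 = [v for v, a in zip(vals, arm) if a == 1]
        ranks = {v: r + 1 for r, v in enumerate(sorted(vals))}
        u_obs = sum(ranks[v] for v in x1) - 4 * 5 / 2
        assert model.statistic_ == pytest.approx(u_obs)
        null_u = []
        for comb in itertools.combinations(vals, 4):
            null_u.append(sum(ranks[v] for v in comb) - 4 * 5 / 2)
        more_extreme = np.mean(
            [min(u, 16 - u) <= min(u_obs, 16 - u_obs) for u in null_u]
        )
        assert model.p_value_ == pytest.approx(more_extreme, abs=1e-12)

    def test_worst_value_imputation_and_exclusions(self):
        # one failure per arm imputed to the pooled maximum, dropouts removed
        y2 = [-0.5, -0.1, 0.4, -0.7, -0.2, 0.1, -0.3, -0.6]
        d1 = [1, 0, 0, 0, 1, 0, 0, 0]
        drop = [0, 0, 0, 1, 0, 0, 0, 0]
        data = _two_arm_frame(
            [7.0] * 8, y2, arm=[0, 0, 0, 0, 1, 1, 1, 1], d1=d1, drop=drop
        )
        model = KarrisonComparison().fit(data)
        observed = [y for y, f, dr in zip(y2, d1, drop) if not f and not dr]
        assert model.imputed_value_ == pytest.approx(max(observed))
        assert model.n_used_ == 7  # 8 minus one dropout

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y2 = rng.normal(-0.3, 0.6, 30)
        arm = np.repeat([0, 1], 15)
        d1 = (rng.random(30) < 0.2).astype(float)
        p_raw = karrison_method(_two_arm_frame([8.0] * 30, y2, arm, d1=d1)).p_value
        p_cub = karrison_method(_two_arm_frame([8.0] * 30, y2**3, arm, d1=d1)).p_value
        assert p_raw == pytest.approx(p_cub, abs=1e-12)

    def test_empty_arm_after_exclusions_errors(self):
        data = _two_arm_frame(
            [7.0] * 4, [-0.5, -0.2, 0.1, 0.3], arm=[0, 0, 0, 1], drop=[0, 0, 0, 1]
        )
        with pytest.raises(ValueError, match="empty"):
            karrison_method(data)


def test_comparators_run_on_simulated_comparative_trial():
    sc = Scenario(
        n_per_arm=75, comparative=True, x=0.175, psi=0.0,
        alpha_D=-1.155, beta_D=-0.5,
    )
    data = simulate_trial(sc, 11)
    for res in (logistic_method(data), karrison_method(data)):
        assert 0.0 <= res.p_value <= 1.0
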