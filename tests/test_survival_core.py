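"""Estimator unit tests against hand calculations and closed forms.

Frozen oracle values (computed independently before the estimators were
written):

* two-group log-rank on events {1,2} vs {3,4}, no censoring:
  chi2 = (O-E)^2/V = (2 - 5/6)^2 / (1/4 + 2/9) = 2.8823529...
* Cox fixture, group A events at 1,3,5 / group B at 2,4,6: grid search of the
  partial log-likelihood over [-5, 5] at step 1e-4 maximizes at
  beta = -0.6321.
"""

import math

import numpy as np
import pytest

from ipdrecon.datatypes import ValidationError
from ipdrecon.simulate import Exponential, SimParams, simulate_arm
from ipdrecon.pooling import pool_arms
from ipdrecon.survival import (
    cox_hr,
    km_estimate,
    km_survival_at,
    log_rank,
    median_survival,
    rmst,
    rmst_diff,
)

from conftest import make_ipd

LOGRANK_CHI2_ORACLE = 2.8823529411764715
COX_GRID_BETA_ORACLE = -0.6321


class TestKM:
    def test_single_event_drops_to_zero(self):
        km = km_estimate(make_ipd([5], [1]))
        assert km.surv.tolist() == [0.0]

    def test_hand_product_limit_with_censoring(self):
        """{(1,1),(2,0),(3,1)}: S(1) = 2/3; at t=3 only one subject remains, S(3) = 0."""
        km = km_estimate(make_ipd([1, 2, 3], [1, 0, 1]))
        assert km.event_times.tolist() == [1.0, 3.0]
        assert km.surv == pytest.approx([2 / 3, 0.0])
        assert km.n_risk.tolist() == [3, 1]

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(make_ipd([1, 2, 3], [0, 0, 0]))
        assert len(km.event_times) == 0
        assert km_survival_at(km, 10.0) == 1.0

    def test_censoring_tie_counted_at_risk(self):
        """A record censored at an event time is at risk for that event."""
        km = km_estimate(make_ipd([2, 2], [1, 0]))
        assert km.surv == pytest.approx([0.5])
        assert km.n_risk.tolist() == [2]


class TestMedian:
    def test_single_crossing(self):
        # 5 subjects, 3 events at t=10: S drops 1.0 -> 0.4
        km = km_estimate(make_ipd([10, 10, 10, 12, 12], [1, 1, 1, 0, 0]))
        assert median_survival(km).median == 10.0

    def test_never_crossing_is_undefined(self):
        km = km_estimate(make_ipd([1, 2, 3, 4, 5], [1, 0, 0, 0, 0]))
        m = median_survival(km)
        assert m.median is None and m.ci_high is None

    def test_large_sample_exponential(self):
        p = SimParams(n_per_arm=20000, hazard=Exponential(rate=math.log(2) / 12), seed=9)
        m = median_survival(km_estimate(simulate_arm(p, 0)))
        assert m.median == pytest.approx(12.0, abs=0.5)
        assert m.ci_low < m.median < m.ci_high


class TestLogRank:
    def test_identical_groups_null(self):
        a = make_ipd([1, 2, 3, 4], [1, 1, 0, 1], arm_id="a")
        chi2, p = log_rank(a, a)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_oracle(self):
        a = make_ipd([1, 2], [1, 1], arm_id="a")
        b = make_ipd([3, 4], [1, 1], arm_id="b")
        chi2, _ = log_rank(a, b)
        assert chi2 == pytest.approx(LOGRANK_CHI2_ORACLE, abs=1e-10)

    def test_symmetry_under_group_swap(self):
        a = make_ipd([1, 2, 5], [1, 1, 0], arm_id="a")
        b = make_ipd([3, 4], [1, 1], arm_id="b")
        assert log_rank(a, b) == pytest.approx(log_rank(b, a))

    def test_no_events_rejected(self):
        a = make_ipd([1, 2], [0, 0], arm_id="a")
        with pytest.raises(ValidationError):
            log_rank(a, a)


class TestCox:
    def test_identical_time_multisets_give_null(self):
        pooled = make_ipd([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        r = cox_hr(pooled, [0, 0, 0, 1, 1, 1])
        assert r.log_hr == pytest.approx(0.0, abs=1e-12)
        assert r.hr == pytest.approx(1.0)

    def test_grid_search_oracle(self):
        pooled = make_ipd([1, 3, 5, 2, 4, 6], [1, 1, 1, 1, 1, 1])
        r = cox_hr(pooled, [0, 0, 0, 1, 1, 1])
        assert r.converged
        assert r.log_hr == pytest.approx(COX_GRID_BETA_ORACLE, abs=1e-3)

    def test_rank_invariance_under_time_scaling(self):
        t = [1, 3, 5, 2, 4, 6]
        e = [1, 1, 0, 1, 1, 1]
        z = [0, 0, 0, 1, 1, 1]
        r1 = cox_hr(make_ipd(t, e), z)
        r2 = cox_hr(make_ipd([2 * x for x in t], e), z)
        assert r1.hr == pytest.approx(r2.hr, abs=1e-12)

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 100) + 0.01
        e = rng.integers(0, 2, 100)
        z = rng.integers(0, 2, 100)
        e[:4] = 1
        r = cox_hr(make_ipd(t, e), z.tolist())
        assert r.ci_low <= r.hr <= r.ci_high
        assert r.hr > 0

    def test_separation_flagged(self):
        # group 1 events all strictly before any group 0 event: monotone likelihood
        pooled = make_ipd([1, 2, 3, 10, 11, 12], [1, 1, 1, 1, 1, 1])
        r = cox_hr(pooled, [1, 1, 1, 0, 0, 0])
        assert not r.converged

    def test_score_agrees_with_logrank_on_large_sample(self):
        pa = SimParams(n_per_arm=500, hazard=Exponential(rate=0.06), seed=21,
                       admin_censor_month=30)
        pb = SimParams(n_per_arm=500, hazard=Exponential(rate=0.05), seed=21,
                       admin_censor_month=30)
        a, b = simulate_arm(pa, 0, arm_id="a"), simulate_arm(pb, 1, arm_id="b")
        _, p_lr = log_rank(a, b)
        pooled = pool_arms([a, b])
        r = cox_hr(pooled, [0] * a.size + [1] * b.size)
        assert abs(r.wald_p - p_lr) < 0.01


class TestRMST:
    def test_no_events_before_tau_gives_tau(self):
        km = km_estimate(make_ipd([5, 6, 7], [0, 0, 0]))
        assert rmst(km, 4.0).rmst == pytest.approx(4.0)

    def test_two_rectangles(self):
        # S = 1 on [0,1), 0.5 on [1,2): area to tau=2 is 1.5
        km = km_estimate(make_ipd([1, 2], [1, 1]))
        assert rmst(km, 2.0).rmst == pytest.approx(1.5)

    def test_closed_form_exponential(self):
        lam = math.log(2) / 12
        p = SimParams(n_per_arm=20000, hazard=Exponential(rate=lam), seed=13)
        r = rmst(km_estimate(simulate_arm(p, 0)), 12.0)
        expected = (1 - math.exp(-lam * 12)) / lam
        assert r.rmst == pytest.approx(expected, rel=0.01)

    def test_beyond_followup_rejected(self):
        km = km_estimate(make_ipd([1, 2], [1, 1]))
        with pytest.raises(ValidationError, match="extrapolat"):
            rmst(km, 5.0)

    def test_monotone_and_bounded_in_tau(self, median12_arm):
        km = km_estimate(median12_arm)
        taus = [3.0, 6.0, 12.0, 18.0]
        vals = [rmst(km, t).rmst for t in taus]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v <= t for v, t in zip(vals, taus))


class TestRMSTDiff:
    def test_self_comparison_null(self, median12_arm):
        r = rmst(km_estimate(median12_arm), 12.0)
        cmp = rmst_diff(r, r)
        assert cmp.diff == 0.0 and cmp.p == pytest.approx(1.0)

    def test_antisymmetry(self, median12_arm, rng):
        other = make_ipd(rng.exponential(14, 150) + 0.01, [1] * 150)
        ra = rmst(km_estimate(median12_arm), 12.0)
        rb = rmst(km_estimate(other), 12.0)
        ab, ba = rmst_diff(ra, rb), rmst_diff(rb, ra)
        assert ab.diff == pytest.approx(-ba.diff)
        assert ab.p == pytest.approx(ba.p)
        assert ab.ci_low == pytest.approx(-ba.ci_high)

    def test_tau_mismatch_rejected(self, median12_arm):
        km = km_estimate(median12_arm)
        with pytest.raises(ValidationError, match="tau"):
            rmst_diff(rmst(km, 6.0), rmst(km, 12.0))
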