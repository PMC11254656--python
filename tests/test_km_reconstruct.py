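"""Curve inversion: preprocessing, exact recovery, and fit audits."""

import math

import numpy as np
import pytest

from ipdrecon.datatypes import (
    CleanCurve,
    DigitizedCurve,
    RiskEntry,
    RiskTable,
    ValidationError,
)
from ipdrecon.reconstruct import (
    preprocess_curve,
    reconstruct_ipd,
    reconstruction_fit,
)
from ipdrecon.simulate import (
    Exponential,
    RenderParams,
    SimParams,
    exact_risk_table,
    render_km_curve,
    render_risk_table,
    simulate_arm,
)
from ipdrecon.survival import km_estimate, km_survival_at

from conftest import make_ipd


def curve_of(points, arm_id="arm"):
    return DigitizedCurve(arm_id=arm_id, endpoint="OS", points=tuple(points))


class TestPreprocess:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(0, 1), (2, 0.9), (1, 0.95)], ((0, 1), (1, 0.95), (2, 0.9))),
            ([(0, 1), (1, 0.8), (2, 0.81)], ((0, 1), (1, 0.8), (2, 0.8))),
            ([(1, 0.9)], ((0, 1), (1, 0.9))),
        ],
    )
    def test_reorder_monotonize_origin(self, raw, expected):
        clean = preprocess_curve(curve_of(raw))
        assert clean.points == tuple((float(a), float(b)) for a, b in expected)

    def test_audit_counts(self):
        clean = preprocess_curve(curve_of([(0, 1), (2, 0.9), (1, 0.95), (3, 0.92)]))
        assert clean.n_reordered == 1 and clean.n_clamped == 1

    def test_single_distinct_time_rejected(self):
        with pytest.raises(ValidationError):
            preprocess_curve(curve_of([(0.0, 1.0), (0.0, 0.9)]))


class TestReconstruct:
    def test_no_censoring_inversion(self):
        """Three uncensored events and only an enrollment count invert exactly."""
        clean = preprocess_curve(curve_of([(0, 1), (1, 2 / 3), (2, 1 / 3), (3, 0.0)]))
        risk = RiskTable(arm_id="arm", entries=(RiskEntry(0, 3),))
        ipd = reconstruct_ipd(clean, risk)
        assert sorted((r.time, r.event) for r in ipd.records) == [(1, 1), (2, 1), (3, 1)]

    def test_noiseless_dense_risk_is_exact(self, median12_arm, noiseless_render):
        curve = preprocess_curve(render_km_curve(median12_arm, noiseless_render))
        risk = exact_risk_table(median12_arm)
        rec = reconstruct_ipd(curve, risk)
        fit = reconstruction_fit(rec, curve, risk)
        assert fit.max_abs_dev <= 1e-9
        assert rec.size == median12_arm.size
        assert rec.n_events == median12_arm.n_events

    def test_noiseless_sparse_risk_close_to_truth(self, median12_arm, noiseless_render):
        """Risk table every 3 months only: KM within 0.01 of the true-IPD KM."""
        curve = preprocess_curve(render_km_curve(median12_arm, noiseless_render))
        risk = render_risk_table(median12_arm, RenderParams(risk_interval_months=3))
        rec = reconstruct_ipd(curve, risk)
        km_true = km_estimate(median12_arm)
        km_rec = km_estimate(rec)
        devs = [
            abs(km_survival_at(km_rec, t) - s)
            for t, s in zip(km_true.event_times, km_true.surv)
        ]
        assert max(devs) <= 0.01

    def test_risk_counts_honored_within_one(self, median12_arm):
        rp = RenderParams(risk_interval_months=3, coordinate_noise_sd=0.005)
        curve = preprocess_curve(render_km_curve(median12_arm, rp, seed=3))
        risk = render_risk_table(median12_arm, rp)
        rec = reconstruct_ipd(curve, risk)
        times = np.array([r.time for r in rec.records])
        for t, n_pub in zip(risk.times, risk.counts):
            assert abs(int(np.sum(times >= t)) - n_pub) <= 1

    def test_count_conservation(self, median12_arm):
        rp = RenderParams(risk_interval_months=3, coordinate_noise_sd=0.005)
        curve = preprocess_curve(render_km_curve(median12_arm, rp, seed=4))
        risk = render_risk_table(median12_arm, rp)
        rec = reconstruct_ipd(curve, risk)
        assert rec.size == risk.enrollment

    def test_event_total_calibration(self, median12_arm, noiseless_render):
        curve = preprocess_curve(render_km_curve(median12_arm, noiseless_render))
        risk = render_risk_table(median12_arm, RenderParams(risk_interval_months=3))
        target = median12_arm.n_events
        rec = reconstruct_ipd(curve, risk, total_events=target)
        assert rec.n_events == target

    def test_determinism(self, median12_arm):
        rp = RenderParams(risk_interval_months=3, coordinate_noise_sd=0.005)
        curve = preprocess_curve(render_km_curve(median12_arm, rp, seed=5))
        risk = render_risk_table(median12_arm, rp)
        assert reconstruct_ipd(curve, risk) == reconstruct_ipd(curve, risk)


class TestReconstructionFit:
    def setup_method(self):
        self.ipd = make_ipd([1, 2, 3, 4], [1, 1, 0, 1])
        km = km_estimate(self.ipd)
        pts = [(0.0, 1.0)] + [(float(t), float(s)) for t, s in zip(km.event_times, km.surv)]
        self.curve = preprocess_curve(curve_of(pts))
        self.risk = RiskTable(arm_id="arm", entries=(RiskEntry(0, 4), RiskEntry(2.5, 2)))

    def test_exact_ipd_has_zero_deviation(self):
        fit = reconstruction_fit(self.ipd, self.curve, self.risk)
        assert fit.max_abs_dev == 0.0 and fit.rmse == 0.0

    def test_shifted_curve_detected(self):
        shifted = preprocess_curve(
            curve_of([(t, min(s + 0.05, 1.0)) for t, s in self.curve.points])
        )
        fit = reconstruction_fit(self.ipd, shifted, self.risk)
        assert fit.max_abs_dev >= 0.04

    def test_residual_rows_match_risk_entries(self):
        fit = reconstruction_fit(self.ipd, self.curve, self.risk)
        assert len(fit.risk_residuals) == 2
        assert fit.risk_residuals[0] == (0.0, 4, 4)
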