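"""Pooling and group-vs-control orchestration."""

import json
import math

import numpy as np
import pytest

from ipdrecon.datatypes import ValidationError
from ipdrecon.io import load_run_config
from ipdrecon.pooling import compare_groups, pool_arms, run_pipeline
from ipdrecon.simulate import Exponential, SimParams, simulate_arm
from ipdrecon.survival import cox_hr

from conftest import make_ipd, write_trial_inputs


class TestPoolArms:
    def test_sizes_sum(self):
        members = [
            make_ipd(np.arange(1, n + 1), [1] * n, arm_id=f"a{i}")
            for i, n in enumerate([201, 268, 230, 201])
        ]
        pooled = pool_arms(members, name="PD-L1")
        assert pooled.size == 900
        assert pooled.sources[0] == "a0" and pooled.sources[-1] == "a3"

    def test_single_member_identity(self):
        a = make_ipd([1, 2, 3], [1, 0, 1], arm_id="a")
        pooled = pool_arms([a], name="g")
        assert pooled.records == a.records

    def test_event_conservation(self):
        a = make_ipd([1, 2], [1, 0], arm_id="a")
        b = make_ipd([3, 4, 5], [1, 1, 0], arm_id="b")
        assert pool_arms([a, b]).n_events == a.n_events + b.n_events

    def test_endpoint_mismatch_rejected(self):
        a = make_ipd([1], [1], endpoint="OS")
        b = make_ipd([1], [1], endpoint="PFS")
        with pytest.raises(ValidationError, match="endpoint"):
            pool_arms([a, b])


class TestCompareGroups:
    def test_self_comparison_is_null(self, median12_arm):
        rep = compare_groups(median12_arm, median12_arm, taus=[6.0, 12.0])
        assert rep.cox.hr == pytest.approx(1.0, abs=1e-9)
        for r in rep.rmst_comparisons:
            assert r.diff == 0.0

    def test_taus_all_reported(self, median12_arm):
        rep = compare_groups(median12_arm, median12_arm, taus=[6.0, 12.0])
        assert [r.tau for r in rep.rmst_comparisons] == [6.0, 12.0]

    def test_known_hazard_ratio_recovered(self):
        lam = math.log(2) / 12
        pa = SimParams(n_per_arm=500, hazard=Exponential(rate=lam), seed=31,
                       admin_censor_month=36)
        pb = SimParams(n_per_arm=500, hazard=Exponential(rate=0.7 * lam), seed=31,
                       admin_censor_month=36)
        ctrl = simulate_arm(pa, 0, arm_id="ctrl")
        grp = simulate_arm(pb, 1, arm_id="grp")
        rep = compare_groups(grp, ctrl, taus=[12.0])
        assert rep.cox.hr == pytest.approx(0.7, abs=0.1)

    def test_direction_symmetry(self, median12_arm, rng):
        other = make_ipd(rng.exponential(16, 300) + 0.01, [1] * 300, arm_id="o")
        fwd = compare_groups(other, median12_arm, taus=[6.0]).cox
        rev = compare_groups(median12_arm, other, taus=[6.0]).cox
        assert fwd.hr == pytest.approx(1.0 / rev.hr, abs=1e-9)


ARM_SPECS = [
    ("ctrl1", 150, Exponential(rate=math.log(2) / 12)),
    ("ctrl2", 150, Exponential(rate=math.log(2) / 12)),
    ("novel", 200, Exponential(rate=0.7 * math.log(2) / 12)),
    ("same", 150, Exponential(rate=math.log(2) / 12)),
]
GROUPS = [
    ("control", ("ctrl1", "ctrl2"), "control"),
    ("novel", ("novel",), "experimental"),
    ("same", ("same",), "experimental"),
]


@pytest.fixture(scope="module")
def run(tmp_path_factory):
    d = tmp_path_factory.mktemp("pipeline")
    config_path, truth = write_trial_inputs(d, ARM_SPECS, GROUPS, seed=42)
    config = load_run_config(config_path)
    out = d / "out"
    report = run_pipeline(config, out_dir=out)
    return config, report, out, truth


class TestRunPipeline:
    def test_one_report_per_non_control_group(self, run):
        _, report, _, _ = run
        assert len(report["comparisons"]["OS"]) == 2
        assert report["n_comparisons"] == 2

    def test_pooled_sizes_conserve_reconstructions(self, run):
        _, report, _, _ = run
        by_group = {c["group"]: c for c in report["comparisons"]["OS"]}
        assert by_group["novel"]["n_group"] == 200
        assert by_group["novel"]["n_control"] == 300

    def test_true_advantage_detected(self, run):
        _, report, _, _ = run
        novel = next(c for c in report["comparisons"]["OS"] if c["group"] == "novel")
        assert novel["cox"]["hr"] < 1.0
        assert novel["cox"]["p"] < 0.05

    def test_null_group_not_flagged(self, run):
        _, report, _, _ = run
        same = next(c for c in report["comparisons"]["OS"] if c["group"] == "same")
        assert same["cox"]["p"] > 0.05

    def test_reconstruction_fits_audited(self, run):
        _, report, _, _ = run
        fits = report["reconstruction_fits"]["OS"]
        assert set(fits) == {"ctrl1", "ctrl2", "novel", "same"}
        assert all(f["max_abs_dev"] <= 0.02 for f in fits.values())

    def test_outputs_written(self, run):
        _, _, out, _ = run
        assert (out / "report.json").exists()
        assert (out / "summary.md").exists()
        assert (out / "manifest.json").exists()
        assert (out / "ipd_novel_OS.csv").exists()

    def test_rerun_is_byte_identical(self, run, tmp_path):
        config, _, out, _ = run
        out2 = tmp_path / "out2"
        run_pipeline(config, out_dir=out2)
        assert (out / "report.json").read_bytes() == (out2 / "report.json").read_bytes()
        m1 = json.loads((out / "manifest.json").read_text())
        m2 = json.loads((out2 / "manifest.json").read_text())
        m1.pop("timestamp"), m2.pop("timestamp")
        assert m1 == m2

    def test_missing_curve_aborts_naming_arm(self, run, tmp_path):
        config, _, _, _ = run
        import dataclasses

        bad = dataclasses.replace(
            config.studies[0],
            curves={"OS": tmp_path / "nope.csv"},
        )
        cfg = dataclasses.replace(config, studies=(bad,) + config.studies[1:])
        with pytest.raises((ValidationError, FileNotFoundError)):
            run_pipeline(cfg)
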