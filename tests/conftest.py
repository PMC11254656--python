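import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ipdrecon.datatypes import IPDRecord, IPDSet
from ipdrecon.simulate import Exponential, RenderParams, SimParams, simulate_arm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ipd(times, events, arm_id="arm", endpoint="OS", provenance="reconstructed"):
    return IPDSet(
        arm_id=arm_id,
        endpoint=endpoint,
        records=tuple(IPDRecord(float(t), int(e)) for t, e in zip(times, events)),
        provenance=provenance,
    )


def random_ipd(rng, n=100, arm_id="arm"):
    """A censored exponential cohort with heavy ties (rounded times)."""
    t = rng.exponential(10.0, n).round(1) + 0.1
    e = rng.integers(0, 2, n)
    if e.sum() == 0:
        e[0] = 1
    return make_ipd(t, e, arm_id=arm_id), t, e


@pytest.fixture
def rng():
    return np.random.default_rng(20240704)


@pytest.fixture
def median12_arm():
    """n=200 exponential arm with 12-month median, accrual and dropout."""
    params = SimParams(
        n_per_arm=200,
        hazard=Exponential(rate=math.log(2) / 12),
        accrual_months=12.0,
        admin_censor_month=24.0,
        dropout_rate=0.01,
        seed=5,
    )
    return simulate_arm(params, 0, arm_id="arm")


@pytest.fixture
def noiseless_render():
    return RenderParams(coordinate_noise_sd=0.0)


def write_trial_inputs(dirpath, arm_specs, groups, seed=0, noise_sd=0.005,
                       risk_interval=3.0, endpoint="OS", rmst_taus=(6.0, 12.0)):
    """Simulate arms, render digitizer-style inputs and write a run config.

    ``arm_specs`` is a list of (arm_id, n, hazard) tuples; ``groups`` a list of
    (name, member_ids, role). Returns (config_path, true_ipd_by_arm).
    """
    import yaml

    from ipdrecon.io import write_ipd_csv  # noqa: F401  (round-trip helpers live here)
    from ipdrecon.simulate import render_km_curve, render_risk_table

    dirpath.mkdir(parents=True, exist_ok=True)
    rp = RenderParams(risk_interval_months=risk_interval, coordinate_noise_sd=noise_sd)
    studies = []
    truth = {}
    for idx, (arm_id, n, hazard) in enumerate(arm_specs):
        params = SimParams(
            n_per_arm=n, hazard=hazard, accrual_months=10.0,
            admin_censor_month=28.0, dropout_rate=0.005, seed=seed,
        )
        ipd = simulate_arm(params, idx, arm_id=arm_id, endpoint=endpoint)
        truth[arm_id] = ipd
        curve = render_km_curve(ipd, rp, seed=seed * 1000 + idx)
        risk = render_risk_table(ipd, rp)
        with open(dirpath / f"{arm_id}_curve.csv", "w") as fh:
            fh.write("time_months,survival\n")
            for t, s in curve.points:
                fh.write(f"{t!r},{s!r}\n")
        with open(dirpath / f"{arm_id}_risk.csv", "w") as fh:
            fh.write("time_months,n_at_risk\n")
            for e in risk.entries:
                fh.write(f"{e.time!r},{e.n_at_risk}\n")
        studies.append(
            {
                "arm_id": arm_id,
                "enrollment": n,
                "curves": {endpoint: f"{arm_id}_curve.csv"},
                "risk_tables": {endpoint: f"{arm_id}_risk.csv"},
                "total_events": {endpoint: ipd.n_events},
            }
        )
    cfg = {
        "seed": seed,
        "alpha": 0.05,
        "rmst_taus": list(rmst_taus),
        "endpoints": [endpoint],
        "control_group": next(name for name, _, role in groups if role == "control"),
        "studies": studies,
        "groups": [
            {"name": name, "members": list(members), "role": role}
            for name, members, role in groups
        ],
    }
    config_path = dirpath / "run.yaml"
    config_path.write_text(yaml.safe_dump(cfg), encoding="utf-8")
    return config_path, truth
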