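"""Synthetic two-arm trial generator and figure renderer.

Published trials expose only a Kaplan-Meier figure and a numbers-at-risk
table, so validating a curve-inversion pipeline needs data where the truth is
known. This module simulates per-patient data from parametric hazards
(exponential, Weibull, piecewise-exponential — the last specifically to
produce the delayed-separation and crossing curves typical of immunotherapy),
applies uniform accrual with a single administrative cutoff plus random
dropout, and then *renders* the simulated arm back into the artifacts a plot
digitizer would produce: step coordinates with optional Gaussian noise on the
survival axis, and an at-risk table on a regular calendar grid.

Reproducibility contract: one integer seed drives everything; per-arm streams
are derived as ``default_rng([seed, arm_index])``, so identical
(params, seed) always yield identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import IPDRecord, IPDSet, RiskEntry, RiskTable, DigitizedCurve, ValidationError
from .io import AECountRow
from .survival import km_estimate

__all__ = [
    "HazardModel",
    "Exponential",
    "Weibull",
    "PiecewiseExponential",
    "SimParams",
    "RenderParams",
    "simulate_arm",
    "render_km_curve",
    "render_risk_table",
    "simulate_ae_table",
    "hazard_from_dict",
]


class HazardModel:
    """Base for parametric event-time models; subclasses implement ``sample``."""

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class Exponential(HazardModel):
    """Constant hazard ``rate`` per month; median = ln 2 / rate."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("rate must be positive")

    def sample(self, rng, n):
        return rng.exponential(1.0 / self.rate, size=n)


@dataclass(frozen=True)
class Weibull(HazardModel):
    """S(t) = exp(-(t/scale)^shape); shape > 1 gives an increasing hazard."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValidationError("shape and scale must be positive")

    def sample(self, rng, n):
        return self.scale * rng.weibull(self.shape, size=n)


@dataclass(frozen=True)
class PiecewiseExponential(HazardModel):
    """Piecewise-constant hazard: ``rates[i]`` applies on ``[change_times[i-1], change_times[i])``.

    ``len(rates) == len(change_times) + 1``; the last rate extends to infinity.
    Sampling inverts the piecewise-linear cumulative hazard of a unit
    exponential draw.
    """

    change_times: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        ct = tuple(float(t) for t in self.change_times)
        rs = tuple(float(r) for r in self.rates)
        object.__setattr__(self, "change_times", ct)
        object.__setattr__(self, "rates", rs)
        if len(rs) != len(ct) + 1:
            raise ValidationError("need len(rates) == len(change_times) + 1")
        if any(r <= 0 for r in rs):
            raise ValidationError("rates must be positive")
        if any(b <= a for a, b in zip(ct, ct[1:])) or (ct and ct[0] <= 0):
            raise ValidationError("change_times must be positive and increasing")

    def sample(self, rng, n):
        e = rng.exponential(1.0, size=n)  # unit cumulative-hazard draws
        bounds = np.array([0.0, *self.change_times])
        rates = np.array(self.rates)
        # cumulative hazard at each boundary
        seg = np.diff(bounds) * rates[:-1]
        H = np.concatenate([[0.0], np.cumsum(seg)])
        out = np.empty(n)
        for i, ei in enumerate(e):
            k = int(np.searchsorted(H, ei, side="right")) - 1
            k = min(k, len(rates) - 1)
            out[i] = bounds[k] + (ei - H[k]) / rates[k]
        return out


def hazard_from_dict(spec: dict) -> HazardModel:
    """Build a hazard model from a config mapping (``model`` key selects the family)."""
    kind = spec["model"]
    if kind == "exponential":
        return Exponential(rate=float(spec["rate"]))
    if kind == "weibull":
        return Weibull(shape=float(spec["shape"]), scale=float(spec["scale"]))
    if kind == "piecewise":
        return PiecewiseExponential(
            change_times=tuple(spec["change_times"]), rates=tuple(spec["rates"])
        )
    raise ValidationError(f"unknown hazard model {kind!r}")


@dataclass(frozen=True)
class SimParams:
    """Design of one simulated arm.

    ``accrual_months`` spreads enrollment uniformly before a single
    administrative cutoff at ``admin_censor_month`` (on the calendar scale);
    ``dropout_rate`` is an exponential loss-to-follow-up hazard per month.
    """

    n_per_arm: int
    hazard: HazardModel
    accrual_months: float = 0.0
    admin_censor_month: float = math.inf
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValidationError("n_per_arm must be positive")
        if self.accrual_months < 0 or self.dropout_rate < 0:
            raise ValidationError("accrual_months and dropout_rate must be >= 0")
        if not self.admin_censor_month > 0:
            raise ValidationError("admin_censor_month must be positive")
        if not math.isfinite(self.dropout_rate):
            raise ValidationError("dropout_rate must be finite")


@dataclass(frozen=True)
class RenderParams:
    """How the simulated arm is turned into digitizer-style artifacts.

    ``coordinate_noise_sd`` is Gaussian noise on the survival axis only —
    time-axis error is second-order for a step curve and leaving times exact
    keeps the renderer invertible for round-trip tests.
    """

    risk_interval_months: float = 3.0
    coordinate_noise_sd: float = 0.005
    max_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.risk_interval_months <= 0:
            raise ValidationError("risk_interval_months must be positive")
        if not 0 <= self.coordinate_noise_sd < 0.05:
            raise ValidationError("coordinate_noise_sd must be in [0, 0.05)")


_TINY = 1e-9


def simulate_arm(
    params: SimParams, arm_index: int, arm_id: str = "", endpoint: str = "OS"
) -> IPDSet:
    """Simulate per-patient (time, event) records for one arm.

    Each subject draws a latent event time from the arm's hazard model and is
    censored at the earlier of exponential dropout and the administrative
    cutoff minus their uniform accrual offset. Deterministic given
    (params, arm_index).
    """
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, arm_index])
    n = params.n_per_arm
    latent = params.hazard.sample(rng, n)
    accrual = rng.uniform(0.0, params.accrual_months, size=n) if params.accrual_months > 0 else np.zeros(n)
    admin = params.admin_censor_month - accrual if math.isfinite(params.admin_censor_month) else np.full(n, math.inf)
    dropout = (
        rng.exponential(1.0 / params.dropout_rate, size=n)
        if params.dropout_rate > 0
        else np.full(n, math.inf)
    )
    censor = np.minimum(admin, dropout)
    time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)
    time = np.maximum(time, _TINY)  # follow-up times are strictly positive
    records = tuple(IPDRecord(float(t), int(e)) for t, e in zip(time, event))
    return IPDSet(
        arm_id=arm_id or f"sim_arm_{arm_index}",
        endpoint=endpoint,
        records=records,
        provenance="simulated",
    )


def render_km_curve(ipd: IPDSet, rp: RenderParams, seed: int = 0) -> DigitizedCurve:
    """Render an arm's exact KM step values as digitizer-style coordinates.

    Steps are optionally thinned to ``max_points``, perturbed with Gaussian
    noise on the survival scale, clipped to [0, 1] and re-monotonized with a
    running minimum. With ``coordinate_noise_sd = 0`` the output is the exact
    product-limit step function.
    """
    km = km_estimate(ipd)
    times = np.concatenate([[0.0], km.event_times])
    surv = np.concatenate([[1.0], km.surv])
    if rp.max_points is not None and len(times) > rp.max_points:
        keep = np.unique(
            np.concatenate(
                [[0, len(times) - 1], np.linspace(0, len(times) - 1, rp.max_points).round().astype(int)]
            )
        )
        times, surv = times[keep], surv[keep]
    if rp.coordinate_noise_sd > 0:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 104729])
        noisy = surv + rng.normal(0.0, rp.coordinate_noise_sd, size=len(surv))
        noisy[0] = 1.0  # the origin of a published curve is never ambiguous
        noisy = np.clip(noisy, 0.0, 1.0)
        surv = np.minimum.accumulate(noisy)
    pts = tuple(zip(times.tolist(), surv.tolist()))
    return DigitizedCurve(arm_id=ipd.arm_id, endpoint=ipd.endpoint, points=pts)


def render_risk_table(ipd: IPDSet, rp: RenderParams) -> RiskTable:
    """At-risk counts on the calendar grid 0, r, 2r, ... up to the last observed time."""
    times = np.asarray([r.time for r in ipd.records])
    tmax = float(times.max())
    grid = [0.0]
    while grid[-1] + rp.risk_interval_months <= tmax:
        grid.append(grid[-1] + rp.risk_interval_months)
    entries = tuple(RiskEntry(t, int(np.sum(times >= t))) for t in grid)
    return RiskTable(arm_id=ipd.arm_id, entries=entries, total_events=ipd.n_events)


def exact_risk_table(ipd: IPDSet) -> RiskTable:
    """At-risk counts at time 0 and every distinct event time.

    This is the densest informative table a figure could print; with a
    noiseless rendered curve it makes the inversion exact.
    """
    km = km_estimate(ipd)
    times = np.asarray([r.time for r in ipd.records])
    grid = np.concatenate([[0.0], km.event_times])
    entries = tuple(RiskEntry(float(t), int(np.sum(times >= t))) for t in grid)
    return RiskTable(arm_id=ipd.arm_id, entries=entries, total_events=ipd.n_events)


def simulate_ae_table(
    incidences: dict, n: int, seed: int, study: str = "sim", arm_id: str = "sim_arm"
) -> list[AECountRow]:
    """Binomial adverse-event counts per category at the stated incidences."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 15485863])
    rows = []
    for category, p in incidences.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"incidence for {category} outside [0, 1]")
        rows.append(
            AECountRow(
                study=study,
                arm_id=arm_id,
                category=category,
                numerator=int(rng.binomial(n, p)),
                denominator=n,
            )
        )
    return rows
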