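"""Core data model shared by every pipeline stage.

The pipeline moves between three representations of a trial arm:

* :class:`DigitizedCurve` — the step coordinates of a published Kaplan-Meier
  figure, as produced by a plot digitizer (or by the synthetic renderer).
* :class:`RiskTable` — the numbers-at-risk printed under the figure, the side
  constraint that makes curve inversion well-posed.
* :class:`IPDSet` — per-patient ``(time, event)`` records, either simulated
  with known ground truth or reconstructed from a curve plus risk table.

All times are in months. Survival probabilities live on the [0, 1] scale
internally; percent-scale input is normalized at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

__all__ = [
    "Endpoint",
    "DigitizedCurve",
    "CleanCurve",
    "RiskEntry",
    "RiskTable",
    "IPDRecord",
    "IPDSet",
    "ValidationError",
]

Endpoint = Literal["OS", "PFS"]

VALID_ENDPOINTS = ("OS", "PFS")


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Step coordinates of a published survival curve.

    ``points`` is an ordered list of ``(time_months, survival)`` pairs. Raw
    digitizer output may be unsorted, non-monotone or percent-scaled; use
    :func:`ipdrecon.reconstruct.preprocess_curve` to obtain a curve satisfying
    the strict invariants (strictly increasing times, non-increasing survival,
    origin at ``(0, 1.0)``).
    """

    arm_id: str
    endpoint: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if len(self.points) == 0:
            raise ValidationError("curve has no points")
        for t, s in self.points:
            if t < 0:
                raise ValidationError(f"negative time {t} in curve {self.arm_id}")
        object.__setattr__(self, "points", tuple((float(t), float(s)) for t, s in self.points))

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.points)

    @property
    def survival(self) -> tuple[float, ...]:
        return tuple(s for _, s in self.points)


@dataclass(frozen=True)
class CleanCurve(DigitizedCurve):
    """A :class:`DigitizedCurve` after preprocessing, with an audit trail.

    ``n_clamped`` counts survival values moved onto [0, 1] or lowered by the
    running-minimum pass; ``n_reordered`` counts input points that were not in
    time order.
    """

    n_clamped: int = 0
    n_reordered: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        pts = self.points
        if pts[0] != (0.0, 1.0):
            raise ValidationError("clean curve must start at (0, 1.0)")
        for (t0, s0), (t1, s1) in zip(pts, pts[1:]):
            if t1 <= t0:
                raise ValidationError("clean curve times must be strictly increasing")
            if s1 > s0:
                raise ValidationError("clean curve survival must be non-increasing")
        for _, s in pts:
            if not 0.0 <= s <= 1.0:
                raise ValidationError("clean curve survival outside [0, 1]")


@dataclass(frozen=True)
class RiskEntry:
    time: float
    n_at_risk: int


@dataclass(frozen=True)
class RiskTable:
    """Published numbers-at-risk at calendar times for one arm.

    The first entry must be at time 0 and equal the arm's enrollment.
    ``total_events`` optionally carries the published event total (e.g. from a
    trial-characteristics table); the reconstruction uses it to calibrate
    censoring after the last risk time.
    """

    arm_id: str
    entries: tuple[RiskEntry, ...]
    total_events: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValidationError("risk table has no entries")
        ent = tuple(RiskEntry(float(e.time), int(e.n_at_risk)) for e in self.entries)
        object.__setattr__(self, "entries", ent)
        if ent[0].time != 0.0:
            raise ValidationError("first risk entry must be at time 0")
        prev_t, prev_n = None, None
        for e in ent:
            if e.time < 0:
                raise ValidationError("negative risk time")
            if e.n_at_risk < 0:
                raise ValidationError("negative n_at_risk")
            if prev_t is not None:
                if e.time <= prev_t:
                    raise ValidationError("risk times must be strictly increasing")
                if e.n_at_risk > prev_n:
                    raise ValidationError(
                        f"n_at_risk increased from {prev_n} to {e.n_at_risk} at t={e.time}"
                    )
            prev_t, prev_n = e.time, e.n_at_risk
        if self.total_events is not None and self.total_events < 0:
            raise ValidationError("total_events must be non-negative")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.entries)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(e.n_at_risk for e in self.entries)

    @property
    def enrollment(self) -> int:
        return self.entries[0].n_at_risk


@dataclass(frozen=True)
class IPDRecord:
    """One patient: follow-up time in months and event indicator (1=event, 0=censored)."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if not (self.time > 0 and self.time < float("inf")):
            raise ValidationError(f"record time must be finite and > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class IPDSet:
    """Per-patient records for one arm and endpoint.

    ``provenance`` records whether the data came from the simulator or from
    curve inversion. ``sources`` (optional, same length as ``records``) tags
    each record with the arm it originated from; pooling fills it in so a
    pooled set remembers its member arms.
    """

    arm_id: str
    endpoint: str
    records: tuple[IPDRecord, ...]
    provenance: Literal["simulated", "reconstructed"] = "reconstructed"
    sources: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if len(self.records) == 0:
            raise ValidationError("IPDSet must contain at least one record")
        if self.provenance not in ("simulated", "reconstructed"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.sources is not None and len(self.sources) != len(self.records):
            raise ValidationError("sources must align with records")

    @property
    def size(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return sum(r.event for r in self.records)

    def times_events(self):
        """Return (times, events) as parallel lists — convenience for estimators."""
        return [r.time for r in self.records], [r.event for r in self.records]
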