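"""Inversion of a digitized Kaplan-Meier curve into individual patient data.

The algorithm is the interval-by-interval inversion used for published-curve
meta-analysis: between consecutive numbers-at-risk times, an integer number
of censorings is hypothesized and spread uniformly over the interval
interior, event multiplicities at each digitized step are chosen so that the
re-estimated product-limit curve tracks the published step values, and the
censoring count is selected so that the implied number at risk at the next
published time matches the printed one. The search over censoring counts is a
monotone integer search from zero upward; ties break toward fewer censorings.

Event multiplicities are allocated sequentially against the *running
reconstructed* survival (not the raw published ratios), so integer rounding
is self-correcting and cannot drift within an interval.

After the last risk time, events are still read off the curve but censoring
is assumed only at the final curve time; when a published event total is
supplied (e.g. from a trial-characteristics table) a calibration pass flips
records in that final block so the reconstructed event count honors it
whenever arithmetically feasible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatypes import (
    CleanCurve,
    DigitizedCurve,
    IPDRecord,
    IPDSet,
    RiskTable,
    ValidationError,
)
from .survival import km_estimate, km_survival_at

log = logging.getLogger(__name__)

__all__ = [
    "preprocess_curve",
    "reconstruct_ipd",
    "reconstruction_fit",
    "ReconstructionFit",
    "ReconstructionError",
]


class ReconstructionError(ValueError):
    """The curve/risk-table pair admits no consistent patient-level data."""


@dataclass(frozen=True)
class ReconstructionFit:
    """Quality audit of a reconstruction against its inputs.

    ``max_abs_dev``/``rmse`` compare the re-estimated KM step function with
    the digitized survival values at every curve time;
    ``risk_residuals`` lists (time, published n, reconstructed n) at every
    risk-table time.
    """

    max_abs_dev: float
    rmse: float
    risk_residuals: tuple[tuple[float, int, int], ...]
    events_total: int

    def __post_init__(self) -> None:
        if not self.max_abs_dev >= self.rmse >= 0:
            raise ValidationError("expected max_abs_dev >= rmse >= 0")


def preprocess_curve(raw: DigitizedCurve) -> CleanCurve:
    """Normalize raw digitizer output into a valid survival step curve.

    Sorts by time, collapses duplicate times to their minimum survival, clamps
    survival onto [0, 1], enforces monotone non-increase by running minimum,
    and prepends the (0, 1.0) origin if absent. The audit counts how many
    points were clamped/lowered and how many were out of time order.
    """
    pts = list(raw.points)
    n_reordered = sum(1 for a, b in zip(pts, pts[1:]) if b[0] < a[0])
    pts.sort(key=lambda p: p[0])
    collapsed: list[tuple[float, float]] = []
    for t, s in pts:
        if collapsed and collapsed[-1][0] == t:
            collapsed[-1] = (t, min(collapsed[-1][1], s))
        else:
            collapsed.append((t, s))
    n_clamped = 0
    out: list[tuple[float, float]] = []
    running = 1.0
    for t, s in collapsed:
        s2 = min(max(s, 0.0), 1.0)
        if s2 != s:
            n_clamped += 1
            s = s2
        if s > running:
            n_clamped += 1
            s = running
        running = s
        out.append((t, s))
    if not out or out[0][0] != 0.0:
        out.insert(0, (0.0, 1.0))
    elif out[0] != (0.0, 1.0):
        n_clamped += 1
        out[0] = (0.0, 1.0)
    if len(out) < 2:
        raise ValidationError("curve needs at least 2 distinct time points")
    return CleanCurve(
        arm_id=raw.arm_id,
        endpoint=raw.endpoint,
        points=tuple(out),
        n_clamped=n_clamped,
        n_reordered=n_reordered,
    )


def _replay_interval(
    pts: list[tuple[float, float]],
    n_start: int,
    s_start: float,
    t_lo: float,
    t_hi: float,
    c: int,
):
    """Allocate events against the published steps with c censorings spread
    uniformly over (t_lo, t_hi); returns implied n at t_hi, running S, events,
    censor times."""
    cen_times = [t_lo + (j + 1) * (t_hi - t_lo) / (c + 1) for j in range(c)]
    n, S = n_start, s_start
    events: list[tuple[float, int]] = []
    ci = 0
    for tk, sk in pts:
        while ci < len(cen_times) and cen_times[ci] < tk and n > 0:
            n -= 1
            ci += 1
        if n <= 0 or S <= 0:
            continue
        d = int(round(n * (1.0 - sk / S)))
        d = min(max(d, 0), n)
        if d > 0:
            S *= 1.0 - d / n
            n -= d
            events.append((tk, d))
    # censorings scheduled after the last event but inside the interval
    remaining = len(cen_times) - ci
    drop = min(remaining, n)
    n -= drop
    return n, S, events, cen_times[: ci + drop]


def reconstruct_ipd(
    curve: CleanCurve, risk: RiskTable, total_events: Optional[int] = None
) -> IPDSet:
    """Invert a preprocessed curve plus risk table into per-patient records.

    Returns one record per enrolled subject (the risk table's time-0 count).
    ``total_events`` overrides ``risk.total_events`` when given. The
    reconstruction is fully deterministic.

    Raises :class:`ReconstructionError` when the inputs are inconsistent
    (curve starting after the risk span, or an interval whose published count
    cannot be approached at all).
    """
    if total_events is None:
        total_events = risk.total_events
    rt = list(risk.times)
    rn = list(risk.counts)
    if len(rt) == 1:
        log.warning(
            "%s: no numbers-at-risk beyond time 0 — censoring will be assumed "
            "only at the end of the curve%s",
            curve.arm_id,
            "" if total_events is not None else "; supply total_events to calibrate the tail",
        )
    last_curve_t = curve.points[-1][0]

    events: list[tuple[float, int]] = []
    censors: list[float] = []
    n_cur = rn[0]
    s_run = 1.0
    pts_all = list(curve.points)

    for i in range(len(rt)):
        t_lo = rt[i]
        has_target = i + 1 < len(rt)
        t_hi = rt[i + 1] if has_target else max(last_curve_t, t_lo)
        pts = [p for p in pts_all if t_lo <= p[0] < t_hi or (not has_target and p[0] >= t_lo)]
        if has_target:
            target = rn[i + 1]
            s_final = pts[-1][1] if pts else s_run
            best = None
            for c in range(n_cur + 1):
                implied, S, ev, cen = _replay_interval(pts, n_cur, s_run, t_lo, t_hi, c)
                # primary: match the published at-risk count at the interval
                # end; tie-break: land the running KM on the last published
                # step value, then prefer fewer censorings
                key = (abs(implied - target), abs(S - s_final), c)
                if best is None or key < best[0]:
                    best = (key, implied, S, ev, cen)
                if implied < target:
                    break  # implied n only decreases with more censoring
            if best is None:
                raise ReconstructionError(f"{curve.arm_id}: empty search in interval {i}")
            key, implied, S, ev, cen = best
            if key[0] > 0:
                log.debug(
                    "%s: interval [%g, %g): implied n=%d vs published %d",
                    curve.arm_id, t_lo, t_hi, implied, rn[i + 1],
                )
            events.extend(ev)
            censors.extend(cen)
            n_cur, s_run = implied, S
        else:
            # Tail beyond the last published at-risk count. Without further
            # information censoring is assumed only at the final curve time
            # (c = 0); when a published event total is available the tail
            # censoring count is searched so the reconstructed event count
            # honors it.
            if total_events is not None:
                remaining = total_events - sum(d for _, d in events)
                s_final = pts[-1][1] if pts else s_run
                best = None
                for c in range(n_cur + 1):
                    implied, S, ev, cen = _replay_interval(pts, n_cur, s_run, t_lo, t_hi, c)
                    tail_events = sum(d for _, d in ev)
                    # primary: honor the event budget; tie-break: land the
                    # final survival on the last published step value
                    key = (abs(tail_events - remaining), abs(S - s_final))
                    if best is None or key < best[0]:
                        best = (key, implied, S, ev, cen)
                    if tail_events < remaining:
                        break  # more censoring only removes further events
                _, implied, S, ev, cen = best
            else:
                implied, S, ev, cen = _replay_interval(pts, n_cur, s_run, t_lo, t_hi, 0)
            events.extend(ev)
            censors.extend(cen)
            n_cur, s_run = implied, S
            if n_cur > 0:
                t_end = max(last_curve_t, t_lo)
                if t_end <= 0:
                    t_end = 1e-9
                censors.extend([t_end] * n_cur)
                n_cur = 0

    records = [IPDRecord(t, 1) for t, d in events for _ in range(d)]
    records += [IPDRecord(max(t, 1e-9), 0) for t in censors]
    if len(records) != rn[0]:
        raise ReconstructionError(
            f"{curve.arm_id}: reconstructed {len(records)} records for enrollment {rn[0]}"
        )

    if total_events is not None:
        records = _calibrate_events(records, total_events, curve.arm_id)
    records.sort(key=lambda r: (r.time, -r.event))
    return IPDSet(
        arm_id=curve.arm_id,
        endpoint=curve.endpoint,
        records=tuple(records),
        provenance="reconstructed",
    )


def _calibrate_events(
    records: list[IPDRecord], total_events: int, arm_id: str
) -> list[IPDRecord]:
    """Flip event indicators so the event count honors a published total.

    Flipping a record's indicator leaves every at-risk count unchanged (the
    subject still leaves observation at the same time), so only the KM drop at
    that time is affected; the relative distortion of one flip is ~1/n(t).
    Flips are therefore made at the earliest eligible times, where the risk
    set is largest. When the exact total is arithmetically infeasible the
    nearest feasible count is used and a warning logged.
    """
    have = sum(r.event for r in records)
    need = total_events - have
    if need == 0:
        return records
    records = sorted(records, key=lambda r: (r.time, -r.event))
    want = 0 if need > 0 else 1  # indicator value of the records to flip
    idx = [i for i, r in enumerate(records) if r.event == want]
    flips = idx[: abs(need)]
    for i in flips:
        records[i] = IPDRecord(records[i].time, 1 - want)
    if len(flips) < abs(need):
        log.warning(
            "%s: published event total %d not arithmetically feasible; using %d",
            arm_id, total_events, have + (1 if need > 0 else -1) * len(flips),
        )
    return records


def reconstruction_fit(ipd: IPDSet, curve: CleanCurve, risk: RiskTable) -> ReconstructionFit:
    """Audit a reconstruction against the curve and risk table it came from."""
    if ipd.arm_id != curve.arm_id:
        raise ValidationError(f"arm mismatch: {ipd.arm_id} vs {curve.arm_id}")
    km = km_estimate(ipd)
    devs = np.array([km_survival_at(km, t) - s for t, s in curve.points])
    times = np.array([r.time for r in ipd.records])
    residuals = tuple(
        (t, n_pub, int(np.sum(times >= t))) for t, n_pub in zip(risk.times, risk.counts)
    )
    max_abs = float(np.max(np.abs(devs))) if len(devs) else 0.0
    rmse = float(np.sqrt(np.mean(devs**2))) if len(devs) else 0.0
    return ReconstructionFit(
        max_abs_dev=max_abs,
        rmse=rmse,
        risk_residuals=residuals,
        events_total=ipd.n_events,
    )
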