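"""CSV readers/writers and the run-configuration schema.

Interchange formats (comma-separated, header row, UTF-8, ``.`` decimal):

* curve CSV: ``time_months,survival`` — survival on the 0–1 or 0–100 scale
  (auto-detected: any value > 1.5 implies percent scale);
* risk CSV: ``time_months,n_at_risk``;
* IPD CSV: ``arm_id,endpoint,time_months,event``;
* AE CSV: ``study,arm_id,category,numerator,denominator``.

All paths inside a run configuration are resolved relative to the config
file's directory.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .datatypes import (
    DigitizedCurve,
    IPDRecord,
    IPDSet,
    RiskEntry,
    RiskTable,
    ValidationError,
)
from .tables import GroupSpec, resolve_groups

log = logging.getLogger(__name__)

__all__ = [
    "read_curve_csv",
    "read_risk_csv",
    "write_ipd_csv",
    "read_ipd_csv",
    "AECountRow",
    "read_ae_csv",
    "write_ae_csv",
    "ArmInputs",
    "RunConfig",
    "load_run_config",
]


def _read_rows(path: Path, columns: Sequence[str]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        missing = set(columns) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return rows


def read_curve_csv(path: str | Path, arm_id: str | None = None, endpoint: str = "OS") -> DigitizedCurve:
    """Read digitized curve coordinates, normalizing survival to [0, 1].

    Rows are sorted by time. A survival value > 1.5 anywhere flags the file as
    percent-scaled and every value is divided by 100 (valid probabilities never
    exceed 1; valid percent curves start at 100).
    """
    path = Path(path)
    rows = _read_rows(path, ("time_months", "survival"))
    pts = []
    for i, row in enumerate(rows, start=2):
        try:
            t = float(row["time_months"])
            s = float(row["survival"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad value at row {i}: {exc}") from None
        if t < 0:
            raise ValidationError(f"{path}: negative time {t} at row {i}")
        pts.append((t, s))
    if any(s > 1.5 for _, s in pts):
        log.info("%s: survival values on percent scale, dividing by 100", path)
        pts = [(t, s / 100.0) for t, s in pts]
    pts.sort(key=lambda p: p[0])
    return DigitizedCurve(arm_id=arm_id or path.stem, endpoint=endpoint, points=tuple(pts))


def read_risk_csv(
    path: str | Path, arm_id: str | None = None, total_events: int | None = None
) -> RiskTable:
    """Read a numbers-at-risk table; entries sorted by time, counts validated."""
    path = Path(path)
    rows = _read_rows(path, ("time_months", "n_at_risk"))
    entries = []
    for i, row in enumerate(rows, start=2):
        try:
            t = float(row["time_months"])
            raw = row["n_at_risk"]
            n = int(raw)
            if float(raw) != n:
                raise ValueError(f"non-integer n_at_risk {raw}")
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad value at row {i}: {exc}") from None
        entries.append(RiskEntry(t, n))
    entries.sort(key=lambda e: e.time)
    try:
        return RiskTable(arm_id=arm_id or path.stem, entries=tuple(entries), total_events=total_events)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_ipd_csv(ipd: IPDSet, path: str | Path) -> None:
    """Write an IPD set as ``arm_id,endpoint,time_months,event`` rows."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["arm_id", "endpoint", "time_months", "event"])
        for rec in ipd.records:
            writer.writerow([ipd.arm_id, ipd.endpoint, repr(rec.time), rec.event])


def read_ipd_csv(path: str | Path, provenance: str = "reconstructed") -> list[IPDSet]:
    """Read an IPD CSV back into one :class:`IPDSet` per (arm_id, endpoint)."""
    path = Path(path)
    rows = _read_rows(path, ("arm_id", "endpoint", "time_months", "event"))
    by_key: dict[tuple[str, str], list[IPDRecord]] = {}
    for i, row in enumerate(rows, start=2):
        try:
            rec = IPDRecord(time=float(row["time_months"]), event=int(row["event"]))
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: bad record at row {i}: {exc}") from None
        by_key.setdefault((row["arm_id"], row["endpoint"]), []).append(rec)
    return [
        IPDSet(arm_id=a, endpoint=e, records=tuple(recs), provenance=provenance)
        for (a, e), recs in by_key.items()
    ]


@dataclass(frozen=True)
class AECountRow:
    """Adverse-event count for one arm and category: numerator/denominator."""

    study: str
    arm_id: str
    category: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValidationError(
                f"{self.arm_id}/{self.category}: numerator {self.numerator} "
                f"outside [0, {self.denominator}]"
            )


def read_ae_csv(path: str | Path) -> list[AECountRow]:
    path = Path(path)
    rows = _read_rows(path, ("study", "arm_id", "category", "numerator", "denominator"))
    out = []
    for i, row in enumerate(rows, start=2):
        try:
            out.append(
                AECountRow(
                    study=row["study"],
                    arm_id=row["arm_id"],
                    category=row["category"],
                    numerator=int(row["numerator"]),
                    denominator=int(row["denominator"]),
                )
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: bad row {i}: {exc}") from None
    return out


def write_ae_csv(rows: Sequence[AECountRow], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["study", "arm_id", "category", "numerator", "denominator"])
        for r in rows:
            writer.writerow([r.study, r.arm_id, r.category, r.numerator, r.denominator])


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class ArmInputs:
    """Input files and published totals for one arm of the analysis."""

    arm_id: str
    study: str
    enrollment: int
    curves: dict  # endpoint -> Path
    risk_tables: dict = field(default_factory=dict)  # endpoint -> Path
    total_events: dict = field(default_factory=dict)  # endpoint -> int

    def __post_init__(self) -> None:
        if self.enrollment <= 0:
            raise ValidationError(f"{self.arm_id}: enrollment must be positive")
        if not self.curves:
            raise ValidationError(f"{self.arm_id}: no curve files configured")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    studies: tuple[ArmInputs, ...]
    groups: tuple[GroupSpec, ...]
    control_group: str
    rmst_taus: tuple[float, ...]
    alpha: float = 0.05
    endpoints: tuple[str, ...] = ("OS", "PFS")
    seed: Optional[int] = None
    ae_table: Optional[Path] = None
    stratify_by_study: bool = False
    base_dir: Path = Path(".")

    def arm(self, arm_id: str) -> ArmInputs:
        for a in self.studies:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    @property
    def control(self) -> GroupSpec:
        return next(g for g in self.groups if g.role == "control")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Group membership is checked against the ``studies`` block, exactly one
    control group is required, and RMST truncation times must be positive.
    Relative file paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    base = path.parent
    try:
        studies = []
        for s in raw["studies"]:
            curves = {ep: base / p for ep, p in s["curves"].items()}
            risks = {ep: base / p for ep, p in s.get("risk_tables", {}).items()}
            studies.append(
                ArmInputs(
                    arm_id=s["arm_id"],
                    study=s.get("study", s["arm_id"]),
                    enrollment=int(s["enrollment"]),
                    curves=curves,
                    risk_tables=risks,
                    total_events={ep: int(v) for ep, v in s.get("total_events", {}).items()},
                )
            )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed studies block ({exc})") from None
    if not studies:
        raise ValidationError(f"{path}: no studies configured")
    ids = [s.arm_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate arm_id in studies")

    # groups are validated against pseudo-arms built from the studies block
    from .tables import StudyArm

    pseudo = [
        StudyArm(
            arm_id=s.arm_id, study=s.study, regimen="", n_patients=s.enrollment,
            pfs_events=0, os_events=0, median_pfs=0.0, median_os=0.0,
        )
        for s in studies
    ]
    groups = tuple(resolve_groups(raw, pseudo))
    control_name = next(g.name for g in groups if g.role == "control")

    taus = tuple(float(t) for t in raw.get("rmst_taus", (12.0, 24.0)))
    if any(t <= 0 for t in taus):
        raise ValidationError(f"{path}: rmst_taus must be positive")
    endpoints = tuple(raw.get("endpoints", ("OS", "PFS")))
    for ep in endpoints:
        for s in studies:
            if ep not in s.curves:
                raise ValidationError(f"{path}: arm {s.arm_id} has no {ep} curve")
    ae_table = raw.get("ae_table")
    return RunConfig(
        studies=tuple(studies),
        groups=groups,
        control_group=control_name,
        rmst_taus=taus,
        alpha=float(raw.get("alpha", 0.05)),
        endpoints=endpoints,
        seed=raw.get("seed"),
        ae_table=(base / ae_table) if ae_table else None,
        stratify_by_study=bool(raw.get("stratify_by_study", False)),
        base_dir=base,
    )
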