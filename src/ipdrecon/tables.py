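"""Study-characteristics table and treatment-class group handling.

The package ships a transcription of the characteristics table of nine
first-line ES-SCLC immunotherapy trials (11 immunotherapy cohorts) together
with the default assignment of those cohorts to five treatment-class groups
(PD-L1, PD-1, tremelimumab, tiragolumab, anlotinib), with the PD-L1 group in
the control role.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .datatypes import ValidationError

__all__ = [
    "StudyArm",
    "GroupSpec",
    "load_study_table",
    "load_default_study_table",
    "default_group_config",
    "resolve_groups",
    "pool_counts",
]


@dataclass(frozen=True)
class StudyArm:
    """One immunotherapy cohort row of the study-characteristics table."""

    arm_id: str
    study: str
    regimen: str
    n_patients: int
    pfs_events: int
    os_events: int
    median_pfs: float
    median_os: float
    median_followup: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError(f"{self.arm_id}: n_patients must be positive")
        if not 0 <= self.pfs_events <= self.n_patients:
            raise ValidationError(
                f"{self.arm_id}: pfs_events {self.pfs_events} exceeds n_patients {self.n_patients}"
            )
        if not 0 <= self.os_events <= self.n_patients:
            raise ValidationError(
                f"{self.arm_id}: os_events {self.os_events} exceeds n_patients {self.n_patients}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """A named pooling of arms; exactly one group per run carries the control role."""

    name: str
    member_arm_ids: tuple[str, ...]
    role: str = "experimental"

    def __post_init__(self) -> None:
        if self.role not in ("control", "experimental"):
            raise ValidationError(f"group {self.name}: unknown role {self.role!r}")
        if len(self.member_arm_ids) == 0:
            raise ValidationError(f"group {self.name}: empty member list")
        object.__setattr__(self, "member_arm_ids", tuple(self.member_arm_ids))


_REQUIRED_COLS = {
    "arm_id",
    "study",
    "regimen",
    "n_patients",
    "pfs_events",
    "os_events",
    "median_pfs_months",
    "median_os_months",
}


def load_study_table(path: str | Path) -> list[StudyArm]:
    """Load a study-characteristics CSV into :class:`StudyArm` records.

    Raises :class:`ValidationError` on duplicate arm ids or event counts
    exceeding enrollment.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not _REQUIRED_COLS.issubset(reader.fieldnames):
            missing = _REQUIRED_COLS - set(reader.fieldnames or ())
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        arms: list[StudyArm] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            arm_id = row["arm_id"].strip()
            if arm_id in seen:
                raise ValidationError(f"{path}: duplicate arm_id {arm_id!r} (row {i})")
            seen.add(arm_id)
            fu = row.get("median_followup_months", "")
            arms.append(
                StudyArm(
                    arm_id=arm_id,
                    study=row["study"].strip(),
                    regimen=row["regimen"].strip(),
                    n_patients=int(row["n_patients"]),
                    pfs_events=int(row["pfs_events"]),
                    os_events=int(row["os_events"]),
                    median_pfs=float(row["median_pfs_months"]),
                    median_os=float(row["median_os_months"]),
                    median_followup=float(fu) if fu not in ("", None) else None,
                )
            )
    if not arms:
        raise ValidationError(f"{path}: empty study table")
    return arms


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ipdrecon").joinpath("data", name)))


def load_default_study_table() -> list[StudyArm]:
    """The shipped 11-cohort table (9 trials, first-line ES-SCLC immunotherapy)."""
    return load_study_table(_data_path("table1.csv"))


def default_group_config() -> dict:
    """The shipped five-group assignment with the PD-L1 group as control.

    Returns a plain dict with keys ``groups`` (list of name/members/role
    mappings) and ``control_group``, the same shape the run configuration uses.
    """
    with open(_data_path("groups.yaml"), encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def resolve_groups(config: dict, arms: Sequence[StudyArm]) -> list[GroupSpec]:
    """Validate a ``groups`` config block against loaded arms.

    Checks that every member arm exists, that no arm is assigned twice, and
    that exactly one group carries the control role (taken from each group's
    ``role`` key, or from a top-level ``control_group`` name).
    """
    known = {a.arm_id for a in arms}
    control_name = config.get("control_group")
    specs: list[GroupSpec] = []
    assigned: set[str] = set()
    for g in config["groups"]:
        name = g["name"]
        members = tuple(g["members"])
        for m in members:
            if m not in known:
                raise ValidationError(f"group {name}: unknown arm_id {m!r}")
            if m in assigned:
                raise ValidationError(f"arm {m!r} assigned to more than one group")
            assigned.add(m)
        role = g.get("role", "control" if name == control_name else "experimental")
        specs.append(GroupSpec(name=name, member_arm_ids=members, role=role))
    controls = [s for s in specs if s.role == "control"]
    if len(controls) != 1:
        raise ValidationError(f"exactly one control group required, found {len(controls)}")
    if control_name is not None and controls[0].name != control_name:
        raise ValidationError(
            f"control_group {control_name!r} does not match group with control role"
        )
    return specs


def pool_counts(group: GroupSpec, arms: Sequence[StudyArm]) -> tuple[int, int, int]:
    """Component-wise sums of (patients, PFS events, OS events) over member arms."""
    by_id = {a.arm_id: a for a in arms}
    missing = [m for m in group.member_arm_ids if m not in by_id]
    if missing:
        raise ValidationError(f"group {group.name}: unknown members {missing}")
    members = [by_id[m] for m in group.member_arm_ids]
    return (
        sum(a.n_patients for a in members),
        sum(a.pfs_events for a in members),
        sum(a.os_events for a in members),
    )
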