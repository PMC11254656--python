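"""Pipeline orchestration: reconstruct every arm, pool into treatment-class
groups, and compare each group against the control.

Pooling is naive concatenation of reconstructed patient records into a
unified arm — each patient keeps its own (time, event) record and the pooled
set is analyzed as a single cohort. Comparisons are pairwise against the
designated control group only; p-values are reported unadjusted and the
number of comparisons is stated in the report header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .datatypes import IPDSet, ValidationError
from .io import (
    RunConfig,
    read_ae_csv,
    read_curve_csv,
    read_risk_csv,
    write_ipd_csv,
)
from .reconstruct import (
    ReconstructionFit,
    preprocess_curve,
    reconstruct_ipd,
    reconstruction_fit,
)
from .survival import (
    CoxResult,
    MedianResult,
    RMSTComparison,
    cox_hr,
    km_estimate,
    median_survival,
    rmst,
    rmst_diff,
)
from .ae import compare_ae

log = logging.getLogger(__name__)

__all__ = ["ComparisonReport", "pool_arms", "compare_groups", "run_pipeline"]


@dataclass(frozen=True)
class ComparisonReport:
    """One group-vs-control comparison on one endpoint."""

    group: str
    control: str
    endpoint: str
    n_group: int
    n_control: int
    cox: Optional[CoxResult]
    median_group: MedianResult
    median_control: MedianResult
    rmst_comparisons: tuple[RMSTComparison, ...]
    errors: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "group": self.group,
            "control": self.control,
            "endpoint": self.endpoint,
            "n_group": self.n_group,
            "n_control": self.n_control,
            "median_group": _median_dict(self.median_group),
            "median_control": _median_dict(self.median_control),
            "rmst": [
                {
                    "tau": r.tau,
                    "diff": r.diff,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                }
                for r in self.rmst_comparisons
            ],
            "errors": list(self.errors),
        }
        if self.cox is not None:
            d["cox"] = {
                "hr": self.cox.hr,
                "ci_low": self.cox.ci_low,
                "ci_high": self.cox.ci_high,
                "p": self.cox.wald_p,
                "log_hr": self.cox.log_hr,
                "se": self.cox.se,
                "events": self.cox.events,
                "converged": self.cox.converged,
            }
        return d


def _median_dict(m: MedianResult) -> dict:
    return {"median": m.median, "ci_low": m.ci_low, "ci_high": m.ci_high}


def pool_arms(members: Sequence[IPDSet], name: str = "pooled") -> IPDSet:
    """Concatenate member arms into a unified arm, tagging each record's source."""
    if not members:
        raise ValidationError("cannot pool an empty member list")
    endpoint = members[0].endpoint
    for m in members[1:]:
        if m.endpoint != endpoint:
            raise ValidationError(
                f"endpoint mismatch while pooling: {m.endpoint} vs {endpoint}"
            )
    records = tuple(r for m in members for r in m.records)
    sources = tuple(m.arm_id for m in members for _ in m.records)
    provenance = members[0].provenance
    return IPDSet(
        arm_id=name, endpoint=endpoint, records=records,
        provenance=provenance, sources=sources,
    )


def compare_groups(
    group: IPDSet, control: IPDSet, taus: Sequence[float], group_name: str | None = None,
    control_name: str | None = None,
) -> ComparisonReport:
    """Compare a pooled group against the pooled control on one endpoint.

    Produces the Cox HR (control as reference; HR < 1 favors the group),
    per-side medians with CIs, and an RMST difference test at every tau.
    Estimator failures are collected into ``errors`` rather than raised, so a
    single undefined quantity does not void the rest of the report.
    """
    if group.endpoint != control.endpoint:
        raise ValidationError("endpoint mismatch between group and control")
    errors: list[str] = []
    pooled = pool_arms([control, group], name="cox_input")
    labels = [0] * control.size + [1] * group.size
    cox: Optional[CoxResult] = None
    try:
        cox = cox_hr(pooled, labels)
        if not cox.converged:
            errors.append("cox: did not converge")
    except ValidationError as exc:
        errors.append(f"cox: {exc}")
    km_g = km_estimate(group)
    km_c = km_estimate(control)
    comparisons = []
    for tau in taus:
        try:
            comparisons.append(rmst_diff(rmst(km_g, tau), rmst(km_c, tau)))
        except ValidationError as exc:
            errors.append(f"rmst tau={tau}: {exc}")
    return ComparisonReport(
        group=group_name or group.arm_id,
        control=control_name or control.arm_id,
        endpoint=group.endpoint,
        n_group=group.size,
        n_control=control.size,
        cox=cox,
        median_group=median_survival(km_g),
        median_control=median_survival(km_c),
        rmst_comparisons=tuple(comparisons),
        errors=tuple(errors),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: Optional[Path] = None,
    make_plots: bool = False,
) -> dict:
    """Run the full analysis: reconstruct, audit, pool, compare, report.

    For each configured endpoint every arm is reconstructed from its curve
    and risk table, audited, pooled into its treatment-class group, and each
    non-control group is compared against the control (Cox HR, medians, RMST
    differences at the configured truncation times). If an AE table is
    configured, pooled incidences of the first two groups are compared with
    the chi-square test. Deterministic given identical inputs; any arm
    failing reconstruction aborts the run naming the arm.

    When ``out_dir`` is given, per-arm IPD CSVs, fit reports, the comparison
    JSON, a text summary and a manifest (input hashes, seed, version) are
    written there.
    """
    input_hashes: dict[str, str] = {}
    reports: dict[str, list[dict]] = {}
    fits: dict[str, dict[str, dict]] = {}
    reconstructed: dict[str, dict[str, IPDSet]] = {}
    warnings: list[str] = []

    for endpoint in config.endpoints:
        reconstructed[endpoint] = {}
        fits[endpoint] = {}
        for arm in config.studies:
            curve_path = arm.curves[endpoint]
            input_hashes[str(curve_path)] = _sha256(curve_path)
            raw = read_curve_csv(curve_path, arm_id=arm.arm_id, endpoint=endpoint)
            clean = preprocess_curve(raw)
            risk_path = arm.risk_tables.get(endpoint)
            if risk_path is not None:
                input_hashes[str(risk_path)] = _sha256(risk_path)
                risk = read_risk_csv(
                    risk_path, arm_id=arm.arm_id,
                    total_events=arm.total_events.get(endpoint),
                )
            else:
                from .datatypes import RiskEntry, RiskTable

                warnings.append(f"{arm.arm_id}/{endpoint}: no risk table; degraded mode")
                risk = RiskTable(
                    arm_id=arm.arm_id,
                    entries=(RiskEntry(0.0, arm.enrollment),),
                    total_events=arm.total_events.get(endpoint),
                )
            try:
                ipd = reconstruct_ipd(clean, risk)
            except Exception as exc:
                raise ValidationError(
                    f"reconstruction failed for arm {arm.arm_id} ({endpoint}): {exc}"
                ) from exc
            fit = reconstruction_fit(ipd, clean, risk)
            reconstructed[endpoint][arm.arm_id] = ipd
            fits[endpoint][arm.arm_id] = {
                "max_abs_dev": fit.max_abs_dev,
                "rmse": fit.rmse,
                "events_total": fit.events_total,
                "risk_residuals": [list(r) for r in fit.risk_residuals],
            }

        control_spec = config.control
        pooled = {
            g.name: pool_arms(
                [reconstructed[endpoint][m] for m in g.member_arm_ids], name=g.name
            )
            for g in config.groups
        }
        control_ipd = pooled[control_spec.name]
        reports[endpoint] = []
        for g in config.groups:
            if g.role == "control":
                continue
            rep = compare_groups(
                pooled[g.name], control_ipd, config.rmst_taus,
                group_name=g.name, control_name=control_spec.name,
            )
            reports[endpoint].append(rep.to_dict())

    result: dict = {
        "tool": "ipdrecon",
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "control_group": config.control_group,
        "n_comparisons": sum(len(v) for v in reports.values()),
        "multiplicity_adjustment": "none (unadjusted p-values)",
        "comparisons": reports,
        "reconstruction_fits": fits,
        "warnings": warnings,
    }

    if config.ae_table is not None:
        input_hashes[str(config.ae_table)] = _sha256(config.ae_table)
        rows = read_ae_csv(config.ae_table)
        ae_groups = [g for g in config.groups if g.role != "control"]
        control_spec = config.control
        ae_out = {}
        for g in ae_groups:
            try:
                comps = compare_ae(rows, g, control_spec)
            except ValidationError as exc:
                warnings.append(f"ae {g.name}: {exc}")
                continue
            ae_out[g.name] = [
                {
                    "category": c.category,
                    "incidence_group": c.incidence_a,
                    "incidence_control": c.incidence_b,
                    "chi2": c.chi2,
                    "p": c.p,
                }
                for c in comps
            ]
        result["ae_comparisons"] = ae_out

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for endpoint, arms in reconstructed.items():
            for arm_id, ipd in arms.items():
                write_ipd_csv(ipd, out_dir / f"ipd_{arm_id}_{endpoint}.csv")
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
        (out_dir / "summary.md").write_text(render_summary(result), encoding="utf-8")
        manifest = {
            "tool": "ipdrecon",
            "version": __version__,
            "seed": config.seed,
            "inputs": dict(sorted(input_hashes.items())),
            "warnings": warnings,
        }
        import datetime

        manifest_on_disk = dict(manifest)
        manifest_on_disk["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest_on_disk, fh, indent=2, sort_keys=True)
        if make_plots:
            from .plots import km_overlay_plot

            for endpoint in config.endpoints:
                pooled = {
                    g.name: pool_arms(
                        [reconstructed[endpoint][m] for m in g.member_arm_ids], name=g.name
                    )
                    for g in config.groups
                }
                km_overlay_plot(pooled, out_dir / f"km_overlay_{endpoint}.png", endpoint)
    return result


def render_summary(report: dict) -> str:
    """Human-readable markdown mirroring the comparison structure of the report."""
    lines = [
        "# Pooled reconstructed-IPD analysis",
        "",
        f"Control group: **{report['control_group']}**  ",
        f"Comparisons: {report['n_comparisons']} (p-values unadjusted)  ",
        f"alpha = {report['alpha']}",
        "",
    ]
    for endpoint, comps in report["comparisons"].items():
        lines.append(f"## {endpoint}")
        lines.append("")
        lines.append("| group | n | median (95% CI) | control median | HR (95% CI) | p |")
        lines.append("|---|---|---|---|---|---|")
        for c in comps:
            med = c["median_group"]
            medc = c["median_control"]
            cox = c.get("cox")
            hr_s = (
                f"{cox['hr']:.2f} ({cox['ci_low']:.2f}-{cox['ci_high']:.2f})" if cox else "—"
            )
            p_s = f"{cox['p']:.3f}" if cox else "—"
            lines.append(
                f"| {c['group']} | {c['n_group']} | {_fmt_med(med)} | {_fmt_med(medc)} "
                f"| {hr_s} | {p_s} |"
            )
        lines.append("")
        for c in comps:
            for r in c["rmst"]:
                lines.append(
                    f"- {endpoint} RMST(tau={r['tau']:g}) {c['group']} vs {c['control']}: "
                    f"diff {r['diff']:.2f} m (95% CI {r['ci_low']:.2f} to {r['ci_high']:.2f}), "
                    f"p = {r['p']:.3f}"
                )
        lines.append("")
    return "\n".join(lines)


def _fmt_med(m: dict) -> str:
    if m["median"] is None:
        return "NR"
    lo = f"{m['ci_low']:.1f}" if m["ci_low"] is not None else "NR"
    hi = f"{m['ci_high']:.1f}" if m["ci_high"] is not None else "NR"
    return f"{m['median']:.1f} ({lo}-{hi})"
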