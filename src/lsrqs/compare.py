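"""Topology discrimination: joint fits across scenarios and the four
qualitative sub-network signature checks."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import ModelSpec, ModelVariant, KnockoutSet, knockouts_from_label
from .params import KineticParameters
from .simulate import DoseResponse, run_dose_series
from .fitting import (
    ExperimentalDataset,
    FitConfig,
    FitResult,
    fit_model,
    sse_objective,
)

__all__ = [
    "CheckResult",
    "ComparisonReport",
    "QUALITATIVE_THRESHOLDS",
    "joint_fit_variants",
    "qualitative_checks",
    "run_scenario_panel",
    "affinity_ratio_report",
]

REQUIRED_SCENARIOS = ("intact", "lsr_operon", "lsrR", "lsrK")

#: operationalized thresholds for "slight dependency" (lsrR-KO) and
#: "low/flat" (lsrK-KO); reported alongside every check result.
QUALITATIVE_THRESHOLDS: dict[str, float] = {
    "lsrK_flat_factor": 1.1,  # lsrK-KO top-dose peak <= 1.1x its zero-dose peak
    "lsrK_low_factor": 0.2,  # ... and <= 0.2x the intact top-dose peak
}


@dataclass
class CheckResult:
    name: str
    passed: bool
    measured: dict[str, float]
    threshold: str


@dataclass
class ComparisonReport:
    joint_sse: dict[str, float]
    per_scenario_sse: dict[str, dict[str, float]]
    fits: dict[str, FitResult]
    checks: list[CheckResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    non_identifiable: bool = False

    def to_dict(self) -> dict:
        return {
            "joint_sse": self.joint_sse,
            "per_scenario_sse": self.per_scenario_sse,
            "checks": [asdict(c) for c in self.checks],
            "failures": self.failures,
            "non_identifiable": self.non_identifiable,
            "fits": {v: f.to_dict() for v, f in self.fits.items()},
        }

    def summary_text(self) -> str:
        lines = ["topology comparison", "-" * 40]
        for v, s in sorted(self.joint_sse.items(), key=lambda kv: kv[1]):
            lines.append(f"{v:16s} joint SSE = {s:.6g}")
            for scen, ss in self.per_scenario_sse.get(v, {}).items():
                lines.append(f"    {scen:12s} {ss:.6g}")
        if self.non_identifiable:
            lines.append(
                "WARNING: fewer than 2 scenarios — variants are not discriminable"
            )
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(f"[{status}] {c.name} ({c.threshold}) {c.measured}")
        for v, msg in self.failures.items():
            lines.append(f"[ERROR] {v}: {msg}")
        return "\n".join(lines)


def joint_fit_variants(
    variants,
    data: ExperimentalDataset,
    config: FitConfig | None = None,
    base_params: KineticParameters | None = None,
) -> ComparisonReport:
    """Fit each topology variant to the pooled multi-scenario data.

    Reports joint and per-scenario SSE per variant.  Fit failures are
    recorded in the report rather than raised.  Single-scenario datasets
    are flagged as non-identifiable (all variants can fit one scenario).
    """
    scenarios = data.scenarios()
    non_identifiable = len(scenarios) < 2

    joint_sse: dict[str, float] = {}
    per_scenario: dict[str, dict[str, float]] = {}
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    obj_tols = (
        {"rtol": config.rtol, "atol": config.atol} if config is not None else {}
    )
    for variant in variants:
        variant = ModelVariant.coerce(variant)
        try:
            fit = fit_model(variant, data, config=config, base_params=base_params)
        except Exception as exc:  # recorded, not fatal to the report
            failures[variant.value] = str(exc)
            continue
        fits[variant.value] = fit
        joint_sse[variant.value] = fit.sse
        per_scenario[variant.value] = {
            scen: sse_objective(
                fit.params,
                ExperimentalDataset(
                    data.records[data.records["scenario"] == scen]
                ),
                variant,
                **obj_tols,
            )
            for scen in scenarios
        }
    return ComparisonReport(
        joint_sse=joint_sse,
        per_scenario_sse=per_scenario,
        fits=fits,
        failures=failures,
        non_identifiable=non_identifiable,
    )


def run_scenario_panel(
    variant: ModelVariant | str = ModelVariant.REG_BINDING,
    params: KineticParameters | None = None,
    doses=(0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0),
    times=None,
) -> dict[str, DoseResponse]:
    """Dose series for the intact network and the three single knockouts."""
    params = params or KineticParameters()
    return {
        scen: run_dose_series(
            ModelSpec(ModelVariant.coerce(variant), knockouts_from_label(scen), params),
            doses=doses,
            times=times,
        )
        for scen in REQUIRED_SCENARIOS
    }


def qualitative_checks(
    panel: dict[str, DoseResponse],
    thresholds: dict[str, float] | None = None,
) -> list[CheckResult]:
    """The four sub-network signatures.

    S1 — intact peak strictly increasing in dose.
    S2 — operon-KO top-dose peak exceeds the intact top-dose peak.
    S3 — lsrR-KO shows weak dose dependence: top/zero peak ratio strictly
         between 1 and the intact ratio.
    S4 — lsrK-KO is flat (top <= 1.1x zero dose) and low (<= 0.2x intact
         top-dose peak).
    """
    thresholds = {**QUALITATIVE_THRESHOLDS, **(thresholds or {})}
    missing = [s for s in REQUIRED_SCENARIOS if s not in panel]
    if missing:
        raise ValueError(f"missing scenario(s): {missing}")

    def peaks(scen: str) -> np.ndarray:
        return panel[scen].peak_table["peak_miller"].to_numpy(float)

    intact = peaks("intact")
    op_ko = peaks("lsr_operon")
    lsrR_ko = peaks("lsrR")
    lsrK_ko = peaks("lsrK")

    results = []
    results.append(
        CheckResult(
            name="S1_intact_dose_monotone",
            passed=bool(np.all(np.diff(intact) > 0)),
            measured={"min_increment": float(np.min(np.diff(intact)))},
            threshold="peak strictly increasing in dose",
        )
    )
    results.append(
        CheckResult(
            name="S2_operon_ko_exceeds_intact",
            passed=bool(op_ko[-1] > intact[-1]),
            measured={
                "operon_ko_top_peak": float(op_ko[-1]),
                "intact_top_peak": float(intact[-1]),
            },
            threshold="operon-KO top-dose peak > intact top-dose peak",
        )
    )
    intact_ratio = intact[-1] / intact[0] if intact[0] > 0 else np.inf
    lsrR_ratio = lsrR_ko[-1] / lsrR_ko[0] if lsrR_ko[0] > 0 else np.inf
    results.append(
        CheckResult(
            name="S3_lsrR_ko_weak_dependence",
            passed=bool(1.0 < lsrR_ratio < intact_ratio),
            measured={"lsrR_ko_ratio": float(lsrR_ratio), "intact_ratio": float(intact_ratio)},
            threshold="1 < top/zero peak ratio < intact ratio",
        )
    )
    flat = lsrK_ko[-1] <= thresholds["lsrK_flat_factor"] * lsrK_ko[0]
    low = lsrK_ko[-1] <= thresholds["lsrK_low_factor"] * intact[-1]
    results.append(
        CheckResult(
            name="S4_lsrK_ko_flat_and_low",
            passed=bool(flat and low),
            measured={
                "lsrK_top_over_zero": float(lsrK_ko[-1] / lsrK_ko[0]) if lsrK_ko[0] > 0 else np.inf,
                "lsrK_top_over_intact_top": float(lsrK_ko[-1] / intact[-1]),
            },
            threshold=(
                f"top <= {thresholds['lsrK_flat_factor']}x zero-dose and "
                f"<= {thresholds['lsrK_low_factor']}x intact top"
            ),
        )
    )
    return results


def affinity_ratio_report(fit: FitResult) -> dict:
    """Relative-affinity diagnostics of a fit with free k1 and k2.

    Flags whether k1/k2 lies within one order of magnitude (the two LsrR
    binding affinities are comparable), whether k4 > k2 (second-repressor
    regulation weaker than LsrR auto-regulation, as repression
    coefficients) and whether k5 < k3 (ligand binds the second repressor
    more weakly than LsrR).
    """
    for required in ("k1", "k2"):
        if required not in fit.free:
            raise ValueError(f"affinity report requires free parameter {required!r}")
    p = fit.params
    ratio = p.k1 / p.k2
    return {
        "k1_over_k2": ratio,
        "k1_k2_same_order": bool(0.1 <= ratio <= 10.0),
        "k4_gt_k2": bool(p.k4 > p.k2),
        "k5_lt_k3": bool(p.k5 < p.k3),
        "values": {"k1": p.k1, "k2": p.k2, "k3": p.k3, "k4": p.k4, "k5": p.k5},
    }
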