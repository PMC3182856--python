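"""Synthetic dose–response datasets standing in for β-galactosidase assays.

Two generators are provided:

* :func:`generate_model_truth` — exact model output (optionally with
  multiplicative log-normal noise) for parameter-recovery benchmarks.
* :func:`generate_experiment_like` — experiment-shaped Miller-unit time
  courses: hourly sampling, per-scenario amplitude calibration so the
  noise-free top-dose peaks match the published summary levels (intact
  ≈ 70 Miller units, operon-knockout ≈ 200).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSpec, ModelVariant, knockouts_from_label, scenario_label
from .params import KineticParameters
from .simulate import integrate_timecourse
from .fitting import ExperimentalDataset

__all__ = [
    "GeneratorConfig",
    "DEFAULT_CALIBRATION_TARGETS",
    "HOURLY_TIMES",
    "generate_model_truth",
    "generate_experiment_like",
]

#: hourly sampling grid, 0–480 min (assay samples were taken at hour intervals)
HOURLY_TIMES = tuple(float(t) for t in range(0, 481, 60))

#: per-scenario noise-free top-dose peak targets (Miller units).  The intact
#: and operon-knockout levels are printed summaries; the lsrR/lsrK levels are
#: declared placeholders consistent with the qualitative signatures.
DEFAULT_CALIBRATION_TARGETS: dict[str, float] = {
    "intact": 70.0,
    "lsr_operon": 200.0,
    "lsrR": 120.0,
    "lsrK": 10.0,
}


@dataclass
class GeneratorConfig:
    scenarios: tuple[str, ...] = ("intact", "lsr_operon", "lsrR", "lsrK")
    doses: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)
    times: tuple[float, ...] = HOURLY_TIMES
    noise_cv: float = 0.10
    seed: int | None = None
    calibration_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_TARGETS)
    )
    params: KineticParameters = field(default_factory=KineticParameters)
    variant: ModelVariant = ModelVariant.REG_BINDING

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for t in self.calibration_targets.values():
            if t <= 0:
                raise ValueError("calibration targets must be positive")


def _apply_noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal noise with coefficient of variation `cv`."""
    if cv == 0:
        return values
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def generate_model_truth(
    spec: ModelSpec,
    doses,
    times,
    seed: int | None = None,
    noise_cv: float = 0.0,
) -> ExperimentalDataset:
    """Sample the model reporter at `times` for each dose, optionally noisy.

    With ``noise_cv=0`` the output is exact model truth: the SSE objective
    at the generating parameters is zero.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    label = scenario_label(spec.knockouts)
    rows = []
    for dose in doses:
        grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
        traj = integrate_timecourse(spec, float(dose), times=grid)
        reporter = np.interp(times, traj.times, traj.reporter)
        reporter = _apply_noise(reporter, noise_cv, rng)
        for t, v in zip(times, reporter):
            rows.append((label, float(dose), float(t), float(v), 1.0))
    return ExperimentalDataset(
        pd.DataFrame(
            rows, columns=["scenario", "dose_uM", "time_min", "miller_units", "weight"]
        )
    )


def generate_experiment_like(
    config: GeneratorConfig | None = None,
) -> tuple[ExperimentalDataset, dict]:
    """Experiment-shaped Miller-unit dataset plus a provenance sidecar.

    Each scenario is simulated with the configured variant/parameters and
    rescaled by a single per-scenario factor so that its noise-free
    top-dose peak (over the sampled times and doses) equals the scenario's
    calibration target exactly.  Noise is applied after calibration.

    Returns ``(dataset, metadata)``; the metadata dict records the config,
    seed and the per-scenario scale factors (so fits can invert them).
    """
    config = config or GeneratorConfig()
    for needed in ("intact", "lsr_operon"):
        if needed in config.scenarios and needed not in config.calibration_targets:
            raise ValueError(f"missing calibration target for scenario {needed!r}")
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    top_dose = max(config.doses)

    rows = []
    scales: dict[str, float] = {}
    for scenario in config.scenarios:
        if scenario not in config.calibration_targets:
            raise ValueError(f"missing calibration target for scenario {scenario!r}")
        spec = ModelSpec(config.variant, knockouts_from_label(scenario), config.params)
        series: dict[float, np.ndarray] = {}
        for dose in config.doses:
            grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
            traj = integrate_timecourse(spec, float(dose), times=grid)
            series[float(dose)] = np.interp(times, traj.times, traj.reporter)
        peak = float(series[float(top_dose)].max())
        if peak <= 0:
            raise RuntimeError(f"scenario {scenario!r} has non-positive peak; cannot calibrate")
        scale = config.calibration_targets[scenario] / peak
        scales[scenario] = scale
        for dose, values in series.items():
            noisy = _apply_noise(values * scale, config.noise_cv, rng)
            for t, v in zip(times, noisy):
                rows.append((scenario, dose, float(t), float(v), 1.0))

    dataset = ExperimentalDataset(
        pd.DataFrame(
            rows, columns=["scenario", "dose_uM", "time_min", "miller_units", "weight"]
        )
    )
    metadata = {
        "seed": config.seed,
        "noise_cv": config.noise_cv,
        "variant": config.variant.value,
        "doses": list(config.doses),
        "times": [float(t) for t in config.times],
        "calibration_targets": dict(config.calibration_targets),
        "scenario_scales": scales,
        "generating_params": config.params.as_dict(),
    }
    return dataset, metadata
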