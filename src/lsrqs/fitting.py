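"""Least-squares parameter estimation by Hooke–Jeeves direct search.

The estimation pipeline mirrors the classic direct-search recipe: an
exploratory/pattern-move minimizer run from multiple Latin-hypercube
starting points, on log-transformed coordinates for all positive rate and
affinity parameters (Hill coefficients stay linear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import ModelSpec, ModelVariant, KnockoutSet, knockouts_from_label
from .params import KineticParameters, HILL_NAMES, PARAM_NAMES, validate_params
from .simulate import IntegrationError, integrate_timecourse

__all__ = [
    "ExperimentalDataset",
    "FitConfig",
    "FitResult",
    "RestartTrace",
    "DEFAULT_BOUNDS",
    "PENALTY_SSE",
    "sse_objective",
    "hooke_jeeves_minimize",
    "latin_hypercube_starts",
    "fit_model",
]

#: objective value returned when integration fails at a parameter point
PENALTY_SSE = 1e12

#: default search boxes: rates/binding constants span [1e-4, 1e2],
#: repression coefficients [1e-2, 1e2] µM, Hill coefficients [1, 6]
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_op": (1e-4, 1e2),
    "k_r": (1e-4, 1e2),
    "k1": (1e-2, 1e2),
    "k2": (1e-2, 1e2),
    "k3": (1e-4, 1e2),
    "k4": (1e-2, 1e2),
    "k5": (1e-8, 1e2),
    "k_f": (1e-4, 1e2),
    "k_imp": (1e-4, 1e2),
    "nOP": (1.0, 6.0),
    "nR": (1.0, 6.0),
    "nG": (1.0, 6.0),
    "k_deg": (1e-4, 1.0),
    "s_rep": (1e-3, 1e3),
}

_COLUMNS = ("scenario", "dose_uM", "time_min", "miller_units", "weight")


@dataclass
class ExperimentalDataset:
    """Tidy (scenario, dose, time, Miller-unit, weight) records."""

    records: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.records).copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing column(s): {missing}")
        df = df[list(_COLUMNS)]
        if len(df) == 0:
            raise ValueError("dataset must contain at least one record")
        for col in ("dose_uM", "time_min", "miller_units", "weight"):
            df[col] = pd.to_numeric(df[col])
        if (df["time_min"] < 0).any() or (df["time_min"] > 500).any():
            raise ValueError("time_min must lie within [0, 500]")
        if (df["dose_uM"] < 0).any():
            raise ValueError("dose_uM must be >= 0")
        if (df["weight"] < 0).any():
            raise ValueError("weights must be >= 0")
        for label in df["scenario"].unique():
            knockouts_from_label(str(label))  # raises on unknown labels
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def scenarios(self) -> list[str]:
        return sorted(self.records["scenario"].unique())

    def groups(self):
        """Yield ((scenario, dose), times, values, weights) per integration unit."""
        for (scenario, dose), g in self.records.groupby(
            ["scenario", "dose_uM"], sort=True
        ):
            yield (
                (str(scenario), float(dose)),
                g["time_min"].to_numpy(float),
                g["miller_units"].to_numpy(float),
                g["weight"].to_numpy(float),
            )


def sse_objective(
    p: KineticParameters,
    data: ExperimentalDataset,
    variant: ModelVariant | str = ModelVariant.REG_BINDING,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Weighted sum of squared residuals (Miller units²) of model vs data.

    One integration per (scenario, dose) pair; model reporter interpolated
    at the record times.  Integration failure returns ``PENALTY_SSE``.
    """
    bad = validate_params(p)
    if bad:
        return PENALTY_SSE
    variant = ModelVariant.coerce(variant)
    sse = 0.0
    for (scenario, dose), times, values, weights in data.groups():
        spec = ModelSpec(variant, knockouts_from_label(scenario), p)
        t_max = float(times.max())
        grid = np.arange(0.0, math.floor(t_max) + 2.0)
        if grid[-1] < t_max:
            grid = np.append(grid, t_max)
        try:
            traj = integrate_timecourse(spec, dose, times=grid, rtol=rtol, atol=atol)
        except (IntegrationError, FloatingPointError):
            return PENALTY_SSE
        model = np.interp(times, traj.times, traj.reporter)
        sse += float(np.sum(weights * (model - values) ** 2))
    return sse


# ---------------------------------------------------------------------------
# Hooke–Jeeves direct search
# ---------------------------------------------------------------------------


def hooke_jeeves_minimize(
    objective,
    start: np.ndarray,
    bounds: np.ndarray,
    step_init: np.ndarray | float | None = None,
    step_reduce: float = 0.5,
    tol: float = 1e-4,
    max_evals: int = 10_000,
):
    """Classic exploratory-move + pattern-move direct search.

    Parameters are projected onto the box `bounds` (shape (d, 2)).  Each
    coordinate keeps its own step; all steps shrink by `step_reduce` when
    an exploratory sweep fails.  Terminates when every step, relative to
    its coordinate range, drops below `tol`, or on the evaluation budget.
    Deterministic for fixed inputs.

    Returns ``(x_best, f_best, trace)`` where trace is a list of
    ``(n_evals, f_best)`` pairs recorded at each improvement.
    """
    x = np.asarray(start, dtype=float).copy()
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("start point outside bounds")
    span = hi - lo
    if step_init is None:
        step = 0.25 * span
    else:
        step = np.broadcast_to(np.asarray(step_init, dtype=float), x.shape).copy()

    n_evals = 0

    def f(pt):
        nonlocal n_evals
        n_evals += 1
        return float(objective(pt))

    def explore(base, fbase):
        """One exploratory sweep around `base`; returns (point, value)."""
        pt = base.copy()
        fb = fbase
        for i in range(len(pt)):
            for delta in (step[i], -step[i]):
                trial = pt.copy()
                trial[i] = min(hi[i], max(lo[i], pt[i] + delta))
                if trial[i] == pt[i]:
                    continue
                ft = f(trial)
                if ft < fb:
                    pt, fb = trial, ft
                    break
        return pt, fb

    fx = f(x)
    trace = [(n_evals, fx)]
    while n_evals < max_evals:
        new, fnew = explore(x, fx)
        if fnew < fx:
            # pattern moves: keep doubling along the improving direction
            while n_evals < max_evals:
                pattern = np.clip(new + (new - x), lo, hi)
                x, fx = new, fnew
                trace.append((n_evals, fx))
                cand, fcand = explore(pattern, f(pattern))
                if fcand < fx:
                    new, fnew = cand, fcand
                else:
                    break
            else:
                break
        else:
            if np.all(step / np.where(span > 0, span, 1.0) < tol):
                break
            step *= step_reduce
    return x, fx, trace


def latin_hypercube_starts(
    bounds: np.ndarray,
    n: int,
    seed: int | None = None,
    log_mask: np.ndarray | None = None,
) -> np.ndarray:
    """`n` stratified start points, log-uniform where `log_mask` is set.

    Each dimension is divided into `n` equal strata (in log10 space for
    masked coordinates) with one sample per stratum, independently
    permuted per dimension.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = np.asarray(bounds, dtype=float)
    d = len(bounds)
    if log_mask is None:
        log_mask = np.ones(d, dtype=bool)
    rng = np.random.default_rng(seed)
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T + rng.uniform(size=(n, d))) / n
    out = np.empty((n, d))
    for j in range(d):
        lo, hi = bounds[j]
        if log_mask[j]:
            out[:, j] = 10 ** (np.log10(lo) + u[:, j] * (np.log10(hi) - np.log10(lo)))
        else:
            out[:, j] = lo + u[:, j] * (hi - lo)
    return out


# ---------------------------------------------------------------------------
# High-level fit driver
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Controls which parameters are free and how the search is run."""

    free: tuple[str, ...] = ("k_op", "k1", "k2", "k4", "nOP")
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    restarts: int = 20
    seed: int = 0
    step_frac: float = 0.25
    step_reduce: float = 0.5
    tol: float = 1e-4
    max_evals: int = 10_000
    starts: list[dict[str, float]] | None = None  # explicit starts (bypass LHS)
    # objective-internal integration tolerances; looser than the simulation
    # defaults (the objective is noisy-data-limited, not integrator-limited)
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        unknown = [n for n in self.free if n not in PARAM_NAMES]
        if unknown:
            raise ValueError(f"unknown free parameter(s): {unknown}")
        if "k_deg" in self.free and "k_deg" not in self.bounds:
            raise ValueError("freeing k_deg requires explicit bounds (fixed by default)")
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        self.bounds = merged
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (0 < lo < hi < math.inf):
                raise ValueError(f"bounds for {name} must be finite and positive")


@dataclass
class RestartTrace:
    start: dict[str, float]
    end: dict[str, float]
    sse: float
    n_evals: int
    converged: bool


@dataclass
class FitResult:
    params: KineticParameters
    sse: float
    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    restarts: list[RestartTrace]
    seed: int
    variant: str

    @property
    def best_restart(self) -> RestartTrace:
        return min(self.restarts, key=lambda r: r.sse)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.as_dict(),
            "sse": self.sse,
            "free": list(self.free),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "restarts": [asdict(r) for r in self.restarts],
        }


def _transform(values: np.ndarray, names: tuple[str, ...], to_log: bool) -> np.ndarray:
    out = values.astype(float).copy()
    for i, name in enumerate(names):
        if name not in HILL_NAMES:
            out[i] = np.log10(out[i]) if to_log else 10 ** out[i]
    return out


def fit_model(
    variant: ModelVariant | str,
    data: ExperimentalDataset,
    config: FitConfig | None = None,
    base_params: KineticParameters | None = None,
) -> FitResult:
    """Multistart Hooke–Jeeves least-squares fit of the free parameters.

    Free rate/affinity parameters are searched in log10 coordinates; Hill
    coefficients linearly.  Fixed parameters come from `base_params`
    updated with `config.fixed`.
    """
    config = config or FitConfig()
    variant = ModelVariant.coerce(variant)
    base = (base_params or KineticParameters()).replace(**config.fixed)
    names = tuple(config.free)
    if not names:
        raise ValueError("no free parameters")

    nat_bounds = np.array([config.bounds[n] for n in names], dtype=float)
    log_mask = np.array([n not in HILL_NAMES for n in names])
    search_bounds = nat_bounds.copy()
    search_bounds[log_mask] = np.log10(search_bounds[log_mask])

    def objective(z: np.ndarray) -> float:
        vals = _transform(np.asarray(z), names, to_log=False)
        p = base.replace(**dict(zip(names, vals)))
        return sse_objective(p, data, variant, rtol=config.rtol, atol=config.atol)

    if config.starts is not None:
        nat_starts = np.array([[s[n] for n in names] for s in config.starts])
    else:
        nat_starts = latin_hypercube_starts(
            nat_bounds, config.restarts, seed=config.seed, log_mask=log_mask
        )

    restarts: list[RestartTrace] = []
    best_z, best_sse = None, math.inf
    span = search_bounds[:, 1] - search_bounds[:, 0]
    for nat_start in nat_starts:
        z0 = _transform(nat_start, names, to_log=True)
        z0 = np.clip(z0, search_bounds[:, 0], search_bounds[:, 1])
        z, sse, trace = hooke_jeeves_minimize(
            objective,
            z0,
            search_bounds,
            step_init=config.step_frac * span,
            step_reduce=config.step_reduce,
            tol=config.tol,
            max_evals=config.max_evals,
        )
        n_evals = trace[-1][0] if trace else 0
        restarts.append(
            RestartTrace(
                start=dict(zip(names, nat_start.tolist())),
                end=dict(zip(names, _transform(z, names, to_log=False).tolist())),
                sse=sse,
                n_evals=n_evals,
                converged=n_evals < config.max_evals,
            )
        )
        if sse < best_sse:
            best_z, best_sse = z, sse

    if best_z is None or not math.isfinite(best_sse):
        raise RuntimeError(
            "all restarts failed; per-restart SSE: "
            + ", ".join(f"{r.sse:.3g}" for r in restarts)
        )
    best_vals = _transform(best_z, names, to_log=False)
    best = base.replace(**dict(zip(names, best_vals.tolist())))
    return FitResult(
        params=best,
        sse=best_sse,
        free=names,
        bounds={n: tuple(config.bounds[n]) for n in names},
        restarts=restarts,
        seed=config.seed,
        variant=variant.value,
    )
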