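"""Kinetic parameter set for the lsr AI-2 uptake circuit.

The default values are the published best-fit constants of the modified
(two-repressor) model.  Two extra fields are artifact additions: ``nG``
(cooperativity of the second repressor, default 1 — no evidence of
cooperativity) and ``s_rep`` (Miller units per µM of reporter protein,
default 1; calibrated downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields, replace
from pathlib import Path
from typing import Iterator

__all__ = ["KineticParameters", "validate_params", "PARAM_NAMES", "HILL_NAMES"]

#: parameters that are Hill cooperativities (linear, >= 1); everything else
#: is a nonnegative rate/affinity searched in log space by the fitter.
HILL_NAMES = ("nOP", "nR", "nG")


@dataclass(frozen=True)
class KineticParameters:
    """Rate, affinity and cooperativity constants (µM / min units).

    Attributes
    ----------
    k_op : float
        Maximal synthesis rate of the transporter/second-repressor pair
        driven by the lsr promoter (µM·min⁻¹).
    k_r : float
        Maximal LsrR synthesis rate (µM·min⁻¹).
    k1 : float
        LsrR → lsr-promoter repression coefficient (µM).
    k2 : float
        LsrR auto-repression coefficient (µM).
    k3 : float
        Phospho-AI-2 / LsrR binding rate (µM⁻¹·min⁻¹).
    k4 : float
        Second-repressor → lsr-promoter repression coefficient (µM).
    k5 : float
        Phospho-AI-2 / second-repressor binding rate (µM⁻¹·min⁻¹).
    k_f : float
        Alternative-pathway import rate, first order in external AI-2
        (min⁻¹).
    k_imp : float
        Transporter-mediated import rate (µM⁻¹·min⁻¹).
    nOP, nR, nG : float
        Hill cooperativities (dimensionless, ≥ 1).
    k_deg : float
        Protein decay / dilution rate (min⁻¹).
    s_rep : float
        Miller units per µM of reporter protein.
    """

    k_op: float = 7.0
    k_r: float = 2.0
    k1: float = 0.2
    k2: float = 0.1
    k3: float = 0.05
    k4: float = 65.0
    k5: float = 1e-4
    k_f: float = 0.01
    k_imp: float = 0.01
    nOP: float = 4.0
    nR: float = 4.0
    nG: float = 1.0
    k_deg: float = 0.02
    s_rep: float = 1.0

    def replace(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())

    # --- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(KineticParameters))


def validate_params(p: KineticParameters) -> list[str]:
    """Return a list of invariant violations (empty list means admissible).

    Every rate/affinity must be >= 0 and every Hill coefficient >= 1;
    each violation message names the offending field.
    """
    violations: list[str] = []
    for name, value in p:
        if not (value == value) or value in (float("inf"), float("-inf")):
            violations.append(f"{name}: must be finite, got {value!r}")
            continue
        if name in HILL_NAMES:
            if value < 1.0:
                violations.append(f"{name}: Hill coefficient must be >= 1, got {value}")
        elif value < 0.0:
            violations.append(f"{name}: must be >= 0, got {value}")
    return violations
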