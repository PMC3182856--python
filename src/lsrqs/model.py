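"""Circuit topologies, knockout transforms and ODE right-hand sides.

Three nested topology variants are supported:

* ``FIRST`` — single repressor (LsrR) with auto-repression, active import
  plus a first-order alternative import flux, and sequestration of the
  repressor by phospho-AI-2.
* ``REG_NO_BINDING`` — adds a second promoter-driven repressor (``G``)
  acting on the lsr promoter, but without ligand sequestration (k5 ≡ 0).
* ``REG_BINDING`` — the full modified model: the second repressor is also
  sequestered by phospho-AI-2.

State vector layout (all µM):

====  =========================================================
OP    transporter
G     second repressor (identically 0 for FIRST)
R     LsrR
Ap    phospho-AI-2
U     unphosphorylated internal AI-2 (nonzero only for ΔlsrK)
Aout  external AI-2
C_R   LsrR·AI-2-P complex
C_G   second-repressor·AI-2-P complex
Y     reporter protein (promoter fusion; never knocked out)
====  =========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from .params import KineticParameters, validate_params

__all__ = [
    "ModelVariant",
    "KnockoutSet",
    "ModelSpec",
    "STATE_VARS",
    "N_STATE",
    "promoter_activity",
    "rhs",
    "apply_knockouts",
    "initial_state",
    "scenario_label",
    "knockouts_from_label",
]

STATE_VARS: tuple[str, ...] = ("OP", "G", "R", "Ap", "U", "Aout", "C_R", "C_G", "Y")
N_STATE = len(STATE_VARS)
_IDX = {name: i for i, name in enumerate(STATE_VARS)}


class ModelVariant(str, Enum):
    FIRST = "first"
    REG_NO_BINDING = "reg_no_binding"
    REG_BINDING = "reg_binding"

    @property
    def has_reg(self) -> bool:
        return self is not ModelVariant.FIRST

    @classmethod
    def coerce(cls, v: "ModelVariant | str") -> "ModelVariant":
        return v if isinstance(v, cls) else cls(str(v).lower())


@dataclass(frozen=True)
class KnockoutSet:
    """Genes removed on top of the luxS-null background."""

    lsr_operon: bool = False
    lsrR: bool = False
    lsrK: bool = False

    @classmethod
    def from_names(cls, names) -> "KnockoutSet":
        names = set(names)
        valid = {"lsr_operon", "lsrR", "lsrK"}
        unknown = names - valid
        if unknown:
            raise ValueError(f"unknown knockout(s): {sorted(unknown)}; valid: {sorted(valid)}")
        return cls(**{n: n in names for n in valid})

    def names(self) -> tuple[str, ...]:
        return tuple(n for n in ("lsr_operon", "lsrR", "lsrK") if getattr(self, n))


#: scenario string labels used in datasets and CLI config
INTACT_LABEL = "intact"


def scenario_label(ko: KnockoutSet) -> str:
    names = ko.names()
    return "+".join(names) if names else INTACT_LABEL


def knockouts_from_label(label: str) -> KnockoutSet:
    label = label.strip()
    if label == INTACT_LABEL:
        return KnockoutSet()
    return KnockoutSet.from_names(label.split("+"))


@dataclass(frozen=True)
class ModelSpec:
    """A topology variant plus a knockout set plus parameters."""

    variant: ModelVariant = ModelVariant.REG_BINDING
    knockouts: KnockoutSet = field(default_factory=KnockoutSet)
    params: KineticParameters = field(default_factory=KineticParameters)

    def __post_init__(self):
        object.__setattr__(self, "variant", ModelVariant.coerce(self.variant))

    def with_params(self, p: KineticParameters) -> "ModelSpec":
        return ModelSpec(self.variant, self.knockouts, p)


def _hill(x: float, k: float, n: float) -> float:
    """Repression factor 1/(1+(x/k)^n); x clipped at 0 for solver probes."""
    if x <= 0.0:
        return 1.0
    if k == 0.0:
        return 0.0
    return 1.0 / (1.0 + (x / k) ** n)


def promoter_activity(
    R: float,
    G: float,
    p: KineticParameters,
    variant: ModelVariant | str = ModelVariant.REG_BINDING,
) -> float:
    """lsr-promoter synthesis rate (µM·min⁻¹) at free-repressor levels R, G.

    FIRST: ``k_op / (1 + (R/k1)^nOP)``.  REG variants multiply in a second
    repression factor ``1 / (1 + (G/k4)^nG)``.  Strictly decreasing in each
    repressor, → k_op as both vanish.
    """
    variant = ModelVariant.coerce(variant)
    if R < 0 or G < 0:
        raise ValueError(f"repressor concentrations must be >= 0 (R={R}, G={G})")
    if p.k1 == 0 and R > 0:
        raise ValueError("k1=0 with nonzero LsrR is singular")
    rate = p.k_op * _hill(R, p.k1, p.nOP)
    if variant.has_reg:
        if p.k4 == 0 and G > 0:
            raise ValueError("k4=0 with nonzero second repressor is singular")
        rate *= _hill(G, p.k4, p.nG)
    return rate


def apply_knockouts(spec: ModelSpec) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the spec (variant + knockouts) into a right-hand side f(t, y).

    Knockout semantics:

    * ``lsr_operon`` — transporter and second-repressor synthesis are
      removed (both are lsr-promoter-driven); import reduces to the
      alternative flux.  The reporter fusion remains.
    * ``lsrR`` — the LsrR equation is removed (R ≡ 0).
    * ``lsrK`` — phosphorylation is blocked: the import flux is routed to
      an inert internal pool U and Ap ≡ 0.
    """
    bad = validate_params(spec.params)
    if bad:
        raise ValueError("inadmissible parameters: " + "; ".join(bad))
    p = spec.params
    variant = spec.variant
    ko = spec.knockouts

    has_reg = variant.has_reg
    k5 = 0.0 if variant is ModelVariant.REG_NO_BINDING else p.k5
    op_driven = not ko.lsr_operon  # gates OP and G synthesis
    has_R = not ko.lsrR
    has_K = not ko.lsrK

    k_op, k_r = p.k_op, p.k_r
    k1, k2, k3, k4 = p.k1, p.k2, p.k3, p.k4
    k_f, k_imp, k_deg = p.k_f, p.k_imp, p.k_deg
    nOP, nR, nG = p.nOP, p.nR, p.nG
    isfinite = math.isfinite

    # hot path: called thousands of times per integration, so scalar math
    # only, no numpy allocation
    def f(t, y):
        OP, G, R, Ap, U, Aout, C_R, C_G, Y = y
        if not isfinite(OP + G + R + Ap + U + Aout + C_R + C_G + Y):
            raise FloatingPointError(f"non-finite state at t={t}: {tuple(y)}")

        P = k_op * _hill(R, k1, nOP)
        if has_reg:
            P *= _hill(G, k4, nG)

        import_flux = (k_imp * OP + k_f) * Aout
        bind_R = k3 * R * Ap if has_R else 0.0
        bind_G = k5 * G * Ap if has_reg else 0.0
        P_syn = P if op_driven else 0.0

        return (
            P_syn - k_deg * OP,
            (P_syn - k_deg * G - bind_G) if has_reg else 0.0,
            (k_r * _hill(R, k2, nR) - k_deg * R - bind_R) if has_R else 0.0,
            (import_flux - bind_R - bind_G) if has_K else 0.0,
            0.0 if has_K else import_flux,
            -import_flux,
            bind_R - k_deg * C_R,
            bind_G - k_deg * C_G,
            P - k_deg * Y,
        )

    return f


def rhs(state: np.ndarray, p: KineticParameters, spec: ModelSpec) -> np.ndarray:
    """Evaluate d(state)/dt once (convenience wrapper over apply_knockouts)."""
    f = apply_knockouts(spec.with_params(p))
    return np.asarray(f(0.0, np.asarray(state, dtype=float)))


def initial_state(dose: float) -> np.ndarray:
    """All-zero state except external AI-2 at `dose` µM."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    y0 = np.zeros(N_STATE)
    y0[_IDX["Aout"]] = dose
    return y0
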