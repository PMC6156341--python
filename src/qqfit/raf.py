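"""Closed-form equilibrium model of Raf dimerization and inhibitor binding.

Raf monomers (R) dimerize (RR) and each protomer can bind a small-molecule
inhibitor (I).  Six species are tracked — R, I, RI, RR, RIR, RIRI — governed
by six association constants K1..K6 (μM⁻¹), of which only four are
independent: detailed balance around the reaction cycles forces

    K4 = K1·K3/K2        and        K6 = K1·K3·K5/K2².

The reaction topology is: K1 for R + R ⇌ RR, K2 for R + I ⇌ RI, K3 for
RR + I ⇌ RIR (first inhibitor binding to the dimer), K5 for RIR + I ⇌ RIRI
(second binding).  With K3 ≫ K2 ≫ K5 this reproduces the paradoxical
activation of Raf by low inhibitor doses: binding one inhibitor to a dimer
stabilizes the dimer, transiently raising the active pool A = RR + RIR.

Free inhibitor I is a clamped (controlled) variable; total Raf R_tot is
conserved.  Given (R_tot, I), free monomer R is the positive root of

    2·K1·(1 + K3·I + K3·K5·I²)·R² + (1 + K2·I)·R − R_tot = 0,

and every other species follows by mass action.  Concentrations are in μM
throughout; no unit conversion is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "EquilibriumConstants",
    "EquilibriumState",
    "derive_constants",
    "solve_equilibrium",
    "occupancy",
    "activity",
    "RafEquilibriumAdapter",
    "GROUND_TRUTH",
]

#: Ground-truth association constants used by the synthetic-data generators
#: (K1, K2, K3, K5) in μM⁻¹.
GROUND_TRUTH: dict[str, float] = {"K1": 0.04, "K2": 20.0, "K3": 4000.0, "K5": 0.1}

#: Default total Raf concentration, μM.
DEFAULT_R_TOT: float = 50.0


@dataclass(frozen=True)
class EquilibriumConstants:
    """The six association constants (μM⁻¹); K4, K6 derived by detailed balance."""

    K1: float
    K2: float
    K3: float
    K5: float
    K4: float
    K6: float

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "K3", "K5", "K4", "K6"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (μM) at equilibrium for a given (R_tot, I)."""

    R: float
    I: float
    RI: float
    RR: float
    RIR: float
    RIRI: float
    R_tot: float

    def conservation_residual(self) -> float:
        """|R + RI + 2(RR + RIR + RIRI) − R_tot|, absolute μM."""
        return abs(self.R + self.RI + 2.0 * (self.RR + self.RIR + self.RIRI) - self.R_tot)


def derive_constants(K1: float, K2: float, K3: float, K5: float) -> EquilibriumConstants:
    """Build the full constant set from the four independent constants.

    K4 = K1*K3/K2 and K6 = K1*K3*K5/K2**2 are filled in exactly.
    Raises ``ValueError`` for non-positive inputs.
    """
    for name, v in (("K1", K1), ("K2", K2), ("K3", K3), ("K5", K5)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v!r}")
    K4 = K1 * K3 / K2
    K6 = K1 * K3 * K5 / K2**2
    return EquilibriumConstants(K1=K1, K2=K2, K3=K3, K5=K5, K4=K4, K6=K6)


def _free_monomer(k: EquilibriumConstants, R_tot, I):
    """Positive root of the mass-conservation quadratic; vectorized over I.

    Uses the cancellation-free form R = 2*R_tot / (b + sqrt(b² + 8*K1*c*R_tot))
    with b = 1 + K2*I and c = 1 + K3*I + K3*K5*I²; falls back to the linear
    solution R = R_tot/b when the quadratic coefficient underflows.
    """
    I = np.asarray(I, dtype=float)
    b = 1.0 + k.K2 * I
    a2 = 2.0 * k.K1 * (1.0 + k.K3 * I + k.K3 * k.K5 * I**2)
    disc = b * b + 4.0 * a2 * R_tot
    R = np.where(a2 < 1e-300, R_tot / b, 2.0 * R_tot / (b + np.sqrt(disc)))
    return R


def solve_equilibrium(
    constants: EquilibriumConstants, R_tot: float = DEFAULT_R_TOT, I: float = 0.0
) -> EquilibriumState:
    """Solve the equilibrium at total Raf ``R_tot`` (μM) and free inhibitor ``I`` (μM)."""
    if not R_tot > 0:
        raise ValueError(f"R_tot must be positive, got {R_tot!r}")
    if I < 0:
        raise ValueError(f"free inhibitor concentration must be >= 0, got {I!r}")
    R = float(_free_monomer(constants, R_tot, I))
    assert R > 0, "mass-conservation quadratic has no positive root"
    RI = constants.K2 * R * I
    RR = constants.K1 * R * R
    RIR = constants.K3 * RR * I
    RIRI = constants.K5 * RIR * I
    return EquilibriumState(R=R, I=I, RI=RI, RR=RR, RIR=RIR, RIRI=RIRI, R_tot=R_tot)


def occupancy(state: EquilibriumState) -> float:
    """Fraction of Raf protomers bound by inhibitor, Ȳ = (RI + RIR + 2·RIRI)/R_tot."""
    return (state.RI + state.RIR + 2.0 * state.RIRI) / state.R_tot


def activity(state: EquilibriumState) -> float:
    """Active Raf pool A = RR + RIR (μM): dimers with at most one inhibitor bound."""
    return state.RR + state.RIR


class RafEquilibriumAdapter:
    """Model adapter exposing the equilibrium model to the objective machinery.

    Condition record: ``{"R_tot": μM, "I": μM}`` (R_tot optional, defaults to
    the adapter's fixed total).  Declared outputs: ``occupancy`` (fraction)
    and ``activity`` (μM).  Parameters: K1, K2, K3, K5; any subset may be
    supplied at evaluation time, the rest fall back to ``fixed_params``.
    """

    output_names = ("occupancy", "activity")

    def __init__(self, fixed_params: Mapping[str, float] | None = None,
                 R_tot: float = DEFAULT_R_TOT):
        self.fixed_params = dict(GROUND_TRUTH if fixed_params is None else fixed_params)
        self.R_tot = float(R_tot)

    def _constants(self, params: Mapping[str, float]) -> EquilibriumConstants:
        merged = {**self.fixed_params, **dict(params)}
        return derive_constants(merged["K1"], merged["K2"], merged["K3"], merged["K5"])

    def evaluate(self, params: Mapping[str, float], condition: Mapping[str, float]
                 ) -> dict[str, float]:
        state = solve_equilibrium(
            self._constants(params),
            R_tot=float(condition.get("R_tot", self.R_tot)),
            I=float(condition["I"]),
        )
        return {"occupancy": occupancy(state), "activity": activity(state)}

    def evaluate_batch(self, params: Mapping[str, float],
                       conditions: list[Mapping[str, float]]) -> dict[str, np.ndarray]:
        """Vectorized evaluation over a list of conditions (same output names)."""
        k = self._constants(params)
        R_tot = np.array([float(c.get("R_tot", self.R_tot)) for c in conditions])
        I = np.array([float(c["I"]) for c in conditions])
        R = _free_monomer(k, R_tot, I)
        RI = k.K2 * R * I
        RR = k.K1 * R * R
        RIR = k.K3 * RR * I
        RIRI = k.K5 * RIR * I
        return {
            "occupancy": (RI + RIR + 2.0 * RIRI) / R_tot,
            "activity": RR + RIR,
        }
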