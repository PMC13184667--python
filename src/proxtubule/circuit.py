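"""Equivalent five-resistor bridge analysis of the epithelium.

The five membranes form a Wheatstone-like bridge between the luminal node
and the grounded serosal bath: the transcellular limb is apical (R1) in
series with serosal (R2), the paracellular limb tight junction (R4) in
series with interspace basement membrane (R5), and the lateral membrane
(R3) bridges the cell and lis nodes. Lumped resistances come from the sum
of chord conductances of the conductive pathways of each membrane; a small
transepithelial current step ΔI_trans then yields branch currents and the
slope response V_trans = I1·R1 + I2·R2 = I4·R4 + I5·R5.

This layer is a small-signal diagnostic about a solved nonlinear state; the
open-circuit transepithelial potential itself is an unknown of the
nonlinear system (:mod:`proxtubule.balance`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import BathComposition, EpithelialState, ModelParameters
from .flux_laws import chord_conductances

__all__ = [
    "BridgeCircuit",
    "lump_resistances",
    "solve_bridge",
    "transepithelial_potential",
    "bridge_from_state",
]

# resistor-to-membrane mapping
RESISTOR_MEMBRANES = ("am", "sm", "lm", "tj", "ibm")  # R1..R5


@dataclass
class BridgeCircuit:
    """Lumped resistances (Ω·m²), injected current step (A·m⁻²) and, once
    solved, the five branch currents (A·m⁻²)."""

    R1: float
    R2: float
    R3: float
    R4: float
    R5: float
    dItrans: float = 0.0
    currents: np.ndarray | None = None

    @property
    def resistances(self) -> tuple[float, float, float, float, float]:
        return (self.R1, self.R2, self.R3, self.R4, self.R5)


def lump_resistances(
    conductances: dict[str, dict[str, float]]
) -> tuple[float, float, float, float, float]:
    """R^m = 1/ΣG over each membrane's conductive pathways, returned in the
    bridge order (R1=am, R2=sm, R3=lm, R4=tj, R5=ibm)."""
    out = []
    for m in RESISTOR_MEMBRANES:
        g = sum(conductances[m].values())
        if not np.isfinite(g):
            raise ValueError(f"non-finite conductance on membrane {m}")
        if g <= 0:
            raise ValueError(f"membrane {m} has zero total conductance")
        out.append(1.0 / g)
    return tuple(out)


def solve_bridge(
    R1: float, R2: float, R3: float, R4: float, R5: float, dItrans: float
) -> np.ndarray:
    """Branch currents (I1..I5) of the bridge under an injected
    transepithelial current step, from a direct linear solve of the two
    Kirchhoff loop equations, the two node equations and the injected
    current:

        I1·R1 + I3·R3 − I4·R4 = 0          (lumen→cell→lis loop)
        I3·R3 + I5·R5 − I2·R2 = 0          (cell→lis→serosa loop)
        I2 + I5 = ΔI_trans                 (current collected at serosa)
        I1 − I2 − I3 = 0                   (cell node)
        I4 + I3 − I5 = 0                   (lis node)

    I3 is oriented cell→lis. At Wheatstone balance (R1·R5 = R2·R4) the
    bridge current I3 vanishes."""
    for r in (R1, R2, R3, R4, R5):
        if r <= 0 or not np.isfinite(r):
            raise ValueError("resistances must be positive and finite")
    A = np.array([
        [R1, 0.0, R3, -R4, 0.0],
        [0.0, -R2, R3, 0.0, R5],
        [0.0, 1.0, 0.0, 0.0, 1.0],
        [1.0, -1.0, -1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, 1.0, -1.0],
    ])
    b = np.array([0.0, 0.0, dItrans, 0.0, 0.0])
    try:
        currents = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - positive R
        raise ValueError("singular bridge system") from exc
    return currents


def transepithelial_potential(circuit: BridgeCircuit) -> float:
    """V_trans response of a solved bridge, I1·R1 + I2·R2 (identically
    I4·R4 + I5·R5)."""
    if circuit.currents is None:
        raise ValueError("bridge circuit has not been solved")
    i = circuit.currents
    return float(i[0] * circuit.R1 + i[1] * circuit.R2)


def bridge_from_state(
    state: EpithelialState,
    params: ModelParameters,
    baths: BathComposition,
    dItrans: float,
) -> BridgeCircuit:
    """Lump the chord conductances of a solved state and apply a current
    step."""
    R = lump_resistances(chord_conductances(state, params, baths))
    circuit = BridgeCircuit(*R, dItrans=dItrans)
    circuit.currents = solve_bridge(*R, dItrans)
    return circuit
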