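"""Algebraic constraints closing the system, and the residual vector.

At a steady state all 16 residuals vanish: eight solute mass balances (cell
and lis × Na, K, Cl, glucose), two water balances, the two electroneutrality
identities, the open-circuit condition, the compliance pressure closure and
the two volume closures. The same residuals, with the conservation rows
replaced by their backward-difference forms, drive the transient integrator
(:mod:`proxtubule.solver`).

Unknown ordering (16 entries)::

    [cNaC, cKC, cClC, cGlucC, cAC,
     cNaL, cKL, cClL, cGlucL,
     psiC, psiL, psiO, pC, pL, volC, volL]

Pressures are carried as excess over the serosal bath pressure inside the
solver vector for conditioning; the state object stores absolute Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import (
    ATM,
    BathComposition,
    EpithelialState,
    GeometryCompliance,
    ModelParameters,
)
from .flux_laws import FluxSet, compute_fluxes

__all__ = [
    "N_UNKNOWNS",
    "ResidualVector",
    "impermeant_concentration",
    "lis_chloride",
    "open_circuit_residual",
    "cell_pressure",
    "lis_volume",
    "cell_volume",
    "assemble_residuals",
    "state_to_vector",
    "vector_to_state",
    "UNKNOWN_SCALES",
    "RESIDUAL_NAMES",
]

N_UNKNOWNS = 16

# characteristic magnitudes used to scale the Newton unknowns
UNKNOWN_SCALES = np.array(
    [100.0] * 9           # concentrations, mol·m⁻³
    + [0.025] * 3         # potentials, V (RT/F)
    + [100.0, 100.0]      # pressure excess over serosa, Pa
    + [1e-5, 3e-7]        # volumes, m³·m⁻²
)

# characteristic magnitudes used to scale the residuals
_FLUX_SCALE = 1e-6       # mol·m⁻²·s⁻¹
_WATER_SCALE = 1e-8      # m·s⁻¹
_CHARGE_SCALE = 1.0      # mol·m⁻³ (electroneutrality rows)
_CURRENT_SCALE = 0.1     # A·m⁻²
_PRESSURE_SCALE = 100.0  # Pa

RESIDUAL_NAMES = (
    "cell_na", "cell_k", "cell_cl", "cell_gluc",
    "lis_na", "lis_k", "lis_cl", "lis_gluc",
    "cell_water", "lis_water",
    "cell_electroneutrality", "lis_electroneutrality",
    "open_circuit", "cell_pressure", "lis_volume", "cell_volume",
)


# ---------------------------------------------------------------------------
# individual closures


def impermeant_concentration(
    cNaC: float, cKC: float, cClC: float, zA: float
) -> float:
    """Cell impermeant-anion concentration from electroneutrality:
    cAᶜ = (cNaᶜ + cKᶜ − cClᶜ)/(−z_A), with z_A < 0."""
    if zA >= 0:
        raise ValueError("mean impermeant valence zA must be negative")
    net = cNaC + cKC - cClC
    if net < 0:
        raise ValueError(
            "cell cation deficit: cNa + cK < cCl implies negative impermeant content"
        )
    return net / (-zA)


def lis_chloride(cNaL: float, cKL: float) -> float:
    """lis electroneutrality: the space holds no impermeant species, so
    cClˡ = cNaˡ + cKˡ."""
    if cNaL < 0 or cKL < 0:
        raise ValueError("concentrations must be >= 0")
    return cNaL + cKL


def open_circuit_residual(fluxes: FluxSet, Iclamp: float, F: float) -> float:
    """I_clamp − Σ apical currents (A·m⁻²); zero at an open-circuit solution
    with I_clamp = 0."""
    return Iclamp - fluxes.apical_current(F)


def cell_pressure(
    geometry: GeometryCompliance, pO: float, pL: float, pS: float
) -> float:
    """Compliance average pᶜ = (μᵃᵐ·pᵒ + μˡᵐ·pˡ + μˢᵐ·pˢ)/Σμ, which always
    lies between the extreme inputs."""
    total = geometry.muAm + geometry.muLm + geometry.muSm
    if total <= 0:
        raise ValueError("compliance weights must have a positive sum")
    return (geometry.muAm * pO + geometry.muLm * pL + geometry.muSm * pS) / total


def lis_volume(geometry: GeometryCompliance, pL: float, pC: float) -> float:
    """Compliant lis volume Volˡ = Volˡ·ʳᵉᶠ·(1 + μˡᵐ·(pˡ − pᶜ))."""
    vol = geometry.volLisRef * (1.0 + geometry.muLm * (pL - pC))
    if vol <= 0:
        raise ValueError("lis volume collapsed to a non-positive value")
    return vol


def cell_volume(geometry: GeometryCompliance, cAC: float) -> float:
    """Volume of the functional syncytium, Volᶜ = Dᶜ·M_A/cAᶜ: the fixed
    impermeant content diluted to the impermeant concentration."""
    if cAC <= 0:
        raise ValueError("impermeant concentration must be positive")
    return geometry.impermeant_content / cAC


# ---------------------------------------------------------------------------
# residual assembly


@dataclass
class ResidualVector:
    """Scaled residuals plus the flux set they were computed from."""

    values: np.ndarray
    fluxes: FluxSet

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.values)))

    def by_name(self) -> dict[str, float]:
        return dict(zip(RESIDUAL_NAMES, self.values.tolist()))


def conservation_rates(fluxes: FluxSet) -> np.ndarray:
    """Right-hand sides of the ten conservation laws, in the order
    (cell Na, K, Cl, gluc; lis Na, K, Cl, gluc; cell water, lis water):
    net influx minus efflux per compartment, per unit apical area."""
    f = fluxes
    return np.array([
        # cell solutes: in across am (and sm uptake counts negative out)
        f.jNa_am - f.jNa_pump - f.jNa_sm,
        f.jK_am - f.jK_lm_total - f.jK_sm_total,
        f.jCl_am - f.jCl_lm - f.jCl_sm_total,
        f.jGluc_sglt - f.jGluc_glut,
        # lis solutes: in across lm and tj, out across ibm
        f.jNa_pump + f.jNa_tj - f.jNa_ibm,
        f.jK_lm_total + f.jK_tj - f.jK_ibm,
        f.jCl_lm + f.jCl_tj - f.jCl_ibm,
        f.jGluc_glut + f.jGluc_tj - f.jGluc_ibm,
        # water
        f.jV_am + f.jW_sglt - f.jV_lm - f.jV_sm,
        f.jV_lm + f.jV_tj - f.jV_ibm,
    ])


def algebraic_residuals(
    state: EpithelialState,
    params: ModelParameters,
    baths: BathComposition,
    fluxes: FluxSet,
    Iclamp: float = 0.0,
) -> np.ndarray:
    """The six scaled algebraic rows: electroneutrality (cell, lis), open
    circuit, compliance pressure, lis volume, cell volume."""
    geo = params.geometry
    return np.array([
        (state.cNaC + state.cKC - state.cClC + geo.zA * state.cAC) / _CHARGE_SCALE,
        (state.cClL - state.cNaL - state.cKL) / _CHARGE_SCALE,
        open_circuit_residual(fluxes, Iclamp, params.constants.F) / _CURRENT_SCALE,
        (state.pC - cell_pressure(geo, baths.pO, state.pL, baths.pS))
        / _PRESSURE_SCALE,
        (state.volL - geo.volLisRef * (1.0 + geo.muLm * (state.pL - state.pC)))
        / UNKNOWN_SCALES[15],
        (state.volC * state.cAC - geo.impermeant_content)
        / max(geo.impermeant_content, UNKNOWN_SCALES[14] * _CHARGE_SCALE),
    ])


def assemble_residuals(
    state: EpithelialState,
    params: ModelParameters,
    baths: BathComposition,
    Iclamp: float = 0.0,
) -> ResidualVector:
    """Steady-state residual vector: the ten conservation laws followed by
    the six algebraic constraints, all scaled to O(1) at physiological
    magnitudes."""
    fluxes = compute_fluxes(state, params, baths)
    rates = conservation_rates(fluxes)
    scaled = np.empty(N_UNKNOWNS)
    scaled[:8] = rates[:8] / _FLUX_SCALE
    scaled[8:10] = rates[8:] / _WATER_SCALE
    scaled[10:] = algebraic_residuals(state, params, baths, fluxes, Iclamp)
    if not np.all(np.isfinite(scaled)):
        raise FloatingPointError("non-finite residual encountered")
    return ResidualVector(values=scaled, fluxes=fluxes)


# ---------------------------------------------------------------------------
# packing


def state_to_vector(state: EpithelialState, baths: BathComposition) -> np.ndarray:
    """Scaled unknown vector (pressures as excess over the serosal bath)."""
    raw = np.array([
        state.cNaC, state.cKC, state.cClC, state.cGlucC, state.cAC,
        state.cNaL, state.cKL, state.cClL, state.cGlucL,
        state.psiC, state.psiL, state.psiO,
        state.pC - baths.pS, state.pL - baths.pS,
        state.volC, state.volL,
    ])
    return raw / UNKNOWN_SCALES


def vector_to_state(x: np.ndarray, baths: BathComposition) -> EpithelialState:
    raw = np.asarray(x, dtype=float) * UNKNOWN_SCALES
    return EpithelialState(
        cNaC=raw[0], cKC=raw[1], cClC=raw[2], cGlucC=raw[3], cAC=raw[4],
        cNaL=raw[5], cKL=raw[6], cClL=raw[7], cGlucL=raw[8],
        psiC=raw[9], psiL=raw[10], psiO=raw[11],
        pC=raw[12] + baths.pS, pL=raw[13] + baths.pS,
        volC=raw[14], volL=raw[15],
    )


def default_initial_state(
    params: ModelParameters, baths: BathComposition
) -> EpithelialState:
    """A physiologically plausible admissible guess: textbook cell interior,
    lis equal to the serosal bath, small negative cell potential."""
    geo = params.geometry
    cNaC, cKC, cClC = 10.0, 135.0, 16.0
    cGlucC = max(2.0 * baths.glucO, 0.5)
    cAC = impermeant_concentration(cNaC, cKC, cClC, geo.zA)
    volC = cell_volume(geo, cAC) if geo.impermeant_content > 0 else 1e-5
    return EpithelialState(
        cNaC=cNaC, cKC=cKC, cClC=cClC, cGlucC=cGlucC, cAC=cAC,
        cNaL=baths.naS, cKL=baths.kS, cClL=lis_chloride(baths.naS, baths.kS),
        cGlucL=max(baths.glucS, 0.1),
        psiC=-0.07, psiL=-0.0005, psiO=-0.0005,
        pC=baths.pS + 20.0, pL=baths.pS + 50.0,
        volC=volC, volL=geo.volLisRef,
    )
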