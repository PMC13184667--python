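"""Membrane transport laws.

Every law is a pure function of concentrations, potential, pressure and
parameters. All of them reduce to a single constant-field kernel

    g(w, a, b) = w · (a·eʷ − b) / (eʷ − 1)

with ``w`` the (dimensionless) sum of the electrical field term zFV/RT and,
for leaky barriers with solvent drag, the Péclet number Pe = J_V(1−σ)/P.
The kernel has a removable singularity at w = 0, handled by a three-term
Taylor expansion for |w| < 1e-6, and is evaluated with only negative
exponentials so it cannot overflow.

Sign conventions follow the transport direction of the epithelium: fluxes
are positive lumen→cell, cell→lis, cell→serosa, lumen→lis and lis→serosa.
Membrane potentials passed to the electrodiffusive laws are ψ_I − ψ_II on
the same orientation (see :func:`proxtubule.core_types.membrane_potential`);
the SGLT1 functions alone take the apical membrane potential on the
electrophysiological convention V_am = ψ_cell − ψ_lumen, which is how the
carrier's current–voltage data and its reversal potential are quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_types import (
    BathComposition,
    CarrierParameters,
    EpithelialState,
    ModelParameters,
    PhysicalConstants,
    PumpParameters,
    Sglt1Parameters,
    membrane_potential,
)

__all__ = [
    "FluxSet",
    "ghk_flux",
    "ghk_chord_conductance",
    "nak2cl_flux",
    "sglt1_fluxes",
    "sglt1_reversal_potential",
    "sglt1_conductance",
    "glut1_flux",
    "pump_fluxes",
    "pump_current",
    "epump_from_dg",
    "solvent_drag_ion_flux",
    "convective_neutral_flux",
    "cell_membrane_water_flow",
    "junction_water_flow",
    "lp_to_pf",
    "pf_to_lp",
    "compute_fluxes",
    "chord_conductances",
]

_TAYLOR_SWITCH = 1e-6

# composite SGLT1 activities cGluc·cNa² are referenced to 1 mol·m⁻³ so that
# the carrier permeability keeps units of m·s⁻¹
_C_REF = 1.0


def _ghk_kernel(w: float, a: float, b: float) -> float:
    """w·(a·eʷ − b)/(eʷ − 1); limit a − b as w → 0."""
    if abs(w) < _TAYLOR_SWITCH:
        return (a - b) + 0.5 * w * (a + b) + w * w * (a - b) / 12.0
    if w > 0:
        em = math.exp(-w)
        return w * (a - b * em) / (1.0 - em)
    ep = math.exp(w)
    return w * (a * ep - b) / (ep - 1.0)


def _w_over_expm1(w: float) -> float:
    """w/(eʷ − 1) > 0, with the removable singularity at w = 0."""
    if abs(w) < _TAYLOR_SWITCH:
        return 1.0 - 0.5 * w + w * w / 12.0
    if w > 0:
        em = math.exp(-w)
        return w * em / (1.0 - em)
    return w / math.expm1(w)


def _expm1_over(x: float) -> float:
    """expm1(x)/x > 0, with the removable singularity at x = 0."""
    if abs(x) < _TAYLOR_SWITCH:
        return 1.0 + 0.5 * x + x * x / 6.0
    return math.expm1(x) / x


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# electrodiffusion


def ghk_flux(
    P: float,
    z: int,
    V: float,
    cI: float,
    cII: float,
    constants: PhysicalConstants,
) -> float:
    """Goldman–Hodgkin–Katz constant-field flux, positive I→II.

    Zero exactly at the Nernst potential V = (RT/zF)·ln(cII/cI) and equal to
    the Fick flux P·(cI − cII) at V = 0.
    """
    _require_finite(P=P, V=V, cI=cI, cII=cII)
    if P < 0 or cI < 0 or cII < 0:
        raise ValueError("permeability and concentrations must be >= 0")
    u = z * constants.F * V / constants.RT
    return P * _ghk_kernel(u, cI, cII)


def ghk_chord_conductance(
    P: float,
    z: int,
    V: float,
    cI: float,
    cII: float,
    constants: PhysicalConstants,
) -> float:
    """Integral (chord) conductance G ≥ 0 such that

        zF · ghk_flux(...) = G · (V − E_j),   E_j = (RT/zF)·ln(cII/cI).

    The removable singularity at V = E_j is evaluated by series.
    """
    _require_finite(P=P, V=V, cI=cI, cII=cII)
    if cI <= 0 or cII <= 0:
        raise ValueError("chord conductance needs strictly positive cI, cII")
    if P < 0:
        raise ValueError("permeability must be >= 0")
    u = z * constants.F * V / constants.RT
    uE = math.log(cII / cI)
    zF = z * constants.F
    return (zF * zF / constants.RT) * P * _w_over_expm1(u) * cII * _expm1_over(u - uE)


# ---------------------------------------------------------------------------
# electroneutral cotransport


def nak2cl_flux(
    k: float,
    cNaI: float,
    cKI: float,
    cClI: float,
    cNaII: float,
    cKII: float,
    cClII: float,
) -> tuple[float, float, float]:
    """1Na⁺:1K⁺:2Cl⁻ cotransport, J = r·k·(cNaᴵ·cKᴵ·cClᴵ² − cNaᴵᴵ·cKᴵᴵ·cClᴵᴵ²)
    with r = 1 for Na⁺ and K⁺ and r = 2 for Cl⁻; electroneutral by
    construction."""
    if k < 0:
        raise ValueError("cotransporter rate constant must be >= 0")
    if min(cNaI, cKI, cClI, cNaII, cKII, cClII) < 0:
        raise ValueError("concentrations must be >= 0")
    drive = k * (cNaI * cKI * cClI * cClI - cNaII * cKII * cClII * cClII)
    return drive, drive, 2.0 * drive


# ---------------------------------------------------------------------------
# SGLT1 (2Na⁺ + 1 glucose + nW·H₂O as a divalent composite particle)


def sglt1_reversal_potential(
    cGlucO: float,
    cGlucC: float,
    cNaO: float,
    cNaC: float,
    constants: PhysicalConstants,
) -> float:
    """Reversal potential of the charged SGLT1 flux on the apical-membrane
    convention V_am = ψ_cell − ψ_lumen:

        V_rev = (RT/2F) · ln[(cGlucᵒ·cNaᵒ²)/(cGlucᶜ·cNaᶜ²)]
    """
    if min(cGlucO, cGlucC, cNaO, cNaC) <= 0:
        raise ValueError("reversal potential needs strictly positive concentrations")
    ratio = (cGlucO * cNaO * cNaO) / (cGlucC * cNaC * cNaC)
    return constants.RT / (2.0 * constants.F) * math.log(ratio)


def _sglt1_activities(cGlucO: float, cGlucC: float, cNaO: float, cNaC: float):
    xO = cGlucO * cNaO * cNaO / (_C_REF * _C_REF)
    xC = cGlucC * cNaC * cNaC / (_C_REF * _C_REF)
    return xO, xC


def sglt1_fluxes(
    params: Sglt1Parameters,
    cGlucO: float,
    cGlucC: float,
    cNaO: float,
    cNaC: float,
    Vam: float,
    constants: PhysicalConstants,
) -> tuple[float, float, float]:
    """Coupled SGLT1 fluxes (J_Na, J_Gluc, J_W), all positive lumen→cell.

    The 2Na:1glucose composite crosses a constant-field membrane as one
    divalent particle with composite activities X = cGluc·cNa² (referenced
    to 1 mol·m⁻³) and a saturable permeability

        P = pmax · km / (cGlucᵒ + km).

    ``Vam`` is ψ_cell − ψ_lumen; the flux vanishes exactly at the reversal
    potential of :func:`sglt1_reversal_potential`.  Stoichiometry:
    J_Na = 2·J_Gluc and J_W = nW·J_Gluc·V̄w (J_W in m·s⁻¹).
    """
    _require_finite(Vam=Vam, cGlucO=cGlucO, cGlucC=cGlucC, cNaO=cNaO, cNaC=cNaC)
    if min(cGlucO, cGlucC, cNaO, cNaC) < 0:
        raise ValueError("concentrations must be >= 0")
    if cGlucO + params.km <= 0:
        raise ValueError("cGlucO + km must be positive")
    p_eff = params.pmax * params.km / (cGlucO + params.km)
    xO, xC = _sglt1_activities(cGlucO, cGlucC, cNaO, cNaC)
    # lumen→cell orientation: ψ_I − ψ_II = ψ_o − ψ_c = −Vam
    w = -2.0 * constants.F * Vam / constants.RT
    jNa = p_eff * _ghk_kernel(w, xO, xC)
    jGluc = 0.5 * jNa
    jW = params.nW * jGluc * constants.Vw
    return jNa, jGluc, jW


def sglt1_conductance(
    params: Sglt1Parameters,
    cGlucO: float,
    cGlucC: float,
    cNaO: float,
    cNaC: float,
    Vam: float,
    constants: PhysicalConstants,
) -> float:
    """Integral conductance G ≥ 0 of SGLT1 with the chord identity

        −2F · J_Na = G · (Vam − Vrev),

    i.e. the carrier current measured on the V_am = ψ_cell − ψ_lumen
    convention is G·(Vam − Vrev)."""
    if min(cGlucO, cGlucC, cNaO, cNaC) <= 0:
        raise ValueError("conductance needs strictly positive concentrations")
    p_eff = params.pmax * params.km / (cGlucO + params.km)
    xO, xC = _sglt1_activities(cGlucO, cGlucC, cNaO, cNaC)
    w = -2.0 * constants.F * Vam / constants.RT
    wE = math.log(xC / xO)
    twoF = 2.0 * constants.F
    return (
        (twoF * twoF / constants.RT)
        * p_eff
        * _w_over_expm1(w)
        * xC
        * _expm1_over(w - wE)
    )


# ---------------------------------------------------------------------------
# GLUT1 (Stein's symmetric saturating carrier)


def glut1_flux(params: CarrierParameters, cC: float, cL: float) -> float:
    """Facilitated glucose exit cell→lis:

        J = Jmax·K·(cᶜ − cˡ) / [(K + cᶜ)(K + cˡ)]

    Antisymmetric in its arguments and bounded by ±Jmax."""
    if cC < 0 or cL < 0:
        raise ValueError("concentrations must be >= 0")
    K = params.glut1K
    return params.glut1Jmax * K * (cC - cL) / ((K + cC) * (K + cL))


# ---------------------------------------------------------------------------
# Na⁺/K⁺ pump


def _pump_saturation(params: PumpParameters, cNaC: float, cKL: float) -> float:
    sNa = cNaC / (params.kNa + cNaC)
    sK = cKL / (params.kK + cKL)
    return sNa * sNa * sNa * sK * sK


def pump_fluxes(
    params: PumpParameters, cNaC: float, cKL: float, Vlm: float
) -> tuple[float, float]:
    """Active cation fluxes across the lateral membrane (positive cell→lis):

        J_Na = ppump·[cNaᶜ/(K_Na+cNaᶜ)]³·[cKˡ/(K_K+cKˡ)]²·(V_lm + E_pump)
        J_K  = −(2/3)·J_Na

    The pump reverses at V_lm = −E_pump."""
    if cNaC < 0 or cKL < 0:
        raise ValueError("concentrations must be >= 0")
    jNa = params.ppump * _pump_saturation(params, cNaC, cKL) * (Vlm + params.epump)
    return jNa, -(2.0 / 3.0) * jNa


def pump_current(
    params: PumpParameters,
    cNaC: float,
    cKL: float,
    Vlm: float,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    """Pump current and conductance. One net charge crosses per 3Na:2K
    cycle, so I = F·J_Na/3 = G_pump·(V_lm + E_pump)."""
    jNa, _ = pump_fluxes(params, cNaC, cKL, Vlm)
    gpump = constants.F * params.ppump * _pump_saturation(params, cNaC, cKL) / 3.0
    return constants.F * jNa / 3.0, gpump


def epump_from_dg(
    dgATP: float, constants: PhysicalConstants
) -> tuple[float, float]:
    """(E_pump, V_rev) from the free energy of ATP hydrolysis.

    With 3 Na⁺ translocated per ATP, V_rev = ΔG_ATP/(3F) (negative) and
    E_pump = −V_rev. ΔG_ATP ≈ −58 kJ·mol⁻¹ in well-aerated cells gives
    V_rev ≈ −200 mV."""
    if dgATP > 0:
        raise ValueError("free energy of ATP hydrolysis must be <= 0")
    vrev = dgATP / (3.0 * constants.F)
    return -vrev, vrev


# ---------------------------------------------------------------------------
# paracellular solvent drag / convection


def solvent_drag_ion_flux(
    P: float,
    z: int,
    sigma: float,
    V: float,
    Jv: float,
    cI: float,
    cII: float,
    constants: PhysicalConstants,
) -> float:
    """Hertz electrodiffusion-with-drag through a leaky barrier.

    With u = zFV/RT and Péclet number Pe = J_V·(1−σ)/P the flux is

        J = P·(u + Pe)·(cᴵ·e^{u+Pe} − cᴵᴵ)/(e^{u+Pe} − 1),

    which reduces exactly to :func:`ghk_flux` as J_V → 0 (or σ → 1) and to
    :func:`convective_neutral_flux` as V → 0."""
    _require_finite(P=P, V=V, Jv=Jv, cI=cI, cII=cII)
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("reflection coefficient must lie in [0, 1]")
    if cI < 0 or cII < 0:
        raise ValueError("concentrations must be >= 0")
    drag = Jv * (1.0 - sigma)
    if P <= 0:
        if drag != 0.0:
            raise ValueError("solvent drag with zero permeability is undefined")
        return 0.0
    u = z * constants.F * V / constants.RT
    pe = drag / P
    return P * _ghk_kernel(u + pe, cI, cII)


def convective_neutral_flux(
    P: float, sigma: float, Jv: float, cI: float, cII: float
) -> float:
    """Convection–diffusion of an electroneutral solute (glucose) through a
    leaky barrier: J = J_V(1−σ)·(cᴵ·e^Pe − cᴵᴵ)/(e^Pe − 1) with
    Pe = J_V(1−σ)/P; the Pe → 0 limit is the Fick flux P·(cᴵ − cᴵᴵ)."""
    _require_finite(P=P, Jv=Jv, cI=cI, cII=cII)
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("reflection coefficient must lie in [0, 1]")
    if cI < 0 or cII < 0:
        raise ValueError("concentrations must be >= 0")
    drag = Jv * (1.0 - sigma)
    if P <= 0:
        if drag != 0.0:
            raise ValueError("convective flux with zero permeability is undefined")
        return 0.0
    pe = drag / P
    return P * _ghk_kernel(pe, cI, cII)


# ---------------------------------------------------------------------------
# water


def cell_membrane_water_flow(
    Lp: float,
    sumOsmI: float,
    sumOsmII: float,
    pI: float,
    pII: float,
    constants: PhysicalConstants,
) -> float:
    """Osmotic/hydrostatic water flow across a cell membrane (σ ≡ 1):

        J_V = Lp·[RT·(ΣCᴵᴵ − ΣCᴵ) + pᴵ − pᴵᴵ]

    positive I→II (toward the osmotically richer / hydrostatically lower
    side)."""
    if Lp < 0:
        raise ValueError("hydraulic conductance must be >= 0")
    return Lp * (constants.RT * (sumOsmII - sumOsmI) + pI - pII)


def junction_water_flow(
    Lp: float,
    sigma_by_species: dict[str, float],
    cI_by_species: dict[str, float],
    cII_by_species: dict[str, float],
    pI: float,
    pII: float,
    constants: PhysicalConstants,
) -> float:
    """Water flow across a leaky barrier with per-species reflection
    coefficients, positive I→II:

        J_V = Lp·[RT·Σᵢ σᵢ·(Cᵢᴵᴵ − Cᵢᴵ) + pᴵ − pᴵᴵ]

    For the tight junction (I = lumen, II = lis) and the interspace basement
    membrane (I = lis, II = serosa)."""
    if Lp < 0:
        raise ValueError("hydraulic conductance must be >= 0")
    if set(cI_by_species) != set(sigma_by_species) or set(cII_by_species) != set(
        sigma_by_species
    ):
        raise ValueError("species of baths and reflection coefficients must match")
    osm = 0.0
    for species, sigma in sigma_by_species.items():
        if not 0.0 <= sigma <= 1.0:
            raise ValueError("reflection coefficient must lie in [0, 1]")
        osm += sigma * (cII_by_species[species] - cI_by_species[species])
    return Lp * (constants.RT * osm + pI - pII)


def lp_to_pf(Lp: float, constants: PhysicalConstants) -> float:
    """Hydraulic conductance → osmotic water permeability, Pf = RT·Lp/V̄w."""
    if Lp < 0:
        raise ValueError("hydraulic conductance must be >= 0")
    return constants.RT * Lp / constants.Vw


def pf_to_lp(Pf: float, constants: PhysicalConstants) -> float:
    if Pf < 0:
        raise ValueError("osmotic permeability must be >= 0")
    return Pf * constants.Vw / constants.RT


# ---------------------------------------------------------------------------
# full flux evaluation at a state


@dataclass
class FluxSet:
    """All per-membrane solute fluxes (mol·m⁻²·s⁻¹), water flows (m·s⁻¹)
    and the pump current (A·m⁻²), evaluated at one state.

    Orientation: positive lumen→cell (am), cell→lis (lm), cell→serosa (sm),
    lumen→lis (tj), lis→serosa (ibm).
    """

    # apical membrane
    jNa_enac: float
    jNa_nak2cl_am: float
    jK_nak2cl_am: float
    jCl_nak2cl_am: float
    jNa_sglt: float
    jGluc_sglt: float
    jW_sglt: float
    jV_am: float
    # lateral membrane
    jNa_pump: float
    jK_pump: float
    iPump: float
    jK_lm: float
    jCl_lm: float
    jGluc_glut: float
    jV_lm: float
    # serosal membrane
    jK_sm: float
    jCl_sm: float
    jNa_nak2cl_sm: float
    jK_nak2cl_sm: float
    jCl_nak2cl_sm: float
    jV_sm: float
    # tight junction
    jNa_tj: float
    jK_tj: float
    jCl_tj: float
    jGluc_tj: float
    jV_tj: float
    # interspace basement membrane
    jNa_ibm: float
    jK_ibm: float
    jCl_ibm: float
    jGluc_ibm: float
    jV_ibm: float

    # ---- aggregates -------------------------------------------------------

    @property
    def jNa_am(self) -> float:
        return self.jNa_enac + self.jNa_nak2cl_am + self.jNa_sglt

    @property
    def jK_am(self) -> float:
        return self.jK_nak2cl_am

    @property
    def jCl_am(self) -> float:
        return self.jCl_nak2cl_am

    @property
    def jNa_lm(self) -> float:
        return self.jNa_pump

    @property
    def jK_lm_total(self) -> float:
        return self.jK_pump + self.jK_lm

    @property
    def jNa_sm(self) -> float:
        return self.jNa_nak2cl_sm

    @property
    def jK_sm_total(self) -> float:
        return self.jK_sm + self.jK_nak2cl_sm

    @property
    def jCl_sm_total(self) -> float:
        return self.jCl_sm + self.jCl_nak2cl_sm

    def apical_current(self, F: float) -> float:
        """Total current entering across the apical barriers (am + tj),
        A·m⁻², the left side of the open-circuit condition."""
        return F * (
            self.jNa_am
            + self.jK_am
            - self.jCl_am
            + self.jNa_tj
            + self.jK_tj
            - self.jCl_tj
        )


def compute_fluxes(
    state: EpithelialState, params: ModelParameters, baths: BathComposition
) -> FluxSet:
    """Evaluate every transport law at a state.

    Membrane wiring: the apical membrane carries ENaC (conductive Na⁺), the
    apical 1Na:1K:2Cl cotransporter, SGLT1 and AQP1 water; the lateral
    membrane the Na⁺/K⁺ pump, K⁺ and Cl⁻ channels, GLUT1 and water; the
    serosal membrane K⁺ and Cl⁻ channels, the recirculation 1Na:1K:2Cl
    cotransporter and water. The tight junction passes Na⁺ and K⁺ with
    solvent drag (Claudin-2), Cl⁻ by pure electrodiffusion
    (Claudin-17/10a, water-impermeable) and glucose convectively; the
    interspace basement membrane passes all four species with drag.
    """
    c = params.constants
    mem = params.membranes

    vAm = membrane_potential(state, baths, "am")   # ψ_o − ψ_c
    vLm = membrane_potential(state, baths, "lm")   # ψ_c − ψ_l
    vSm = membrane_potential(state, baths, "sm")   # ψ_c − ψ_s
    vTj = membrane_potential(state, baths, "tj")   # ψ_o − ψ_l
    vIbm = membrane_potential(state, baths, "ibm")  # ψ_l − ψ_s

    # --- water flows (needed for the drag terms) --------------------------
    osmO = baths.osmolarity_lumen
    osmS = baths.osmolarity_serosa
    jV_am = cell_membrane_water_flow(
        mem.am.lp, osmO, state.osmolarity_cell, baths.pO, state.pC, c
    )
    jV_lm = cell_membrane_water_flow(
        mem.lm.lp, state.osmolarity_cell, state.osmolarity_lis, state.pC, state.pL, c
    )
    jV_sm = cell_membrane_water_flow(
        mem.sm.lp, state.osmolarity_cell, osmS, state.pC, baths.pS, c
    )
    sig_tj = {s: mem.tj.sigma(s) for s in ("na", "k", "cl", "gluc")}
    sig_ibm = {s: mem.ibm.sigma(s) for s in ("na", "k", "cl", "gluc")}
    lumen = {"na": baths.naO, "k": baths.kO, "cl": baths.clO, "gluc": baths.glucO}
    serosa = {"na": baths.naS, "k": baths.kS, "cl": baths.clS, "gluc": baths.glucS}
    lis = {
        "na": state.cNaL,
        "k": state.cKL,
        "cl": state.cClL,
        "gluc": state.cGlucL,
    }
    jV_tj = junction_water_flow(
        mem.tj.lp, sig_tj, lumen, lis, baths.pO, state.pL, c
    )
    jV_ibm = junction_water_flow(
        mem.ibm.lp, sig_ibm, lis, serosa, state.pL, baths.pS, c
    )

    # --- apical membrane --------------------------------------------------
    jNa_enac = ghk_flux(mem.am.pNa, 1, vAm, baths.naO, state.cNaC, c)
    jNa_cot_am, jK_cot_am, jCl_cot_am = nak2cl_flux(
        params.carriers.kAmNaK2Cl,
        baths.naO, baths.kO, baths.clO,
        state.cNaC, state.cKC, state.cClC,
    )
    jNa_sglt, jGluc_sglt, jW_sglt = sglt1_fluxes(
        params.sglt1,
        baths.glucO, state.cGlucC, baths.naO, state.cNaC,
        -vAm,  # ψ_c − ψ_o
        c,
    )

    # --- lateral membrane -------------------------------------------------
    jNa_pump, jK_pump = pump_fluxes(params.pump, state.cNaC, state.cKL, vLm)
    iPump, _ = pump_current(params.pump, state.cNaC, state.cKL, vLm, c)
    jK_lm = ghk_flux(mem.lm.pK, 1, vLm, state.cKC, state.cKL, c)
    jCl_lm = ghk_flux(mem.lm.pCl, -1, vLm, state.cClC, state.cClL, c)
    jGluc_glut = glut1_flux(params.carriers, state.cGlucC, state.cGlucL)

    # --- serosal membrane -------------------------------------------------
    jK_sm = ghk_flux(mem.sm.pK, 1, vSm, state.cKC, baths.kS, c)
    jCl_sm = ghk_flux(mem.sm.pCl, -1, vSm, state.cClC, baths.clS, c)
    jNa_cot_sm, jK_cot_sm, jCl_cot_sm = nak2cl_flux(
        params.carriers.kSmNaK2Cl,
        state.cNaC, state.cKC, state.cClC,
        baths.naS, baths.kS, baths.clS,
    )

    # --- tight junction ---------------------------------------------------
    jNa_tj = solvent_drag_ion_flux(
        mem.tj.pNa, 1, mem.tj.sigmaNa, vTj, jV_tj, baths.naO, state.cNaL, c
    )
    jK_tj = solvent_drag_ion_flux(
        mem.tj.pK, 1, mem.tj.sigmaK, vTj, jV_tj, baths.kO, state.cKL, c
    )
    # Cl⁻ crosses the junction through the water-impermeable Claudin-17/10a
    # pore: simple electrodiffusion, no drag
    jCl_tj = ghk_flux(mem.tj.pCl, -1, vTj, baths.clO, state.cClL, c)
    jGluc_tj = convective_neutral_flux(
        mem.tj.pGluc, mem.tj.sigmaGluc, jV_tj, baths.glucO, state.cGlucL
    )

    # --- interspace basement membrane -------------------------------------
    jNa_ibm = solvent_drag_ion_flux(
        mem.ibm.pNa, 1, mem.ibm.sigmaNa, vIbm, jV_ibm, state.cNaL, baths.naS, c
    )
    jK_ibm = solvent_drag_ion_flux(
        mem.ibm.pK, 1, mem.ibm.sigmaK, vIbm, jV_ibm, state.cKL, baths.kS, c
    )
    jCl_ibm = solvent_drag_ion_flux(
        mem.ibm.pCl, -1, mem.ibm.sigmaCl, vIbm, jV_ibm, state.cClL, baths.clS, c
    )
    jGluc_ibm = convective_neutral_flux(
        mem.ibm.pGluc, mem.ibm.sigmaGluc, jV_ibm, state.cGlucL, baths.glucS
    )

    return FluxSet(
        jNa_enac=jNa_enac,
        jNa_nak2cl_am=jNa_cot_am,
        jK_nak2cl_am=jK_cot_am,
        jCl_nak2cl_am=jCl_cot_am,
        jNa_sglt=jNa_sglt,
        jGluc_sglt=jGluc_sglt,
        jW_sglt=jW_sglt,
        jV_am=jV_am,
        jNa_pump=jNa_pump,
        jK_pump=jK_pump,
        iPump=iPump,
        jK_lm=jK_lm,
        jCl_lm=jCl_lm,
        jGluc_glut=jGluc_glut,
        jV_lm=jV_lm,
        jK_sm=jK_sm,
        jCl_sm=jCl_sm,
        jNa_nak2cl_sm=jNa_cot_sm,
        jK_nak2cl_sm=jK_cot_sm,
        jCl_nak2cl_sm=jCl_cot_sm,
        jV_sm=jV_sm,
        jNa_tj=jNa_tj,
        jK_tj=jK_tj,
        jCl_tj=jCl_tj,
        jGluc_tj=jGluc_tj,
        jV_tj=jV_tj,
        jNa_ibm=jNa_ibm,
        jK_ibm=jK_ibm,
        jCl_ibm=jCl_ibm,
        jGluc_ibm=jGluc_ibm,
        jV_ibm=jV_ibm,
    )


def chord_conductances(
    state: EpithelialState, params: ModelParameters, baths: BathComposition
) -> dict[str, dict[str, float]]:
    """Chord conductances (S·m⁻²) of every conductive pathway, grouped by
    membrane, for the equivalent-circuit analysis. Electroneutral carriers
    (the two NaK2Cl cotransporters, GLUT1) carry no current and do not
    appear."""
    c = params.constants
    mem = params.membranes
    vAm = membrane_potential(state, baths, "am")
    vLm = membrane_potential(state, baths, "lm")
    vSm = membrane_potential(state, baths, "sm")
    vTj = membrane_potential(state, baths, "tj")
    vIbm = membrane_potential(state, baths, "ibm")

    _, gPump = pump_current(params.pump, state.cNaC, state.cKL, vLm, c)

    def g(P, z, V, cI, cII):
        if P == 0.0:
            return 0.0
        return ghk_chord_conductance(P, z, V, cI, cII, c)

    out: dict[str, dict[str, float]] = {
        "am": {
            "na": g(mem.am.pNa, 1, vAm, baths.naO, state.cNaC),
            "sglt1": sglt1_conductance(
                params.sglt1, baths.glucO, state.cGlucC, baths.naO, state.cNaC,
                -vAm, c,
            ) if params.sglt1.pmax > 0 else 0.0,
        },
        "lm": {
            "k": g(mem.lm.pK, 1, vLm, state.cKC, state.cKL),
            "cl": g(mem.lm.pCl, -1, vLm, state.cClC, state.cClL),
            "pump": gPump,
        },
        "sm": {
            "k": g(mem.sm.pK, 1, vSm, state.cKC, baths.kS),
            "cl": g(mem.sm.pCl, -1, vSm, state.cClC, baths.clS),
        },
        "tj": {
            "na": g(mem.tj.pNa, 1, vTj, baths.naO, state.cNaL),
            "k": g(mem.tj.pK, 1, vTj, baths.kO, state.cKL),
            "cl": g(mem.tj.pCl, -1, vTj, baths.clO, state.cClL),
        },
        "ibm": {
            "na": g(mem.ibm.pNa, 1, vIbm, state.cNaL, baths.naS),
            "k": g(mem.ibm.pK, 1, vIbm, state.cKL, baths.kS),
            "cl": g(mem.ibm.pCl, -1, vIbm, state.cClL, baths.clS),
        },
    }
    return out
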