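"""Domain types, physical constants and unit conventions.

All quantities are stored internally in MKSA units:

* concentrations   mol·m⁻³  (numerically equal to mM)
* potentials       V, referenced to the serosal (peritubular) bath, ψˢ ≡ 0
* pressures        Pa (absolute)
* volumes          m³ per m² of apical membrane (1 nL·cm⁻² = 1e-8 m³·m⁻²)
* solute fluxes    mol·m⁻²·s⁻¹ (1 pmol·cm⁻²·s⁻¹ = 1e-8 mol·m⁻²·s⁻¹)
* water flows      m·s⁻¹ ≡ m³·m⁻²·s⁻¹ (1 nL·cm⁻²·s⁻¹ = 1e-8 m·s⁻¹)

Presentation layers (protocol tables, the CLI) convert to the customary
physiological units: mM, mV, atm, nL·cm⁻², pmol·cm⁻²·s⁻¹, µA·cm⁻².

The epithelium has two internal compartments — the lumped cell ("functional
syncytium") and the lateral intercellular space (lis) — bounded by five
membranes: apical (am), lateral (lm), serosal (sm), tight junction (tj) and
interspace basement membrane (ibm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PhysicalConstants",
    "BathComposition",
    "CellMembrane",
    "JunctionMembrane",
    "MembranePermeabilities",
    "PumpParameters",
    "Sglt1Parameters",
    "CarrierParameters",
    "GeometryCompliance",
    "ModelParameters",
    "EpithelialState",
    "MEMBRANES",
    "SPECIES",
    "membrane_potential",
    "ATM",
    "atm_to_pa",
    "pa_to_atm",
    "nl_per_cm2_to_m",
    "m_to_nl_per_cm2",
    "pmol_per_cm2s_to_si",
    "si_to_pmol_per_cm2s",
    "nl_per_cm2s_to_si",
    "si_to_nl_per_cm2s",
    "a_per_m2_to_ua_per_cm2",
]

MEMBRANES = ("am", "lm", "sm", "tj", "ibm")
SPECIES = ("na", "k", "cl", "gluc")

ATM = 101325.0  # Pa

# ---------------------------------------------------------------------------
# unit conversions (round-trip exact to machine precision)

def atm_to_pa(p: float) -> float:
    return p * ATM


def pa_to_atm(p: float) -> float:
    return p / ATM


def nl_per_cm2_to_m(v: float) -> float:
    """nL·cm⁻² → m³·m⁻² (volume per unit apical area)."""
    return v * 1e-8


def m_to_nl_per_cm2(v: float) -> float:
    return v * 1e8


def pmol_per_cm2s_to_si(j: float) -> float:
    """pmol·cm⁻²·s⁻¹ → mol·m⁻²·s⁻¹."""
    return j * 1e-8


def si_to_pmol_per_cm2s(j: float) -> float:
    return j * 1e8


def nl_per_cm2s_to_si(jv: float) -> float:
    """nL·cm⁻²·s⁻¹ → m·s⁻¹."""
    return jv * 1e-8


def si_to_nl_per_cm2s(jv: float) -> float:
    return jv * 1e8


def a_per_m2_to_ua_per_cm2(i: float) -> float:
    """A·m⁻² → µA·cm⁻²."""
    return i * 1e2


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants.

    F : Faraday constant, C·mol⁻¹
    R : gas constant, J·mol⁻¹·K⁻¹
    T : absolute temperature, K (default 310 K, mammalian body temperature)
    Vw: molar volume of water, m³·mol⁻¹
    """

    F: float = 96485.33212
    R: float = 8.314462618
    T: float = 310.0
    Vw: float = 1.8e-5

    def __post_init__(self) -> None:
        for name in ("F", "R", "T", "Vw"):
            if not getattr(self, name) > 0:
                raise ValueError(f"physical constant {name} must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T

    @property
    def RT_over_F(self) -> float:
        return self.R * self.T / self.F


@dataclass(frozen=True)
class BathComposition:
    """Well-stirred luminal ("outer", o) and serosal ("inner", s) baths.

    Concentrations in mol·m⁻³; hydrostatic pressures in Pa; the serosal
    electrical potential is the fixed reference, ψˢ ≡ 0.
    """

    naO: float = 146.0
    kO: float = 4.0
    clO: float = 150.0
    glucO: float = 6.0
    naS: float = 146.0
    kS: float = 4.0
    clS: float = 150.0
    glucS: float = 6.0
    pO: float = ATM
    pS: float = ATM
    psiS: float = 0.0

    def __post_init__(self) -> None:
        for name in ("naO", "kO", "clO", "glucO", "naS", "kS", "clS", "glucS"):
            if getattr(self, name) < 0:
                raise ValueError(f"bath concentration {name} must be >= 0")
        if self.psiS != 0.0:
            raise ValueError("the serosal potential is the reference: psiS == 0")

    def lumen(self, species: str) -> float:
        return getattr(self, f"{species}O" if species != "na" else "naO")

    def serosa(self, species: str) -> float:
        return getattr(self, f"{species}S" if species != "na" else "naS")

    @property
    def osmolarity_lumen(self) -> float:
        return self.naO + self.kO + self.clO + self.glucO

    @property
    def osmolarity_serosa(self) -> float:
        return self.naS + self.kS + self.clS + self.glucS

    def with_glucose(self, gluc: float) -> "BathComposition":
        """Both baths set to the same glucose concentration (mol·m⁻³)."""
        return replace(self, glucO=gluc, glucS=gluc)


def _check_sigma(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"reflection coefficient {name}={value} outside [0, 1]")


@dataclass(frozen=True)
class CellMembrane:
    """Permeabilities of one cell membrane (am, lm or sm).

    Ionic permeabilities in m·s⁻¹; hydraulic conductance Lp in
    m·s⁻¹·Pa⁻¹. Water crossing cell membranes sees every solute with a
    reflection coefficient of one (AQP1-type pathway), so no σ is stored.
    A permeability of zero means the pathway is absent from that membrane.
    """

    pNa: float = 0.0
    pK: float = 0.0
    pCl: float = 0.0
    lp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pNa", "pK", "pCl", "lp"):
            if getattr(self, name) < 0:
                raise ValueError(f"membrane parameter {name} must be >= 0")


@dataclass(frozen=True)
class JunctionMembrane:
    """Leaky paracellular barrier (tight junction or interspace basement
    membrane): ionic/glucose permeabilities (m·s⁻¹), hydraulic conductance
    (m·s⁻¹·Pa⁻¹) and per-species reflection coefficients σ = 1 − β.
    """

    pNa: float = 0.0
    pK: float = 0.0
    pCl: float = 0.0
    pGluc: float = 0.0
    lp: float = 0.0
    sigmaNa: float = 0.0
    sigmaK: float = 0.0
    sigmaCl: float = 0.0
    sigmaGluc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pNa", "pK", "pCl", "pGluc", "lp"):
            if getattr(self, name) < 0:
                raise ValueError(f"membrane parameter {name} must be >= 0")
        for name in ("sigmaNa", "sigmaK", "sigmaCl", "sigmaGluc"):
            _check_sigma(getattr(self, name), name)

    def sigma(self, species: str) -> float:
        return getattr(self, "sigma" + species.capitalize())

    def permeability(self, species: str) -> float:
        return getattr(self, "p" + species.capitalize())


@dataclass(frozen=True)
class MembranePermeabilities:
    """The five membranes of the epithelium."""

    am: CellMembrane = field(default_factory=CellMembrane)
    lm: CellMembrane = field(default_factory=CellMembrane)
    sm: CellMembrane = field(default_factory=CellMembrane)
    tj: JunctionMembrane = field(default_factory=JunctionMembrane)
    ibm: JunctionMembrane = field(default_factory=JunctionMembrane)


@dataclass(frozen=True)
class PumpParameters:
    """Lateral Na⁺/K⁺-ATPase (3Na⁺ : 2K⁺ : 1 ATP per cycle).

    ppump : rate coefficient, mol·s⁻¹·V⁻¹ per m² apical membrane
    kNa   : half-saturation for cytosolic Na⁺, mol·m⁻³ (kidney: 3.4)
    kK    : half-saturation for lis K⁺, mol·m⁻³ (kidney: 0.75)
    epump : electromotive force, V (the pump current reverses at
            V_lm = −epump)
    dgATP : free energy of ATP hydrolysis, J·mol⁻¹ (≤ 0); linked to epump
            through the 3 Na⁺ per ATP stoichiometry, epump = −ΔG/(3F)
    """

    ppump: float = 0.0
    kNa: float = 3.4
    kK: float = 0.75
    epump: float = 0.2
    dgATP: float = -58000.0

    def __post_init__(self) -> None:
        if self.ppump < 0 or self.kNa <= 0 or self.kK <= 0:
            raise ValueError("pump parameters must be positive")
        if self.dgATP > 0:
            raise ValueError("free energy of ATP hydrolysis must be <= 0")


@dataclass(frozen=True)
class Sglt1Parameters:
    """Apical 2Na⁺:1-glucose cotransporter with stoichiometric water.

    pmax : maximal permeability of the composite divalent particle, m·s⁻¹
           (composite activities are referenced to 1 mol·m⁻³)
    km   : luminal-glucose half-saturation of the carrier permeability,
           mol·m⁻³ (default 1.0)
    nW   : water molecules co-transported per glucose molecule
           (human SGLT1 ≈ 264, rabbit ≈ 424)
    """

    pmax: float = 0.0
    km: float = 1.0
    nW: float = 264.0

    def __post_init__(self) -> None:
        if self.pmax < 0 or self.km <= 0:
            raise ValueError("SGLT1 pmax must be >= 0 and km > 0")
        if self.nW < 0:
            raise ValueError("SGLT1 water coupling ratio nW must be >= 0")


@dataclass(frozen=True)
class CarrierParameters:
    """Electroneutral carriers: lateral GLUT1 and the two 1Na:1K:2Cl
    cotransporters (apical uptake; serosal recirculation, off by default).

    glut1Jmax  : maximal GLUT1 flux, mol·m⁻²·s⁻¹
    glut1K     : GLUT1 half-saturation, mol·m⁻³
    kAmNaK2Cl  : apical cotransporter rate constant,
                 mol·m⁻²·s⁻¹·(mol·m⁻³)⁻⁴ (flux = k·Δ(cNa·cK·cCl²))
    kSmNaK2Cl  : serosal recirculation cotransporter rate constant, same
                 units; zero in the non-recirculating reference state
    """

    glut1Jmax: float = 0.0
    glut1K: float = 5.0
    kAmNaK2Cl: float = 0.0
    kSmNaK2Cl: float = 0.0

    def __post_init__(self) -> None:
        if min(self.glut1Jmax, self.kAmNaK2Cl, self.kSmNaK2Cl) < 0:
            raise ValueError("carrier rate constants must be >= 0")
        if self.glut1K <= 0:
            raise ValueError("GLUT1 half-saturation must be > 0")


@dataclass(frozen=True)
class GeometryCompliance:
    """Geometry and compliance closure.

    muAm, muLm, muSm : membrane compliance factors, Pa⁻¹ (only their ratios
                       enter the cell-pressure average; muLm also scales the
                       lis volume response)
    volLisRef        : lis volume at pressure equality, m³·m⁻²
    Dc               : cells per unit apical area, m⁻²
    MA               : impermeant (nondiffusible) anion content per cell, mol
    zA               : mean valence of the impermeant anions (< 0)
    """

    muAm: float = 1e-3
    muLm: float = 1e-3
    muSm: float = 1e-3
    volLisRef: float = 3e-7
    Dc: float = 1e10
    MA: float = 1e-13
    zA: float = -1.0

    def __post_init__(self) -> None:
        if min(self.muAm, self.muLm, self.muSm) < 0 or (
            self.muAm + self.muLm + self.muSm
        ) <= 0:
            raise ValueError("compliance weights must be >= 0 with positive sum")
        if self.volLisRef <= 0 or self.Dc <= 0 or self.MA < 0:
            raise ValueError("volLisRef, Dc must be > 0 and MA >= 0")
        if self.zA >= 0:
            raise ValueError("mean impermeant valence zA must be negative")

    @property
    def impermeant_content(self) -> float:
        """Total impermeant anion per unit apical area, mol·m⁻² (Dc·MA)."""
        return self.Dc * self.MA


@dataclass(frozen=True)
class ModelParameters:
    """One complete epithelium instance."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    baths: BathComposition = field(default_factory=BathComposition)
    membranes: MembranePermeabilities = field(default_factory=MembranePermeabilities)
    pump: PumpParameters = field(default_factory=PumpParameters)
    sglt1: Sglt1Parameters = field(default_factory=Sglt1Parameters)
    carriers: CarrierParameters = field(default_factory=CarrierParameters)
    geometry: GeometryCompliance = field(default_factory=GeometryCompliance)


# ---------------------------------------------------------------------------
# state


@dataclass
class EpithelialState:
    """The unknowns of the model.

    Concentrations in mol·m⁻³, potentials in V (serosal reference),
    pressures in Pa (absolute), volumes in m³ per m² apical membrane.
    ``psiO`` is the luminal potential, i.e. the transepithelial potential
    V_trans at open circuit.
    """

    cNaC: float
    cKC: float
    cClC: float
    cGlucC: float
    cAC: float
    cNaL: float
    cKL: float
    cClL: float
    cGlucL: float
    psiC: float
    psiL: float
    psiO: float
    pC: float
    pL: float
    volC: float
    volL: float

    def validate(self, zA: float | None = None, tol: float = 1e-6) -> None:
        """Check physical admissibility and, if ``zA`` is given, the two
        electroneutrality identities."""
        for name in (
            "cNaC", "cKC", "cClC", "cGlucC", "cAC",
            "cNaL", "cKL", "cClL", "cGlucL", "volC", "volL",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"state field {name} must be >= 0")
        if zA is not None:
            cell = self.cNaC + self.cKC - self.cClC + zA * self.cAC
            if abs(cell) > tol * max(1.0, self.cNaC + self.cKC):
                raise ValueError(f"cell electroneutrality violated ({cell:g})")
            lis = self.cClL - self.cNaL - self.cKL
            if abs(lis) > tol * max(1.0, self.cClL):
                raise ValueError(f"lis electroneutrality violated ({lis:g})")

    @property
    def osmolarity_cell(self) -> float:
        """Glucose counts as a full osmolyte, as do the impermeant anions."""
        return self.cNaC + self.cKC + self.cClC + self.cGlucC + self.cAC

    @property
    def osmolarity_lis(self) -> float:
        """The lis contains no impermeant species."""
        return self.cNaL + self.cKL + self.cClL + self.cGlucL

    def lis(self, species: str) -> float:
        return getattr(self, f"c{species.capitalize()}L")

    def cell(self, species: str) -> float:
        return getattr(self, f"c{species.capitalize()}C")

    def copy(self) -> "EpithelialState":
        return replace(self)


def membrane_potential(
    state: EpithelialState, baths: BathComposition, membrane: str
) -> float:
    """Potential difference ψ_I − ψ_II across a membrane, with (I, II) the
    positive-flux direction: (lumen, cell) for am, (cell, lis) for lm,
    (cell, serosa) for sm, (lumen, lis) for tj, (lis, serosa) for ibm.
    """
    if membrane == "am":
        return state.psiO - state.psiC
    if membrane == "lm":
        return state.psiC - state.psiL
    if membrane == "sm":
        return state.psiC - baths.psiS
    if membrane == "tj":
        return state.psiO - state.psiL
    if membrane == "ibm":
        return state.psiL - baths.psiS
    raise ValueError(f"unknown membrane id {membrane!r}; expected one of {MEMBRANES}")


def _finite(x: float, name: str) -> float:
    if not math.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x
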