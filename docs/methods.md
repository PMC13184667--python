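# Model and methods

## Scope and compartments

`proxtubule` models the S3 (proximal straight) segment of the kidney
proximal tubule as a minimal epithelium: one lumped cell compartment (the
"functional syncytium") and the lateral intercellular space (lis), bounded
by five membranes — apical (am), lateral (lm), serosal (sm), tight junction
(tj) and interspace basement membrane (ibm) — between two well-stirred,
constant baths. Mobile species are Na⁺, K⁺, Cl⁻ and glucose; the tubular
fluid reaching S3 is bicarbonate-poor and chloride-rich, so proton and
bicarbonate transport (NHE3) are deliberately outside the model's ion set.
All extensive quantities are per unit apical membrane area. Internal units
are MKSA (mol·m⁻³ ≡ mM for concentrations, V, Pa, m³·m⁻²); presentation
layers convert to mM, mV, atm, nL·cm⁻², pmol·cm⁻²·s⁻¹ and µA·cm⁻²
(1 pmol·cm⁻²·s⁻¹ = 10⁻⁸ mol·m⁻²·s⁻¹ and 1 nL·cm⁻²·s⁻¹ = 10⁻⁸ m·s⁻¹, so the
customary numbers carry one shared factor).

## Transport laws

All passive electrodiffusion reduces to one constant-field kernel
`g(w, a, b) = w·(a·eʷ − b)/(eʷ − 1)`:

* **Channels** (GHK): `J = P·g(u, C_I, C_II)`, `u = zFV/RT`, `V = ψ_I − ψ_II`
  oriented along the transport direction (lumen→cell, cell→lis,
  cell→serosa, lumen→lis, lis→serosa). Zero flux falls exactly on the
  Nernst potential. The chord conductance satisfies
  `zF·J = G·(V − E_Nernst)` with `G ≥ 0`, evaluated in the numerically
  stable form `G = (zF)²/RT·P·[u/(eʷ−1)]·C_II·expm1(u−u_E)/(u−u_E)`.
* **Solvent drag** (leaky barriers): the Péclet number `Pe = J_V(1−σ)/P`
  adds to the field term in one exponent, `J = P·g(u+Pe, C_I, C_II)`. This
  single form reduces exactly to the GHK flux as `J_V → 0` (or σ → 1) and
  to pure convection–diffusion as `V → 0`; those limits are the binding
  contract and are enforced by property tests. Junctional Na⁺ and K⁺ use it
  (Claudin-2); junctional Cl⁻ crosses the water-impermeable anion pore by
  plain electrodiffusion; glucose crosses both junctions convectively.
* **Na⁺/K⁺ pump** (lateral membrane): saturable in cytosolic Na⁺
  (K_Na = 3.4 mM) and lis K⁺ (K_K = 0.75 mM), linear in the electric
  driving force `V_lm + E_pump`, with `J_K = −⅔·J_Na` and current
  `I = F·J_Na/3` (one net charge per 3Na:2K cycle). The electromotive force
  is tied to energy metabolism by `E_pump = −ΔG_ATP/(3F)`; −58 kJ·mol⁻¹
  gives 200 mV. The pump reverses at `V_lm = −E_pump`.
* **SGLT1** (apical): 2 Na⁺ + 1 glucose cross as one divalent composite
  through a constant-field membrane, with composite activities
  `X = C_gluc·C_Na²` referenced to 1 mol·m⁻³ and a self-inhibiting
  permeability `P = P_max·K_m/(C_gluc^lumen + K_m)`, `K_m = 1.0 mM`. n_W
  water molecules accompany each glucose (`J_W = n_W·J_gluc·V̄_w`; human
  SGLT1 ≈ 264, the packaged default). The SGLT1 functions take the apical
  potential on the electrophysiological convention `V_am = ψ_cell − ψ_lumen`
  (the convention under which the carrier's reversal potential
  `(RT/2F)·ln(X_lumen/X_cell)` and its near-linear current–voltage relation
  between −100 and −40 mV are quoted); the flux assembly negates the
  package's lumen-minus-cell membrane potential accordingly. The
  reconstructed saturation curve reproduces hyperbolic uptake kinetics with
  an effective half-saturation near 1 mM; the test suite bounds its
  deviation from the 530·c/(0.6+c) pmol·cm⁻²·s⁻¹ hyperbola at 14% of the
  saturating flux over 0–6 mM.
* **GLUT1** (lateral): Stein's symmetric saturating carrier,
  `J = J_max·K·(C_c − C_lis)/[(K+C_c)(K+C_lis)]`.
* **1Na:1K:2Cl cotransporters**: mass-action electroneutral flux
  `J = r·k·(C_Na·C_K·C_Cl²|_I − C_Na·C_K·C_Cl²|_II)`, r = 2 for Cl⁻. One
  sits apically (K⁺/Cl⁻ uptake); a second, serosal copy is the regulated
  ion-recirculation pathway and is off (k = 0) in the reference state.
* **Water**: `J_V = L_p·[RT·Σσ_i·ΔC_i + Δp]` with σ ≡ 1 across cell
  membranes (AQP1-type), per-species σ across the junctions
  (σ_Na^tj = σ_K^tj = 0.7, σ_Cl^tj = 0.45, σ_gluc^tj = 0.8, σ^ibm = 0.03).
  The osmotic permeability conversion is `P_f = RT·L_p/V̄_w`.

Removable singularities (u → 0, Pe → 0, chord at the reversal potential)
switch to three-term Taylor series below an exponent magnitude of 1e-6; the
kernel is evaluated with negative exponentials only, so it cannot overflow.

## Closure and unknowns

Sixteen unknowns: cell and lis concentrations (Na, K, Cl, glucose), the
cell impermeant-anion concentration, three potentials (cell, lis, lumen —
the serosal bath is the ψ ≡ 0 reference, so the luminal potential is
V_trans), two pressures, two volumes. Sixteen residuals: eight solute and
two water conservation laws, cell electroneutrality
(`C_Na + C_K − C_Cl + z_A·C_A = 0`, z_A = −0.95 so that the impermeant pool
simultaneously balances charge and osmolarity at the documented cell
composition), lis electroneutrality (`C_Cl = C_Na + C_K`; the lis holds no
impermeant species, and glucose counts as a full osmolyte everywhere), the
open-circuit condition (zero net current through the apical barriers), the
compliance pressure average `p_c = Σμ·p/Σμ`, the compliant lis volume
`Vol = Vol_ref·(1 + μ_lm·(p_lis − p_c))`, and the cell-volume law
`Vol_c·C_A = D_c·M_A` (fixed impermeant content — Vol_c is the osmotic
dilution of the impermeant pool, treated as an algebraic closure rather
than a separate water ODE; the cell water-balance residual then determines
the membrane water flows consistently, which the tests verify).

At steady state the electrogenic balance is implicit: when every species
balance closes, the cell- and lis-node currents vanish automatically, and
the open-circuit row independently pins V_trans.

## Numerics

* **Steady state**: damped Newton–Raphson on scaled unknowns
  (concentrations /100, potentials /25 mV, pressure excess over the serosal
  bath /100 Pa, volumes by their reference magnitudes). The Jacobian is
  one-sided finite differences (relative step 1e-7, validated against a
  Richardson-extrapolated central-difference oracle to 1e-4). The linear
  step is an SVD-truncated least-squares solve (rcond 1e-10) — identical to
  the Newton step on a well-conditioned Jacobian, well-defined in the
  degenerate impermeant-free limit where the cell volume decouples.
  Backtracking halves the step until the max-norm residual decreases;
  iterates project small negative-concentration overshoots onto zero and
  keep volumes strictly positive. Convergence at max |scaled residual|
  < 1e-11 (absolute flux imbalance ~1e-17 mol·m⁻²·s⁻¹, i.e. relative ledger
  closure ~1e-12 of the gross fluxes). Fallbacks, in order: a fresh default
  start, a continuation ramp of pump/SGLT1/cotransporter activity, and
  pseudo-transient relaxation (backward-Euler steps with a growing Δt).
* **Transients**: second-order three-point backward differences
  (`(3Xⁿ − 4Xⁿ⁻¹ + Xⁿ⁻²)/(2Δt)` for the ten conserved quantities — volumes
  and volume×concentration products) coupled with the six algebraic rows at
  every step; each run or time-step phase starts with one backward-Euler
  step. Measured convergence order on a smooth relaxation: ≈ 1.9–2.0. Fast
  forcings (the τ = 1 ms glucose step) are resolved by an initial refined
  phase (default Δt = 0.1 ms) before the main Δt = 10 ms phase; long tails
  may use coarser phases since the scheme is A-stable.
* **Equivalent circuit**: the five chord-conductance sums form a
  Wheatstone-type bridge (transcellular limb am+sm, paracellular limb
  tj+ibm, lateral membrane bridging cell and lis). Branch currents under an
  injected transepithelial current step come from a direct dense solve of
  the two loop laws, the two internal node laws and the collected current;
  the closed-form identities (I₃ = 0 at R₁R₅ = R₂R₄, V_trans = I₁R₁ + I₂R₂
  = I₄R₄ + I₅R₅) are test oracles, not the implementation. The circuit is a
  small-signal diagnostic about a solved state; the open-circuit V_trans
  itself is an unknown of the nonlinear system.
* **Root-finding in protocols**: bracketing scans plus Brent's method for
  the scalar tunings (isosmotic recirculation; default tolerance 0.1 mosM);
  a damped two-dimensional quasi-Newton on logarithms for the joint
  VRAC/recirculation solve; bounded least squares on log-scaled parameters
  (weighted relative deviations) for calibration.

## The reference epithelium

The published description of this model class does not include the full
numeric parameter listing, so the packaged fixture
(`proxtubule/data/reference.params`) is produced by the package's own
calibration: printed constants are fixed (bath composition, T = 310 K,
K_Na, K_K, K_m, the σ set, the stoichiometries, ΔG_ATP = −58 kJ·mol⁻¹,
n_W = 264), and the membrane permeabilities, hydraulic conductances, pump
and carrier rate constants, lateral compliance, reference lis volume and
impermeant content are fitted to the documented steady-state observables at
1 mM bilateral glucose (active Na⁺ flux 541 pmol·cm⁻²·s⁻¹, V_cell −78.5 mV,
cell glucose 1.88 mM, lis composition ≈ bath with 0.91 mM glucose, lis
volume 33 nL·cm⁻², lis pressure 1.00074 atm, fluid uptake
4.9 nL·cm⁻²·s⁻¹, apical glucose flux 250 pmol·cm⁻²·s⁻¹) and at 6 mM (cell
Cl⁻ 16.3 mM, cell volume 1022 nL·cm⁻², absorbate 344.9 mosM, compartment
osmolarities 307.1/308.7 mosM). Per-target residuals are recorded in
`proxtubule/data/reference_calibration.json`; all are below 0.5% except the
lis glucose at 1 mM (≈ +10%: with GLUT1 delivering glucose to the lis, the
lis must be glucose-enriched above the bath to export it across the ibm, so
a sub-bath lis glucose is not reachable under this wiring) and the lis
osmolarity excess (1.2 vs 2.7 mosM). The fitted values are effective
lumped-epithelium parameters, not single-channel measurements; the
interspace basement membrane in particular is close to a free boundary
(large solute permeabilities, σ = 0.03).

Two observables in the source material imply different operating points
(an active Na⁺ flux of 541 pmol·cm⁻²·s⁻¹ at 1 mM glucose versus 1432 at
6 mM): with the stated SGLT1 saturation (K_m = 1 mM) dominating apical Na⁺
entry, no single parameter set can produce both. The fixture is calibrated
to the 541-regime, and the 1432-regime results (absolute fluxes of the ATP
accounting table) are reproduced in trend only: the isosmotic surcharge
ΔATP is positive and decreases as n_W grows, but its magnitude
(≈ 34 pmol·cm⁻²·s⁻¹ at n_W = 264) is fixture-specific.

## What the experiments show

* **Energy sweep**: lowering |ΔG_ATP| from 58 to 29 kJ·mol⁻¹ weakens
  E_pump from 200 to 100 mV; cell Na⁺ rises and cell K⁺ falls strictly
  monotonically — the bioenergetic signature of excised-tubule ion
  compositions.
* **Glucose step** (1 → 5 mM bilateral, τ = 1 ms): the apical glucose flux
  and the SGLT1 charge influx jump immediately, depolarizing the cell by a
  few mV, which stimulates the voltage-dependent pump within milliseconds
  (the flux increment converts to an inward current of F·ΔJ/3); over the
  following minute the cell accumulates glucose, the lis swells and
  pressurizes, and the transepithelial water uptake roughly doubles.
* **Isosmotic tuning**: without recirculation the absorbate leaving across
  the ibm is hyperosmotic (344.9 vs 306 mosM — mostly a glucose surcharge,
  since the GLUT1-delivered glucose must exit the lis at a concentration
  well above the bath). Activating the serosal 1Na:1K:2Cl cotransporter
  recirculates serosal ions through the cell into the lis; the pump works
  harder, more near-isotonic fluid is drawn through the junctions and the
  cell, and the exit concentration falls monotonically until it is exactly
  isosmotic. The root-finder lands within 0.1 mosM. The cost: higher cell
  Cl⁻, a swollen cell, and extra ATP hydrolysis.
* **Water-pathway crosstalk**: sweeping n_W from 0 to 600 moves water
  between the SGLT1 and AQP1 routes nearly one-for-one (the slope ratio is
  ≈ 0.96) while the total transepithelial uptake changes by well under 1% —
  total water transport is set by the solute pumping, not by which apical
  pore carries it.
* **Pump–water linearity**: scaling the pump rate coefficient over
  0.25–1.5× moves the steady fluid uptake along a straight line in the
  active Na⁺ flux (R² > 0.9999), the classical signature of solute-coupled
  water transport.

## Known limitations

* The VRAC experiment (restoring the recirculation-swollen cell volume by
  opening the lateral Cl⁻ pathway while keeping the absorbate isosmotic) is
  implemented as a joint two-dimensional root-find, but in the packaged
  fixture's regime the two targets conflict: along the isosmotic manifold
  the cell volume is minimal at the recirculation-tuned point itself, so a
  full return to the baseline volume is out of reach and the protocol
  reports this instead of silently abandoning the isosmotic constraint. At
  fixed recirculation, opening the lateral Cl⁻ pathway does monotonically
  shrink the cell and lower its Cl⁻, which is the tested contract. The
  conflict traces back to the irreconcilable 541/1432 operating points
  above: the fixture's recirculation loop must swell the cell far more than
  the regime the VRAC observation was reported for.
* The model is zero-dimensional: no axial gradients along the tubule, no
  multi-cell heterogeneity, no capacitive electrical transients, no
  mechanosensitive compliance, and ideal osmotic coefficients throughout.
* Solute–water coupling in SGLT1 is instantaneous and of fixed
  stoichiometry; multi-state carrier kinetics are not modeled.
* The calibration is deliberately over-parameterized (more free
  permeabilities than independent observables), so the fixture is one
  member of a family that reproduces the targets; derived magnitudes not
  pinned by a target (e.g. the swollen-state cell Cl⁻, the ΔATP magnitude)
  vary across that family and should be read as qualitative.
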