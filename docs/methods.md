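# Methods

## Scope and structure

`saliduct` models the intercalated (ID) and striated (SD) sections of a
mouse salivary-gland duct as a branched epithelial tube that modifies a
flowing primary saliva.  The acinus is not modelled mechanistically: its
output — composition and volumetric flow — is the boundary condition.
Downstream of the SD the excretory ducts are assumed to transport saliva
unchanged, so the SD outlet fluid is the final saliva.

The state of the system is: per cell, the amounts (zmol) of Na⁺, K⁺, Cl⁻,
HCO₃⁻ and H⁺ plus the cell volume; per 1 µm lumen segment, the five
luminal concentrations.  Amounts rather than concentrations are the cell
state variables so that conservation under volume change is exact.
Membrane potentials are not states: membrane capacitance charges orders of
magnitude faster than any other process, so at every right-hand-side
evaluation a damped Newton solve finds, per cell, the cell and local lumen
potentials at which (i) no net current leaves the cell and (ii) the
transcellular current returns through the tight junction.  The solve is
warm-started and iterated to round-off so the ODE right-hand side stays
smooth; a degenerate cell (no electrogenic pathway at all) is reported as
an error by the public API and treated as 0 mV by the simulator only for
fully inert test configurations.

## Geometry

The synthetic generator reproduces the measured duct anatomy: `n_acini`
ID branches (radius 0.8 µm, length 45 µm) merge at one junction into a
single SD (radius 4 µm, length 80 µm), giving a ≈130 µm path from the
farthest acinus to the outlet.  Cells tile each branch in ≈5 µm rings —
36 ID cells (resting volume ≈400 µm³, basolateral area 200 µm²) and 16 SD
cells (≈700 µm³, 500 µm²) for the 4-acinus reference duct.  Each cell's
apical membrane is split into strips, one per facing lumen segment; strip
areas partition the apical area exactly.  Per-cell volumes and basolateral
areas are drawn lognormally with a 5 % coefficient of variation
(deterministic per seed).  Real surface meshes can be ingested through
`classify_apical_triangles`, which labels a triangle apical when its
centroid lies within `radius_factor` (default 1.2) local radii of the
centreline; any factor in [1.1, 1.5] labels a smooth tube identically, and
values above 1.0 tolerate mesh smoothing.

Terminal partial segments keep their true length and scale fluxes and
volumes accordingly.  Junction segments list every parent branch and sum
their advected fluxes and flows, which is forced by mass conservation.

## Luminal transport

Axial diffusion is neglected (convection dominates at these flow rates)
and the luminal water column is quasi-steady: transit time through the
whole duct is ~10 s versus hours for the cellular relaxation, so the flow
out of a segment is the sum of upstream inflows plus all water secreted up
to that segment.  The advection operator is first-order upwind over the
segment tree; it telescopes to an exact discrete mass ledger (asserted
against a finite-volume oracle in the tests).  Positive membrane flux is
*into* the lumen throughout the code, so the balance reads
d(moles)/dt = in − out + J·A_L·Δx, and the physical directions (ENaC
removes luminal Na⁺, Maxi-K adds K⁺) fix all signs unambiguously.
Hydrostatic pressure is neglected.

## Membrane mechanisms

* **Channels** (ENaC, CFTR, CaCC, Maxi-K, basolateral K⁺): GHK flux with
  RT/F = 26.7 mV (310 K).  The anion channels pass HCO₃⁻ at 0.3× their
  Cl⁻ permeability.  ENaC open probability is additionally scaled by
  km/(km+[Na⁺]_L) with km = 5 mM (luminal self-inhibition), which makes
  Na⁺ absorption quasi-zeroth-order over most of the duct and is what lets
  a short duct absorb a ten-fold Na⁺ range without proximal overload.
* **NaK-ATPase**: 3 Na⁺ out : 2 K⁺ in, rate ∝ (Na_C/(Na_C+40))³ ·
  (K_o/(K_o+1.5))².  The 40 mM half-saturation keeps the pump in its
  steeply Na-sensitive regime, which narrows the axial spread of [Na⁺]_C.
* **NHE, AE**: electroneutral 1:1 antiporters with symmetric saturating
  rate laws that vanish exactly at the product-rule equilibrium.
* **NBC**: electrogenic Na⁺–nHCO₃⁻ cotransport with a symmetric Eyring
  potential factor; n = 2 apically (uptake-favouring) and n = 3
  basolaterally.  The basolateral 1:3 form (the renal NBCe1
  stoichiometry) runs outward at physiological potentials and gives the
  cell a self-limiting bicarbonate exit — without it, apically imported
  HCO₃⁻ can only leave in exchange for Cl⁻ and the most proximal SD cell
  accumulates Cl⁻ and swells without bound.
* **Water**: osmotic, J = Lp·A·Δosmolarity.  Only ID cells have apical
  aquaporin; all cells have basolateral water permeability.  Each cell
  carries a fixed impermeant osmolyte amount (concentration × resting
  volume, 92 mM for SD and 112 mM for ID at rest), chosen so steady-state
  volumes match the observed cell sizes.
* **Tight junction**: GHK fluxes for Na⁺, K⁺ and Cl⁻ only, driven by the
  transepithelial potential; HCO₃⁻ and H⁺ are blocked.
* **Buffering**: CO₂ + H₂O ⇌ H⁺ + HCO₃⁻ with mass-action rate
  k·(CO₂ − [H][HCO₃]/Ka), Ka = 10^−3.1 mM (pK′ 6.1).  Luminal
  k = 0.1056 s⁻¹; intracellular (carbonic-anhydrase-assisted) rates of
  0.45 s⁻¹ (SD) and 2.5 s⁻¹ (ID).  Dissolved CO₂ is fixed per
  compartment: 1.2 mM in cells and interstitium (pCO₂ ≈ 40 mmHg) and
  0.10 mM in the lumen.  The low luminal CO₂ encodes the observation that
  final saliva is alkaline at modest bicarbonate; with plasma-level
  luminal CO₂ the buffer would pin the final pH near 7.2.

The interstitium is a fixed plasma-like bath (Na⁺ 140, K⁺ 5, Cl⁻ 110,
HCO₃⁻ 25 mM, pH 7.4, plus 13.7 mM non-ionic osmolytes).  A global
`time_scale` multiplies every transport coefficient and the buffer rates;
scaling it by s while scaling time by 1/s leaves cellular steady states
unchanged and compresses the axial profile, the standard trade for fitting
a truncated duct.

## Parameter provenance and calibration

The transporter density/permeability coefficients are not measured
quantities; they were calibrated by hand, on the full 4-acinus model, to
reproduce the measured resting behaviour of the mouse parotid duct:
final saliva Na⁺ 12, K⁺ 57, Cl⁻ 54, HCO₃⁻ 14 mM at 419 µm³/s outlet flow
for 417 µm³/s inflow, ID water secretion ≈2 µm³/s, transepithelial
potentials ≈5 mV (ID) and ≈50 mV (distal SD), and cellular states inside
physiological windows.  The calibrated defaults live in
`saliduct.transporters.default_params` and serialise to YAML.

Known residuals of the calibration, with uniform per-type coefficients
and the generic kinetic forms above:

* [K⁺]_C sits near 117 mM in ID cells and 109–135 mM across SD cells,
  below the 131–146 mM window of reported duct-cell values at the duct
  ends; the basolateral potential would need ~3 mV more hyperpolarisation
  than the charge balance allows with these mechanism densities.
* [Na⁺]_C spans 15–28 mM across SD cells (reported range 20–25); a cubic
  saturating pump cannot compress a multi-fold axial variation in ENaC
  load into a 1.25× concentration band.

## Drivers and reported outputs

`run_to_steady_state` integrates the stiff system (BDF, absolute
tolerance 10⁻¹⁰ scaled per state, relative 10⁻⁹, hand-built Jacobian
sparsity) to 20 000 s of model time, extending in 10 000 s chunks until
the relative state change falls below 10⁻⁸/s.  `run_stimulation` starts
from that steady state and ramps the inflow with the sigmoid protocol
(half-rise 50 s after onset, plateau m×basal, switch-off at 400 s); the
state at t = 400 s is the conventional "stimulated" reporting point — the
system is deliberately *not* at equilibrium there, matching how stimulated
saliva is collected over minutes.  `flow_sweep` repeats this per flow
multiplier.  Primary-saliva composition is held constant under
stimulation (the high-flow assumption); an optional mode instead raises
osmolarity linearly to 330 mM at m = 4.

`build_simplified` collapses the duct to one ID and one SD compartment
with summed membrane areas, volumes and lumen volumes and the same
per-area parameters.  The simplified model preserves the flow-sweep
trends and the water/flow budget, but its well-mixed SD lumen
overestimates final Na⁺ (≈36 vs ≈13 mM) and Cl⁻ (≈64 vs ≈53 mM): a
single stirred compartment satisfies A·J(C_out) = V·(C_in − C_out),
which can only coincide with the plug-flow outlet when the axial profile
has reached its zero-net-flux plateau by the outlet, and placing every
species' passive plateau at the measured final composition is not
possible here without pushing the cellular states out of their
physiological windows (the apical Nernst cut-offs for Na⁺ and K⁺ scale by
the same e^{V_A/RT·F} factor, so their plateau ratio is pinned to
[Na⁺]_C:[K⁺]_C).  Treat the two-compartment model as a fast qualitative
surrogate, not a quantitative replacement.

## Synthetic data and what the tests show

All test inputs are generated in code: tiny ducts (one to four cells),
an inert duct (every density zero — the outlet must reproduce the inlet
exactly), a two-branch junction (flow conservation), and randomized
membrane states for the property tests.  The generator reproduces duct
*statistics* (radii, lengths, mean cell sizes with 5 % lognormal
variation) but not real anatomy: no curvature, no irregular lumen cross
sections, no cell-to-cell contact geometry.  Passing tests therefore
demonstrate internal consistency (conservation, thermodynamic signs,
solver correctness) and agreement with the published summary numbers,
not anatomical fidelity.

## Numerical choices

Concentrations are floored at 10⁻¹² mM inside rate evaluations; the
potential Newton accepts either 10⁻¹³ relative residual (against the
largest current seen, so zero-current solutions are well-posed) or a
round-off stall below 10⁻⁹.  The initial condition for cold steady-state
solves is a generic polarised cell (Na⁺ 25, K⁺ 120, Cl⁻ 40, HCO₃⁻ 12 mM,
pH 7.3) with the lumen at the primary-saliva composition: starting the
cells at the interstitial composition instead places K⁺ at its channel
equilibrium and can trap the system in a depolarised, pump-defeated fixed
point.  Halving Δx from 1 µm to 0.5 µm changes the final saliva by ≈1.5 %
(Na⁺), the first-order upwind truncation error on the steep profile near
the ID/SD junction.

## Limitations

Only pilocarpine-type (parasympathetic) stimulation is represented, as a
flow change with fixed composition; duct cells do not sense the stimulus
directly.  There is no intracellular Ca²⁺ — CaCC is modelled at a fixed
basal open state.  Transport coefficients are uniform within each cell
type, so luminal profiles are monotone; glands whose final [Cl⁻] is
non-monotonic in flow would need axially varying coefficients.  Backflow,
axial diffusion, hydrostatic pressure and granular-duct biology are out
of scope.
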