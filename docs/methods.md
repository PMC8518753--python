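# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `phipflow`, in the order the pipeline runs.

## Kinetic network

The hydrogenation is reduced to six irreversible mass-action reactions
over ten species (precursor catalyst `1`, active catalyst `1a`, hydrogen
`2`, propargyl acetate `3`, bound complex `3a`, hyperpolarised allyl
acetate `4`, bound complex `4a`, relaxed allyl acetate `4rx`, propyl
acetate `5`, cyclooctene `6`).  The catalyst induction period — in
reality a multi-step COD hydrogenation/elimination — is collapsed into a
single bimolecular activation step, and each catalytic hydrogenation
(oxidative addition + migratory insertion + elimination) into one
bimolecular step; no reverse reactions are modelled.  Two linear
invariants follow from the stoichiometry and are enforced in tests:
total catalyst `[1]+[1a]+[3a]+[4a]` and total organic backbone
`[3]+[3a]+[4]+[4a]+[4rx]+[5]` are constants of motion.

The relaxation sink `4 → 4rx` with k₆ = 1/T₁ models loss of
hyperpolarisation as a chemical conversion; `4rx` is never consumed, a
deliberate simplification — relaxed product could in principle re-enter
the cycle via `1a + 4rx`, which would slightly deplete the active
catalyst.  Only *concentrations* of hyperpolarised versus relaxed product
are tracked; no spin dynamics, polarisation levels or signal enhancements
are computed.  k₆ is active only in the chip model: the tube calibration
used thermal hydrogen, where no distinct hyperpolarised pool exists, so
k₆ = 0 there.

Units: concentrations in mM, which equals mol m⁻³ exactly, so the tube
rate constants (mM⁻¹ s⁻¹) transfer to the SI chip solver without
conversion.

**Integration.**  Adaptive LSODA with analytic Jacobian, rtol 10⁻⁸,
atol 10⁻¹⁰ mM (the system is stiff once `[1a]` builds up: the
coordination step is ~300× faster than activation).  Negative excursions
below 10⁻⁹ mM are clipped to zero; larger ones would indicate integrator
failure and are not silently repaired.

## Calibration

Observables are the four NMR integral regions: free propargyl acetate
`[3]`, allyl acetate `[4]`, propyl acetate `[5]` and precursor catalyst
`[1]`.  Bound complexes are *not* added to the observables — the integral
regions are chemical-shift-specific to the free species — an approximation
documented here because the catalyst COD region in reality tracks bound
COD as well.

Dissolved hydrogen is clamped at 20 mM during fitting (solubility
4 mM/bar × 5 bar); the intermittent bubble/settle cycle of the real
experiment (10 s bubbling / 25 s settling) is idealised away, consistent
with how the constants are used downstream.

The fit minimises Σ((model−obs)/σ)² with scipy's bounded
trust-region-reflective least squares, bounds [0, 10] mM⁻¹ s⁻¹, default
guess 0.01 for every constant.  Two numerical details matter:

- the finite-difference step for the fit Jacobian is 10⁻⁴ (relative),
  well above the ODE solver's 10⁻⁸ noise floor — the default √ε step
  probes integrator noise and destroys the weakly identified directions;
- confidence intervals are linearised Wald intervals,
  estimate ± z·SE at 95%, with the covariance (JᵀJ)⁻¹ scaled by the
  reduced chi-square.  Profile-likelihood intervals are not implemented.

**Identifiability caveat.**  At the experimental design (19 points, 40 s
cadence) the coordination constant k₂ is *sloppy*: the weighted χ²
changes by less than 0.02 across ±20% of k₂ on noise-free data.  With
0.5 mM noise its estimator wanders over an order of magnitude between
replicates, and when it lands in locally steep territory the Wald
interval is confidently narrow yet wrong.  In a 100-replicate simulation
the nominal 95% intervals cover the truth 95/91/85 times for k₃/k₅/k₄
but only 82/72 times for k₁/k₂.  This is an intrinsic property of Wald
intervals under this design, not an optimiser defect (multistart finds
the same minima); it is the main reason reported k₂ uncertainties should
be treated with caution.

## Synthetic tube data

The generator integrates the clamped-hydrogen network at chosen "true"
constants on the acquisition schedule (19 spectra, t = 0…720 s every
40 s; initial 20 mM propargyl acetate, 5 mM catalyst), maps the
trajectory to the four observables, adds independent Gaussian noise and
truncates negatives at zero.  Default σ = 0.5 mM for every observable:
the real error bars derive from SNR variation and are small but
unquantified; 0.5 mM visually matches their scatter and is documented as
arbitrary.  What the generator does *not* emulate: the bubble/settle
hydrogen transient, catalyst degradation (observed after ~460 s in
reality, unmodelled), baseline/phasing artefacts, and any correlation
between observables.  Passing recovery tests therefore demonstrates the
estimator works under the idealised conditions, not that the original
experiment is free of systematic error.

## Chip transport model

**Domain.**  The 2D mid-plane of the device: channel 55 × 0.1 mm,
membrane slab 25 × 0.4 mm on one wall, chamber widening to 0.5 mm over
2 mm, out-of-plane depth 1.4 mm (used to convert fluxes and volumes).
The real chip's serpentine plan view and gas channel are not modelled.
Axial positions are not published; the defaults — inlet development
2 mm, membrane 2–27 mm, chamber 48–50 mm, outlet 55 mm — were chosen so
the liquid volume (8.8 µL) and pre-chamber residence are close to the
reported ~8.5 µL device, and are config-overridable.  The "upstream"
scenario moves the chamber to 35.5–37.5 mm, all else fixed.

**Flow.**  Re ≪ 1 in a straight duct, so instead of a numerical
Navier–Stokes solve the velocity is prescribed: plane Poiseuille across
the local liquid width, rescaled per segment so every cross-section
carries the inlet flow rate, with transverse face velocities
reconstructed from discrete continuity (the face field is exactly
divergence-free on the mesh).  The chamber transition therefore
redistributes flow instantly over the widened cross-section; a Stokes
solution would do so over an entrance length comparable to the width,
which is short relative to the 2 mm chamber.

**Membrane.**  Hydrogen alone exists in the membrane subdomain, with
diffusion only (no velocity), D = 10⁻⁹ m² s⁻¹ (a single diffusivity is
used everywhere; the membrane's true internal diffusivity is not
published).  A Dirichlet value h_pdms (default 20 mM) holds on the outer
boundary and concentration is continuous across the membrane/liquid
interface.  The through-thickness resistance (0.4 mm at 10⁻⁹ m² s⁻¹) is
the dominant mass-transfer resistance; a series-resistance estimate
D/(b + w/3) reproduces the solver's ~4.3 mM uptake at 20 µL/min, which
is the physical regime the model needs to capture.  Other species see
the interface as an impermeable wall.  No hydrogen is lost through the
chip plastic.

**Discretisation.**  Structured rectilinear finite volumes: 8 cells
across the 0.1 mm channel (12.5 µm), 8 across the membrane/chamber strip
(50 µm), and 100 µm axial spacing (~6 600 active cells).  Axial cell
Péclet numbers are O(100), so convection is first-order upwinded;
central differencing is available for diagnostics and warns when cell
Péclet exceeds 2.  Halving all spacings changes the chamber-mean
read-outs by <0.5%, which is why the 100 µm default (rather than 50 µm)
is used; the grid-convergence check is part of the test suite.

**Steady solver.**  The coupled steady system for the species that
appear as reactants (7 of 10 under full kinetics) is solved by damped
Newton iteration on the assembled sparse system (block transport
operators minus the analytic reaction Jacobian), with iterates projected
onto non-negative concentrations — large negative excursions make the
mass-action Jacobian near-singular.  If Newton stagnates, the solver
falls back to pseudo-transient continuation with
switching-evolution-relaxation time-step control.  Product-only species
(`4rx`, `5`, `6`) decouple and are recovered by single linear solves.
Convergence: residual 2-norm below 10⁻⁸ of the boundary-flux scale.
Sweeps reuse each converged state as the next flow rate's initial guess.
A zero-flow configuration treats the inlet as closed (no-flux), so the
reactions-off limit relaxes to uniform h_pdms.

**Read-out.**  "Chamber concentration" is the volume-weighted mean over
the chamber cells; whether the original device read-out is a volume
average or a point probe is unknown, and the profile helper
(width-averaged concentration along the axis) exposes the alternative.

## Experiments

The uptake curve zeroes all kinetics and inlet concentrations; the
product sweep uses inlet 20 mM `3` + 5 mM `1`, membrane-fed hydrogen and
k₆ = 0.14 s⁻¹; default grid 2–20 µL/min in 0.5 steps.  The optimum flow
rate is refined by a quadratic fit through the three points around the
discrete maximum (the curve's peak is broad, so the refinement is
well-conditioned); peak *values* and scenario deltas are taken directly
from the grid maxima.  Scenario definitions: k₁ × 10 (0.015 mM⁻¹ s⁻¹);
h_pdms = 40 mM; chamber 12.5 mm upstream with h_pdms = 40 mM.

Under the default layout the model places the product optimum at
4.8 µL/min with doubled-hydrogen peak ≈ 1.37 mM (≈ 2.3 × baseline) and
an upstream-shift gain ≈ 0.48 mM.  The exact peak ratio is sensitive to
the unpublished axial layout: with more hydrogen the catalyst also
activates faster upstream of the chamber, making the doubling slightly
super-linear here.

## Known limitations

- The 2D mid-plane with fixed depth ignores the third dimension and any
  membrane deformation under pressure (a proposed explanation for the
  measured uptake collapse above 10 µL/min that the model does not
  reproduce).
- Catalyst degradation/oxidation at long times is unmodelled.
- The relaxation constant is a literature T₁ for comparable molecules,
  not a measured one, and is field- and position-independent.
- k₂ is weakly identified at the calibration design (above).
- The synthetic-noise level σ = 0.5 mM is a simulation knob, not a
  measured uncertainty.
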