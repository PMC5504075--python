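# Methods

## The slab model

The interface is a one-dimensional SLD profile perpendicular to the
silicon surface, described as homogeneous slabs between two semi-infinite
media (Si fronting, aqueous backing).  The z axis has its origin at the
Si/oxide interface and increases towards the solvent.  Each slab carries

* thickness (Å),
* SLD (Å⁻²), always the volume-fraction weighted mean of its components,
* the r.m.s. roughness of its substrate-side interface (Å),
* a component bookkeeping (lipid head / lipid tail / water / protein /
  solvent) whose fractions must sum to 1 to within 1e-9.

**Substrate.**  The oxide slab mixes SiO₂ with solvent according to an
"oxide coverage" fraction; a hydration layer of pure solvent separates
oxide and bilayer.  Coverage is implemented as in-slab solvent volume
mixing rather than incoherent patch averaging, which keeps the forward
model single-valued and matches the custom-model family standard for
supported-bilayer reflectometry.

**Bilayer.**  Four slabs (inner heads, inner tails, outer tails, outer
heads) are derived from five physical parameters: APM, waters per
headgroup, waters per tail, and global plus local roughnesses.  Head-bound
water is housed in the head slabs and tail-associated water (hydration
defects) in the tail slabs.  Slab-bound water exchanges freely with the
bulk and therefore scatters with the solvent SLD.  The 1:1 lipid mixture
is treated as a single averaged species (mole-fraction averaged head/tail
scattering lengths and volumes) because a single APM is fitted per
bilayer.  Default moiety volumes: PC head 320 Å³, PG head 289 Å³,
di-C14 tails 720 Å³, water 29.9 Å³ — literature fluid-phase values,
configurable in the materials registry.  Tail-perdeuterated (d54) lipids
replace the 54 tail hydrogens with deuterium at unchanged volume.

**Roughness combination.**  The global roughness applies to every bilayer
interface; the local inner and outer roughnesses add in quadrature at the
inner head/hydration and outer head/solvent (or head/protein-layer)
interfaces respectively.  The combination rule is a package choice — the
parameter names imply separate global and local scales but no explicit
rule, and quadrature addition is the natural composition of independent
Gaussian widths.

**Insertion models.**  M1 appends a protein surface layer with solvent
fraction 1 − coverage.  M2 additionally converts a fraction of the
outer-head slab's water volume into protein.  M3 converts a fraction of
the outer-leaflet lipid volume (heads and tails alike) into protein; M4
applies the same substitution to both leaflets with an independent inner
fraction.  Thicknesses are unchanged by insertion (protein fills the
displaced volume), so volume bookkeeping is conserved slab by slab.
Setting every insertion fraction to zero reduces M2–M4 exactly to M1 —
this degeneracy is why model comparison needs a parsimony rule (below).

## Scattering length densities

SLDs are computed from a small internal table of bound coherent scattering
lengths (H, D, C, N, O, P, Si, Na) and molecular volumes; package
constants reproduce the standard values H₂O −0.56, D₂O 6.36, Si 2.07,
SiO₂ 3.47 (×1e-6 Å⁻²).  Solvent mixtures interpolate linearly in D₂O
volume fraction, and the inverse (contrast matching) is closed-form; the
silicon match point falls at 38% D₂O.  Labile hydrogens (lipid glycerol
OH, protein amides/side chains) exchange with the solvent deuterium pool;
the protein SLD is modelled as 1.8e-6 Å⁻² in H₂O rising to 3.1e-6 Å⁻² in
D₂O at full exchange, with a default exchange completeness of 0.9.  These
protein endpoints are registry-configurable because they are
sequence-dependent at the few-percent level.

## Reflectivity

The Abelès/Parratt recursion with Névot–Croce roughness damping computes
R(q); no absorption terms are included (imaginary SLDs are negligible for
these isotopes).  The Névot–Croce treatment is cross-validated against an
independent micro-slicing oracle (the erf-broadened profile discretised
into 0.1 Å sharp slabs): agreement is better than 1e-3 relative for
q ≤ 0.3 Å⁻¹ when roughnesses are small compared to slab thicknesses,
which is the regime in which the analytic factors are valid.  For
roughnesses comparable to slab thicknesses (as in the fitted
tail-deuterated datasets) the two treatments genuinely diverge at the
0.5% level; the package follows the analytic convention used by standard
reflectometry fitting software.

Instrumental resolution is applied point-wise as a Gaussian convolution in
q using a 17-node fixed quadrature over ±3.5σ.  Synthetic data default to
a 150-point logarithmic q grid over 0.008–0.3 Å⁻¹ with a constant 5%
FWHM dq/q — a typical time-of-flight reflectometer configuration, chosen
because the instrument range and resolution are not part of the model.

## Co-refinement and uncertainties

All datasets passed to `corefine` share one parameter set (substrate,
bilayer, optional protein); only the solvent contrast differs.  Fits of
the before-protein and after-protein conditions are run separately, with
substrate values optionally pinned from the before fit — equivalent to
the joint fit with substrate held constant across all curves, but with a
smaller search space per run.  Optimisation is bounded, seeded
differential evolution (midpoint starting values; default bounds e.g. APM
40–80 Å², layer thickness 0–150 Å) followed by a trust-region
least-squares polish with tight (1e-12) tolerances so that noiseless
self-generated data are recovered to better than 1e-3 relative.
Non-convergence is flagged on the result, not raised.

The parametric bootstrap redraws every point from Normal(R_model, σ_R),
refits locally from the best values, and quotes the central 68% of the
refitted values per parameter; residual resampling is available as an
option.  Each dataset's noise stream is seeded from a content hash so the
intervals do not depend on dataset ordering.  Nested Monte-Carlo
calibration (50 outer replicates) puts the empirical coverage of the 68%
interval at ~70%.

**Model selection.**  All four insertion models are fitted from identical
midpoint starting conditions and ranked by total χ².  Because M2–M4
contain M1 as a boundary case, any model whose reduced χ² lies within
0.05 of the best is treated as statistically tied and the tie resolves to
the fewest free parameters (then to the simpler model identity).  On
synthetic M3 data at 3% noise this selects M3 essentially always, with M4
collapsing onto M3 and losing on parsimony.

**Time-resolved fitting.**  Single-contrast time slices are fitted with
the substrate frozen (from the protein-free fit) and bilayer/protein
parameters free per slice; the per-slice insertion model may follow a
sequence (surface adsorption → headgroup penetration → full insertion).
A slice is flagged as steady state when every floating parameter moved by
less than one bootstrap σ (half the central-68% interval) from the
previous slice — the qualitative "no further change" criterion made
quantitative; the 1σ threshold is a package choice.

## SPR analyses

The four-parameter logistic fit is unweighted by default (σ-weights
accepted); it is scale-equivariant in response and recovers noiseless
truth to 1e-6 relative.  The association window is 0–180 s from injection
by default.  A one-phase association fit is flagged as poor — not
rejected — when the exponential curvature is unresolved in the window
(k_obs·window < 0.2, the linear-ramp failure mode) or the residual
variance is large; the pipeline reports fit quality and asserts nothing
about the underlying binding mechanism, which for this system is known to
be more complex than 1:1.  k_obs regression offers the all-points set and
a ≥ 500 nM set, since low-concentration points violate pseudo-first-order
assumptions most strongly.

## Lamellar diffraction

The background is a power law plus constant fitted outside a masked
window around the candidate peak (running averages are used only for
display, never quantitation).  The apex of the background-subtracted,
Savitzky–Golay-smoothed curve is refined by quadratic interpolation; the
width is the FWHM from half-height crossings.  A curve whose maximum
excursion stays below 3× the background residual noise returns a no-peak
verdict (the protein-free control).  With multiple diffraction orders the
lowest-s qualifying maximum is returned as the first order; a minimum
height of 25% of the tallest excursion guards against structured
background residuals masquerading as low-s orders.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (scenario, seed).  Reflectivity noise is
multiplicative Gaussian, 3% fractional by default with a 1e-7 floor on
the quoted σ — chosen to make truth-scenario parameter recovery
discriminating but feasible; real counting statistics vary strongly with
q and instrument.  Not emulated: footprint/overillumination effects at
grazing angles (assumed corrected in reduced data), background terms,
imperfect bilayer coverage heterogeneity, or inter-point correlations
from rebinning.  SPR truth follows the dose-response model exactly with
additive Gaussian noise and pseudo-first-order kinetics (optionally biased
below 500 nM); real sensorgrams contain bulk-shift and mass-transport
artefacts the generator omits.  SAXD curves are a Gaussian peak (optional
weak second order) on a power-law background with intensity-scaled noise.
Passing recovery tests therefore demonstrates the correctness and
identifiability of the analysis chain under its own assumptions, not the
adequacy of those assumptions for any particular instrument.

## Problem sizes and determinism

The recovery studies use three contrasts × 150 points with the full
10–14-parameter search; the replicated model-selection study uses 40
points per contrast with substrate pinned and a reduced
differential-evolution budget, sizes at which each study completes in
minutes on one core while leaving the χ² gaps between models orders of
magnitude larger than the selection margin.  All stochastic steps
(generation, differential evolution, bootstrap) are seeded and
bit-reproducible; derived seeds stay below 2³¹.

## Known limitations

* No lateral in-plane structure, curvature, or per-leaflet asymmetric
  lipid compositions.
* Névot–Croce roughness is trusted outside its strict validity regime for
  large fitted roughnesses, as is conventional.
* The bootstrap refits are local (no global stage per resample), which
  can understate uncertainty if the χ² surface is multimodal within the
  noise scale.
* Protein SLD endpoints are generic hydrogenated-protein values, not
  sequence-computed.
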