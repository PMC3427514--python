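# Methods

## Model and assumptions

The model reduces adult subventricular neurogenesis to a linear
differentiation cascade (type-B stem cells → type-C transit-amplifying
cells → type-A migratory neuroblasts → mature neurons) on a planar
domain, justified by the predominantly planar geometry of the rostral
migratory stream and by imaging that quantifies two-dimensional axial
slices.  Domain growth is neglected (adult brain).  Key biological
simplifications, inherited deliberately:

* a **single** diffusible chemoattractant f_A steers neuroblast taxis;
  it is secreted by the OB environment (Gaussian source q centred on
  the bulb) and by the cells themselves (κ_A, κ_B, κ_C), taken up by
  neuroblasts (κ_D f_A n_A) and subject to first-order decay (λ);
* B and C cells are immotile and confined to the SVZ; their densities
  are identically zero elsewhere;
* all radial granule/periglomerular development is collapsed into a
  single OB-centre square of side b where neuroblasts either die at the
  boosted rate γ_A + ε or become neurons at rate ζ = µε; mature neurons
  then drift against a static Gaussian field g, a phenomenological
  stand-in for radial dispersal;
* endothelial (type-E) conversion of neuroblasts is folded into the
  type-A apoptosis rate;
* neurons do not secrete attractant (no κ_N in the parameter set);
* logistic growth uses carrying capacity 1 (densities are
  non-dimensional); all 27 parameters are non-dimensional with the time
  unit taken as days.

Two algebraic steady states anchor the analysis: the non-trivial root
n_B* = 1 − (α_C + γ_B)/β_B of the stem-cell equation, and the positive
root of β_C n² − (β_C − α_A − γ_C) n − α_C n_B* = 0.  Parameter sets are
*admissible* when both are positive and taxis dominates diffusion for
both motile species (η_A > δ_A, η_N > δ_N); inadmissible sets either
collapse to the trivial state or transport cells by random diffusion
rather than directed migration.

## Geometry

Three axis-aligned boxes: OB [0,2]², RMS channel [2,4]×[0.85,1.15], SVZ
[4,4.6]×[0.7,1.3] (model units; 1 unit ≈ 1.4 mm).  These dimensions
reproduce the anatomy's relative proportions (large OB, long thin RMS,
small SVZ) and are fully configurable.  The OB centre is (1,1) and the
centre square has side b = 0.5.  The grid is cell-centred with
half-open cell ownership; the default spacing h ≈ 0.0178 yields
≈ 15,600 active cells; the desk-scale fixture uses h = 0.1
(496 cells).  Both Gaussians (source q: amplitude a_1, width
a_2; dispersal g: amplitude a_4, width a_5) use the convention
a·exp(−|r−c|²/w²).  The magnitude of ε inside the centre square is the
parameter d, the only otherwise-unassigned constant in the reference
list.

## Discretization and integration

Method of lines.  Diffusion: standard five-point second-order stencil;
zero-flux boundaries by ghost-cell reflection, so the operator's row
sums vanish and transport conserves mass exactly (tested).  Taxis:
conservative face fluxes; face velocity from the central difference of
the potential; upwind-side face density reconstructed with the van Leer
limiter φ(r) = (r+|r|)/(1+|r|) (ratio r of the upwind to the local
slope, r = 0 at zero denominators), which guarantees positive solutions
— negativity in any species can seed spurious oscillations in this
strongly coupled system.  Boundary faces carry no flux.

Time integration uses an adaptive implicit BDF method with relative
tolerance 1e-6 (absolute 1e-9) — the contract is stiff stability and
per-step local error control, not a specific formula.  The Jacobian is
assembled by grouped forward differences on the exact sparsity pattern
(reaction blocks pointwise; transported fields couple to their 2-ring
axis neighbours because the limiter reaches two cells upwind; n_A
couples to the 1-ring of f_A through face velocities), with a greedy
column colouring (~30 groups instead of ~1,560 columns).  n_B/n_C
degrees of freedom are stored on SVZ cells only.  A compiled kernel
evaluates the right-hand side; the pure-numpy implementation is kept as
the reference and the two are asserted equal in the suite.  Runs
terminate early when any field exceeds 10³ × the initial maximum
(blow-up) or when an evaluation budget is exhausted; both are reported
as failures with the partial trajectory retained, never raised.

## Initial conditions and readouts

Mimicking the labelling experiment: n_C = n_A = n_N = 0; f_A is a
Gaussian in the OB (peak 1, width half the OB side); n_B a Gaussian at
the SVZ centre (peak 100, width 5/6 × half the SVZ side) truncated to
the SVZ.  Runs last 300 days (the imaging horizon); screening campaigns
use a 100-day horizon.  The scalar readout `ob_signal` = Σ_OB (n_A +
n_N)·h² stands in for the photon flux with unit proportionality and no
label decay — hence, unlike the in-vivo signal, it does not decline
after the plateau (the model tracks all progeny, not a finite labelled
cohort).  Saved frames default to one per day.

## Solution classifier

Categories are qualitative; every threshold is an explicit
`ClassifierConfig` field:

* **unphysical** — failed/partial integration, positivity violation
  beyond 1e-6 × field max, blow-up beyond 10³ × initial max, or more
  than 2 sign changes of d(ob_signal)/dt after day 30 (growing
  oscillations / pattern formation);
* **non_neurogenic** — final OB signal below 10⁻³ × the initial SVZ
  content, or a plateau reached before day 30 (immediate constant-flux
  regime);
* **physiological** — SVZ means within 10% of the algebraic steady
  states from day 100 onward, monotone OB-signal growth (1% dips
  tolerated) reaching a plateau (final slope ≤ 5% of peak slope; for
  horizons under 200 days, where the plateau may lie beyond the window,
  the requirement is that growth has at least decelerated past its
  peak, final slope ≤ 50%), and admissibility of the parameter set
  (positive steady states, η_i > δ_i) — directed, taxis-driven
  migration is part of what "physiological" means; a diffusion-
  dominated run can grow and plateau yet is not controlled migration.

Anything passing the unphysical and non-neurogenic gates but failing a
physiological check falls back to non_neurogenic.  The classifier is a
pure function of the stored result and parameters (deterministic).

## Parameter-space campaigns

Draws come from a seeded Mersenne-twister generator; campaigns are
byte-reproducible from (spec, seed).  Perturbation campaigns multiply
every coordinate by an independent uniform factor in [1−f, 1+f]
(default f = 0.1).  The guided search automates a manual-style
narrowing procedure: each round samples the current box, keeps the coordinate
span of physiological hits padded by 20% (never widening), and stops
when a full verification batch is entirely physiological.  The
narrowing heuristic itself is a package design choice — the original
search was manual.

## Deviation metric and sloppiness

ζ²(θ) = (1/A) Σ_species ∭ [u_i(x,y,t;θ) − u_i(x,y,t;θ*)]² dx dy dt with
A = 2·T_c·N_s (N_s = 5), evaluated by trapezoidal quadrature applied
successively in x, then y (honouring the multi-segment rows of the
box union), then t.  Any additional constant normalisation would scale
ζ² only and cannot affect normalized spectra (asserted).

The ζ² surface over parameter space is reconstructed from Monte-Carlo
samples by scattered-data interpolation.  The default backend is an
angular-distance-weighted modified Shepard scheme: inverse-distance
weights attenuated when a sample point is shadowed behind another
(weights fall as the angle subtended at the query point becomes acute),
blending local nodal models fitted by weighted least squares around
each node — quadratic where the cloud supports it, else linear — so the
interpolant is exact at the nodes and carries genuine curvature for
Hessian estimation.  Inverse-distance and thin-plate RBF backends serve
as cross-checks.  Hessians are computed by central differences
(five-point diagonal, four-point cross terms, symmetrized), with steps
of 1e-2 × coordinate on interpolated surfaces (matching the sampled
band).  Eigenvalues are reported by decreasing magnitude; the span in
decades (log₁₀|λ_max/λ_min|) and the sloppy-axis ratio
√(λ_max/λ_min) summarise the spectrum; a system is flagged sloppy when
the span reaches the configured threshold without any single gap
exceeding 3 decades (a sharp gap would mark a clean stiff/sloppy split
rather than the continuum characteristic of sloppy models).

Note that the spectrum measured this way is a property of the
*interpolated* surface at the campaign's sampling scale; the
finite-difference Hessian of ζ² by direct simulation probes strictly
local curvature and yields a narrower (but still multi-decade,
gap-free) span.  The suite asserts agreement of the two routes within
two orders of magnitude, the tolerance motivated by the ~50% relative
interpolation error measured on holdout solves.

## Problem sizes used by the test suite

Tests and the acceptance script run on the coarse fixture (h = 0.1, 496
cells, T_c = 100, 101 frames) — chosen so a single run takes seconds —
with the 300-day reference run for the growth-plateau and onset checks,
a 200-sample ±10% screening campaign, a 180-sample blind uniform(0,1)
campaign, and a 5-parameter (β_B, α_C, γ_N, δ_N, κ_B) ζ² sub-campaign
of 60 solves for the spectrum checks, in a two-shell design (±10% band
plus a ±3% inner shell) so the interpolant is accurate both across the
band and locally where the Hessian is differenced.  The sub-space mixes
strong SVZ kinetics with weak death/diffusion rates so that widely
separated sensitivities are represented.  The full 27-parameter campaign at
h ≈ 0.0178 behaves the same way but needs hundreds of expensive PDE
solves; the CLI (`svzsim sloppy`, `svzsim perturb`) runs it on demand.

## What the synthetic conditions do and do not show

All inputs are generated (no external data): the initial bolus, the
geometry and the reference parameters define the study conditions.
Passing tests demonstrate internal consistency — correct transport
operators, error-controlled stiff integration, reproducible campaigns,
and the documented qualitative regimes over these conditions.  They do
not validate the biology: the attractant is hypothetical, the dispersal
field g phenomenological, the photon-flux proxy ignores label dilution,
tissue absorption and scar artefacts, and the classifier thresholds,
while explicit, are package choices rather than measured quantities.

## Known limitations

* The guided search narrows a single box; disjoint physiological
  islands would be merged or missed.
* Shepard-type interpolation is exact at nodes but its curvature
  between distant nodes is an extrapolation of local fits; Hessian
  spectra inherit interpolation error (hence the two-route check).
* The blow-up guard (10³ × initial max) cannot distinguish a genuinely
  large-amplitude physiological regime from divergence; with the
  shipped initial conditions (max 100) the bound is far above any
  plausible density scale.
* The OB-centre square is rasterised by cell-centre membership, so the
  death/specification region changes in whole rings of cells as b
  crosses a cell boundary; the reference b = 0.5 on the h = 0.1 grid
  sits exactly on such a boundary, making observables discontinuous in
  b there (a property of any sharp-indicator discretization).
* At horizons shorter than ~200 days the growth-plateau judgement is
  intrinsically ambiguous; the short-horizon deceleration rule is a
  pragmatic compromise and is reported per-criterion in the
  classification report.
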