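# Methods

This note records the models, conventions, numerical choices, and known
limitations of `memperm`, in the spirit of a package's model
documentation: what is computed, under which assumptions, and what the
synthetic validation does and does not establish.

## Coordinate and unit conventions

All analysis runs in membrane-centered coordinates: z = 0 at the bilayer
midplane, z periodic over the box height H, with the single water slab
spanning the periodic wrap (the box edge lies in water). Lengths are Å,
times ps, energies kcal/mol, temperatures K; k_B = 0.0019872041
kcal/(mol·K). Permeabilities convert as 1 Å/ps = 10⁴ cm/s; number
densities convert to mol/L through Avogadro's number.

Geometry is held by three numbers: the dividing surfaces at |z| = h/2
separating membrane from water; the midplane region |z| < z_mid
(default 4 Å, the transit rule's central region, adopted for all
permeant types and configurable); and a water-reference zone, default
|z| ∈ [h/2 + 5 Å, H/2], over which the free-energy reference F_ref is
averaged. The reference zone is a convention — any interval where the
profile has flattened gives the same physics — and is exposed as
configuration.

## Synthetic trajectory generator

Permeant z-motion follows the overdamped Itô equation

    dz = [−β D⊥(z) F′(z) + D⊥′(z)] dt + √(2 D⊥(z)) dW,

with periodic wrap over H; x and y diffuse independently with
√(2 D∥(z)) dW evaluated at the pre-step z. This is exactly the model
class the Bayesian analysis assumes (one-dimensional diffusive
transport, no memory), which is the point: the generator provides data
for which the inference problem is well-specified, with closed-form
ground truth.

Profiles are truncated cosine series periodic over H — F(z) with
harmonics k = 1..10 (the constant is gauge), ln D(z) with k = 0..5 —
so that ground truth lies exactly in the basis the inference uses, and
D > 0 by construction. Arbitrary even shapes are projected onto the
basis by quadrature (`ProfileSpec.from_shapes`).

Integration is Euler–Maruyama with the explicit D⊥′ spurious-drift term,
force and diffusion linearly interpolated from a 4096-point table. The
drift term is load-bearing: the test suite contains an ablation showing
that omitting it biases the stationary distribution toward low-D regions
(density ∝ 1/D for flat F), detectably at the default parameters.

The default step is **0.02 ps**. A 0.05 ps step reproduces equilibrium
occupancies well but biases membrane crossing rates of the default
oxygen-like profile by about 10% (weak first-order error amplified by
the exponential sensitivity of rates); rates are converged at 0.02 ps
(0.02 and 0.005 agree within counting noise). Frames are saved every
1 ps by default. A warning fires when √(2 D_max Δt) approaches the
finest basis feature.

Default study conditions mirror a typical all-atom permeation setup:
50 permeants in a 40 × 40 × 70 Å box at 298 K, tens of ns per permeant,
initial positions drawn from the Boltzmann distribution of F (so the
initially-inside half-crossing rule is exercised); a uniform or
water-slab start is available. The built-in profile fixtures are
qualitative: an "oxygen-like" midplane well of −1.5 kcal/mol with weak
head-group shoulders and interior-enhanced diffusion (≈0.2 Å²/ps in
water, ≈0.44 at the midplane, anisotropy > 1 inside), and a
"water-like" 6 kcal/mol central barrier with a shallow metastable
midplane dip. They are test fixtures with realistic magnitudes, not
parametrizations of any specific lipid system.

What the generator does **not** emulate: solvent memory and
non-diffusive short-time dynamics, permeant–permeant interactions,
membrane undulations and thickness fluctuations, and any coupling
between lateral position and the free-energy profile. Passing the
validation suite therefore shows the estimators are correct for
memoryless diffusion — it does not show that counting and
profile-based permeabilities agree on real MD data, where memory
effects genuinely separate them.

## Crossing events and the counting permeability

Event detection runs on a continuous unwrapped coordinate built from
minimum-image frame displacements, so wraps through the water slab can
never fabricate membrane events. Episodes are classified crossing /
rebound / initial-escape / unresolved / unresolved-at-end; a crossing
requires opposite entry and exit sides plus an observed midplane visit.
Opposite-side exits with no observed midplane frame — including
single-frame jumps clean through the membrane — are "unresolved" and
excluded from the count rather than guessed. Times use the frame
convention (entry = first frame inside; exit = first frame outside;
midplane = first frame in the central region); episodes also record the
*last* midplane visit, because at equilibrium the entrance segment
(entry → first midplane arrival) is the time-reverse of the terminal
escape segment (last midplane visit → exit) — an exact identity the
tests verify. Note that τ_esc as defined (first midplane arrival →
exit) exceeds τ_entr even without trapping whenever the permeant
lingers near the midplane; the two approach each other only when the
profile expels permeants quickly, and a deep well makes τ_esc ≫ τ_entr.

The effective count is (#crossings) + 0.5·(#initial escapes); its
default 95% CI is the exact (Garwood) Poisson interval, with an
across-replicate t-interval when ≥3 replicate groups are supplied (both
labeled). Initial escapes do not require a midplane visit — their entry
history is unobserved and the rule rests on memoryless exits, an
assumption the acceptance script verifies by direct Monte-Carlo
(expected 0.5 crossings per initial escape).

A systematic property of frame-based counting, measured here across
seeds and profiles: at a 1 ps save interval the counted transit rate
falls ≈9% below the continuous transition-path rate 2 c_w P, because
sub-save-interval water excursions at a surface merge transit pairs
into apparent rebounds. The deficit is independent of the integrator
step and shrinks with the save interval (≈4% at 0.2 ps). Consequently,
the counting/ISD equivalence check runs on trajectories saved every
0.2 ps, where the artifact is below its statistical resolution; users
comparing the two estimators on their own data should treat the save
interval as part of the counting method's error budget.

L∥ is reported as the root-mean-square lateral displacement between
entry and exit over resolved residence episodes (the mean-absolute
alternative is not provided); a profile-based companion estimate
√(4 ⟨D∥⟩_Boltzmann τ_esc) is available and labeled as a convention.

## Free energy, concentrations, partitioning

F(z) = −k_BT ln p(z) from the pooled histogram (default 100 bins),
unsymmetrized (a symmetrize flag exists for diagnostics only);
unvisited bins carry an infinite-F sentinel that round-trips through
the TSV format and is excluded from F_ref averaging. c_w comes from the
Boltzmann-integral expression, with an optional far-zone time-average
cross-check; both are gauge-invariant under constant shifts of F.
K(h) integrates e^{−β(F−F_ref)} between interpolated dividing surfaces
by composite trapezoid.

The thickness-insensitivity of the K ratio deserves a caveat the
headline statement omits: K₁(h)/K₂(h) is flat in h only when both
Boltzmann integrals are dominated by the membrane interior (K ≫ 1, as
for oxygen). For weakly partitioning systems the common water-like edge
contribution makes the ratio drift by several percent over a ±3 Å
sweep. The validation fixture uses midplane wells of 3.5 and 3.0
kcal/mol (σ = 5 Å), which differ only deep inside the membrane and give
a ratio variation below 1% while the individual K(h) vary by > 5%.

## Bayesian rate-matrix inference

Transitions are counted with sliding origins at every saved frame, z
binned on the periodic grid, lateral displacements by per-axis minimum
image (radial histogram up to R_max, overflow in the last bin with a
tally). The generator is the nearest-neighbor Smoluchowski rate matrix
with midpoint (arithmetic-mean) diffusion and detailed balance built
in; its exponential is computed from the eigendecomposition of the
exp(±βF/2)-symmetrized matrix, with scipy's scaling-and-squaring as a
fallback. Probabilities at or below 1e−15 — the cancellation noise
floor of the spectral exponential — are treated as zero, and a nonzero
count there returns −∞.

The radial (in-plane) likelihood expands the lateral propagator in J₀
Bessel modes with a reflecting wall at R_max (x_k the zeros of J₁,
mode k damping the z-generator by D∥(z) x_k²/R_max²); the radial start
is a point at Δr = 0, so only bin-integrated J₀ end-weights are needed.
Defaults follow the standard settings (100 z-bins, 10 F-cosines, 6 per
ln D, 50 modes, 100 radial bins, R_max = 50 Å, lags 20/30/40/50 ps).
At strongly reduced mode counts the truncated expansion rings negative
in sparse bins; reduced-setting runs therefore shrink R_max so that all
mode weights stay positive (10 modes with R_max = 25 Å), and the
likelihood floors residual ringing at 1e−12.

Sampling is component-wise adaptive Metropolis: flat priors (|a_k| ≤ 10
k_BT for F; ln D within ±4 of its initialization), per-coefficient step
sizes adapted during burn-in toward a 25–50% acceptance window,
initialization from the histogram F and a mean-squared-displacement
constant-D fit, one independent run per lag, fully seeded. Acceptance
below 1% after adaptation aborts with diagnostics. D(z; τ) is fitted
per bin linearly in 1/τ; the intercept is the infinite-lag profile and
the fit residuals are kept as diagnostics. The linear-in-1/τ form is a
package choice; empirically it removes both the bin-center
discretization inflation (∝ Δz²/τ) and short-time-memory deficits,
which both enter the apparent D at order 1/τ.

Two sources of systematic error matter at reduced settings: bin-center
discretization (apparent D inflated by ~Δz²/6 per 2τ; a few percent at
50 bins and the standard lags, ~15% at 25 bins and 20 ps) and the
sliding-origin correlation (overlapping pairs are treated as
independent, so single-run posterior spreads understate uncertainty —
which is why between-replicate spread over four independent replicate
runs is the error convention for BA results).

Validation at the package's study sizes (48 permeants × 40 ns):
lag-averaged F recovered within 0.3 k_BT RMS (typically ≈0.03), D⊥
within 10% per bin after extrapolation at 50 z-bins (typically ≤5%),
D∥ within 15% via the radial likelihood at 25 z-bins and 10 modes
(typically ≤5%).

## Transport summaries

ISD and the effective radial permeability integrate on the profile grid
with the dividing surfaces interpolated as exact endpoints. P∥ is
defined here as the Boltzmann-weighted in-plane conductance

    P∥ = (1/h²) ∫ e^{−β(F−F_ref)} D∥(z) dz,

a convention chosen to be dimensionally a permeability and to reduce to
D∥/h for a homogeneous membrane; outputs carry the convention tag so a
different literature form can be swapped in at one site. The anisotropy
profile D∥/D⊥ propagates relative errors in quadrature.

## Pathway classification

Chain–permeant distance is the minimum over (heavy atom, chain carbon)
pairs under the lateral minimum image; z is not imaged (chains live
inside the membrane). Ties at the third neighbor break deterministically
by (distance, chain_id). A sterol counts as a single chain comprising
all its carbons; each acyl chain of a two-chain lipid is its own chain.
Class fractions are pooled over frames (not averaged per frame), the
sample's slab is set by its first heavy atom's z, and slabs default to
1 Å. The toy-membrane generator records ground-truth classes through an
independent geometric route (site positions + carbon z-levels), so
generator and classifier can disagree only on near-degenerate triples;
measured agreement exceeds 95%, with residual disagreements from
permeants nearly equidistant to competing chains.

## Oximetry surrogate

n_O2(r) counts oxygen *atoms* within r (a molecule-counting mode exists
for sensitivity analysis), averaged over frames and probes under the
full 3D minimum image; g(r) normalizes shell counts by shell volume and
the mean box density, warning when radii pass the inscribed sphere. The
probe-to-oxygen distance uses atom positions; whether the original
analysis used atom or molecule-center distances is exposed as the same
mode switch. I(r) divides c_w-normalized populations; its default
contact radius is 4.5 Å.

Saturation fitting is Levenberg–Marquardt on the homogeneous-saturation
amplitude formula with initial guesses from the unsaturated low-power
region; at P = P_{1/2} the model equals half the unsaturated
extrapolation I₀√P, an identity kept exact by construction. Relaxation
ratios form enhancements as oxygenated-minus-inert differences before
dividing (R2 from linewidths, R1 from P_{1/2}/linewidth), average the
two ratios, and propagate errors in quadrature; a zero enhancement in
the reference system yields NaN for that channel rather than a
division error.

## Degenerate inputs and tie-breaks (summary)

Empty histograms, all-sentinel profiles, lags incommensurate with the
save interval, fewer than three chains, fewer than four saturation
powers, and missing gas conditions raise immediately with named
context. Sentinels inside the ISD or K integration range are errors
(not silently skipped); outside, they contribute zero Boltzmann weight.
Zero crossing counts produce P = 0 with a one-sided Poisson upper
bound. Identical seeds reproduce trajectories, posteriors, and reports
bitwise.

## Problem sizes used in validation

The validation suite runs scaled-down but statistically meaningful
studies: the shared long run is 48 permeants × 40 ns (0.2 ps saves) for
the counting/ISD comparison (≥200 full crossings) and profile recovery;
replicate BAs use 12 permeants each; the event-detection oracle runs
1,000 randomized series; classifier and fit oracles use 100 fixtures or
seeds. These sizes were chosen so that statistical error sits near or
below the systematic tolerances being asserted.

## Known limitations

* The counting estimator inherits the save-interval undercount
  described above; it is a property of frame-based counting, not of
  this implementation.
* The BA assumes Markovian diffusion on a grid; its posterior widths
  from a single run are optimistic (sliding-origin correlation), and
  reduced grids trade accuracy for speed as quantified above.
* P∥ and the profile-based L∥ are conventions pending a canonical
  definition; both are tagged in outputs.
* The oximetry surrogate ties relaxation enhancement to a contact count
  at a fixed radius; lineshape physics and spin dynamics are out of
  scope (amplitudes and linewidths are inputs).
* MD trajectory formats are not parsed directly; adapters emitting the
  TSV dialects are the intended integration point.
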