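# Methods

This note records the models, estimators, numerical conventions and design
choices behind `flowsle`, in the order the pipeline runs. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Vorticity and binarization

The vorticity ω = ∂ₓu_y − ∂_yu_x of a gridded velocity field is computed
with the standard fourth-order five-point central stencil,
(f₋₂ − 8f₋₁ + 8f₊₁ − f₊₂)/(12h), applied to each partial derivative. The
stencil is exact on polynomials up to degree four (a unit test asserts
this). For experimental-style fields the outer two-node frame, where the
stencil is undefined, is cropped; simulator fields use periodic wrapping.
Arrays are oriented so that physical y grows with the row index, which fixes
the sign of ω and makes the orientation convention below reproducible.

The binary field is 1 where ω > 0 *strictly*; zeros join the non-positive
phase. Binarization is invariant under positive rescaling of the velocity
field, so the downstream statistics do not depend on velocity units.

## Oriented contours

Contours live on the dual lattice: vertices at cell corners, unit steps of
one grid spacing, and every walk keeps cells of positive vorticity on its
right. Outer boundaries and hole boundaries are traced as separate closed
cycles; with y up, outer boundaries are clockwise (negative signed area).
Two saddle conventions exist for the ambiguous marching-squares cell:

* **square** — the positive phase stays 4-connected, the negative phase
  8-connected (used for vorticity fields);
* **triangular** — sites are also adjacent along the +row/+col diagonal,
  the standard square-grid embedding of the triangular lattice, on which
  site percolation is critical at exactly p = 1/2. The complementary phase
  uses the same adjacency (the lattice is self-matching), so saddles are
  joined exactly when their 1-cells lie on the adjacency diagonal.

The *accessible external perimeter* of a cluster is the outer contour of
its one-iteration dilation by a 3×3 square structuring element, which seals
fjords narrower than one lattice unit — the discrete analogue of probing
the boundary from outside with a finite-radius disk.

Chordal explorer traces are produced by drawing a real axis along a dual
lattice row and starting a walk at each up-crossing of a contour. The axis
condition is implemented exactly like the chordal boundary condition of a
percolation exploration: a virtual boundary row below the axis is coloured
positive to the right of the origin and negative to the left, after which
the ordinary right-hand tracing rule reproduces the required behaviour
(following the contour, sliding along the axis until the walk can re-enter
the upper half-plane) with no special cases. Walks end at the domain edge.

## Scaling statistics

**Gyration radius.** R_g is the root-mean-square distance of cluster sites
from their centroid, equivalently √[(1/2N²) Σₙₘ |rₙ − rₘ|²]. (The pair-sum
form normalised by N alone would carry units of length·√N; only the
standard normalisation matches "mean square displacement from the centre of
mass", and it is the one implemented.)

**Fractal dimensions.** D (complete) and D* (accessible) are least-squares
slopes of log l against log R_g over log-binned medians (12 bins per
decade, ≥5 clusters per bin, relaxed for smoke-scale ensembles). The
default window excludes the smallest decade of R_g — tracing and dilation
act at the scale of single sites there — and everything above 0.35 R_g,max,
where the largest clusters feel the domain boundary. Axes are normalised by
R_g,max, which cannot change a log-log slope but makes exported axes
comparable across systems. The accessible-perimeter exponent has slow
finite-size corrections: its effective slope is still ≈1.26 for clusters
up to R_g ≈ 100 lattice units and approaches 4/3 from below only once the
fit window reaches R_g of several hundred, which is why the percolation
reference ensembles use fields of 2048² sites.

**Winding angles.** The winding angle is the cumulative sum of signed
turning angles between consecutive segments. Var(θ) at arclength s is
estimated the way the conformal prediction Var = a + [2κ/(8+κ)] ln s is
formulated: each trace is cut into non-overlapping windows of s steps, the
angles inside each window are measured *relative to the window's average
angle*, and the pooled variance is fitted against ln s over s ∈ [32, L/4]
(L a lower-quartile trace length). Anchoring instead at window endpoints
measures tangent-angle differences between two deep interior points and
doubles the slope — the segment-mean convention is the one under which the
percolation ensemble reproduces 6/7. Gaussianity at fixed s is assessed by
standardized skewness and excess kurtosis plus a KS distance to the unit
normal. Curves sampled non-uniformly in arclength (e.g. Loewner-time
sampling) must be resampled to uniform arclength first
(`resample_arclength`); note that forward-SLE traces at practical step
counts remain too coarse for faithful winding statistics — the loop-erased
random walk is the lattice-resolved κ = 2 ensemble used for
cross-validation.

## SLE inference

**Left passage.** A trace passes left of a point z when the cumulative
angle subtended by the trace at z is negative (the point lies right of the
directed curve); this winding-style criterion is robust for curves that
touch the real axis, as κ = 6 traces do. The sample points are 5
logarithmically spaced radii × 9 angles (π/10 … 9π/10). The radii span
0.04–0.15 of the median trace extent: Schramm's formula describes a curve
running to infinity, and radii that are not small compared to the observed
curve acquire a truncation bias that systematically depresses the fitted κ
(by ≈0.3 when radii reach half the extent). κ̂ minimises the weighted
mean-square deviation Q(κ) between empirical frequencies and P_κ(φ) over
κ ∈ (0.5, 7.9) — bounded away from 8 where Γ((8−κ)/2κ) has a pole — with a
standard error from the curvature of Q at its minimum.

**Driving function.** The vertical-slit zipper: at each step the first
unmapped point w = x + iy fixes a slit map with base δ = x and capacity
increment Δ = y²/4; U_t is the sequence of bases against cumulative
capacity. Points on the axis carry zero capacity and are skipped (they
produce the jumps a boundary-touching discrete curve implies). The zipper
is O(n²), so traces are subsampled to ≤1500–2500 vertices first; on exact
SLE test curves subsampling at these levels leaves the recovered variance
slope unchanged. κ̂ is the through-origin slope of the ensemble variance
Var(U_t) on a common time grid, with all traces truncated at the common
capacity horizon (the grid end), so times rescaled by the horizon lie in
[0, 1] for every trace; the collapse diagnostic compares U_t/√(κ̂t) at
t = 0.25 and 0.75 of the horizon to a unit normal, and the Markov
diagnostic is the increment autocorrelation averaged over time origins.

For *lattice* curves Var(U_t)/t has three regimes: an excess at small t
(the curve is not yet fractal at lattice scales, and O(1) boundary
excursions near the origin are large compared to √t), a plateau at the
universal diffusivity, and a suppression once U has diffused across the
finite domain (|U| cannot exceed the lateral half-width W). The fit window
[max(800, t_sat/8), t_sat] with t_sat = 0.025 W² brackets the plateau;
`lattice_driving_window` encodes it. With this window an ensemble of
~1500 interfaces on 500-wide lattices determines κ to ±0.22 (the effective
degrees of freedom of a variance fit are the trace count).

## Synthetic ground truth

**Percolation interfaces.** Site percolation at p = 1/2 on the triangular
lattice, realised as hexagonal cells explored chordally: the boundary row
below the real axis is coloured by the sign of x, the walk starts on the
edge shared by the two forced cells meeting at the origin — so the
interface invariant holds from the first step — and each turn is decided
by the cell straight ahead (left if positive, keeping it on the right).
The walk is provably edge-self-avoiding (a unit test checks it) and ends
at the lattice boundary. Its scaling limit is chordal SLE₆.

**Forward SLE.** Discrete Loewner evolution: Brownian driving with
Var = κ dt per step, trace points from composing inverse slit maps in
reverse. The zipper inverts it to machine precision, which makes the
forward/inverse pair a closed round-trip oracle.

**Loop-erased walk.** The simple random walk conditioned to stay in the
upper half-plane (h-transform with h = y) with loops erased on the fly;
its scaling limit is chordal SLE₂. Unlike forward-SLE traces it is fully
resolved at the lattice scale, so it also supports winding statistics.

**Active nematic.** The minimal incompressible active nematic: a traceless
symmetric order parameter Q (stored as its two independent components, so
symmetry and tracelessness are exact) advected and co-rotated by the flow,
relaxing via the molecular field H = 2K∇²Q (no bulk free energy — ordering
is activity-induced), coupled to a D2Q9 lattice-kinetic flow step with Guo
forcing by the divergence of the elastic and active stresses (−ζQ). The
production parameter set is Γ = 0.05, K = 0.05, μ = 1, λ = 1, ζ = 0.1 on a
4096² lattice, where the active length √(K/ζ) = 0.7 lattice units. At the
scaled-down default of 256² that length is unresolvable, so (K, ζ) are
moved along the line preserving the production velocity scale
ζ√(K/ζ)/μ ≈ 0.07 — keeping the kinetic solver in its low-Mach regime —
while raising √(K/ζ) to a resolvable value. Numerical safeguards, each
with a dedicated test:

* first-order upwind advection of Q (centred advection is unstable at the
  low molecular diffusivities used);
* sub-stepping of the Q update whenever 2ΓK approaches the explicit
  diffusion limit;
* a spectral low-pass on the body force (0.4 of the Nyquist wavenumber at
  the default elasticity): the centred stencils of the stress divergence
  and of the velocity gradients disagree at sub-lattice scales, and
  unfiltered high-k forcing closes an anti-dissipative feedback loop
  through the flow-alignment coupling. The passive (ζ = 0)
  free-energy-descent test pins the admissible cutoff, which grows as K
  shrinks; the physical bend-instability forcing at ~2π√(K/ζ) lies well
  inside the passband;
* a weak biharmonic filter on Q and a soft cap on the order-parameter
  magnitude (2|Q| ≤ 1.25; the stationary turbulent state sits near 1),
  which never engages in normal operation but prevents rare local
  overshoots from running away through the cubic flow-alignment terms.

Initial conditions smooth the random Q perturbation at the active length —
structure below the coherence length is unphysical and would kick the flow
solver with O(K) forces. The warm-up default detects the transient from
the RMS velocity (stationary when successive 200-step windows change by
<2% three times in a row) and discards the same duration again.

What the scaled-down run does *not* emulate: the production run's two
decades of scaling range between the active length and the box. With
√(K/ζ) of a few lattice units in a 256² box, vorticity clusters span barely
one decade above the smooth sub-active-length regime, so exponent estimates
from the scaled-down model carry visible crossover corrections; the
percolation ensembles, which have no inner smoothing scale, are the
precision ground truth, and the continuum run is a qualitative
recapitulation at reduced scale.

## Acceptance computations

`scripts/acceptance.py --seed S --out F` recomputes, from fresh synthetic
data seeded by S: the left-passage κ on 600 interfaces (400-wide lattices),
the driving-function κ on 1200 interfaces (500-wide lattices, plateau
window as above), and the duality product from the complete and accessible
exponents of sixteen 2048² percolation fields (clusters of ≥25 sites). All
three have exact reference values (6, 6, 1). Runtime is ~6 minutes on one
CPU.

## Known limitations

* The accessible-perimeter exponent converges slowly from below; fields
  smaller than ~1000² underestimate D*.
* Left-passage and driving estimates on finite lattices carry residual
  truncation corrections of a few per cent even inside the chosen windows.
* Forward-SLE traces at feasible step counts under-resolve the curve in
  arclength; only capacity-based statistics (the driving function) should
  be measured on them.
* The continuum model is a scaled-down surrogate: its exponents are
  crossover-affected (see above) and the lattice-kinetic solver is run at
  low but finite Mach number. At 256² the vorticity-cluster perimeter
  exponent and the left-passage diffusivity measured by the test suite
  remain a few per cent below their asymptotic values — the corresponding
  production-tolerance checks are expected to fail at desk scale, and the
  percolation ensembles carry the quantitative burden instead.
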