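# Methods

This note documents the models, conventions and numerical choices behind
`gaitspace`, in the order data flows through the package.

## Tracked trials and derivatives

A trial is a fixed-rate time series of dorsal-view 2-D landmarks in mm:
body COM, cranial and caudal ends, and up to eight tarsus tips labelled
`L1–L4, R4–R1` (the canonical counterclockwise circuit from foremost left to
foremost right leg). Absent leg columns denote autotomized legs. Interior
tracking gaps of at most 3 frames are linearly interpolated with a warning;
longer gaps fail validation — tolerating longer gaps per stride rather than
per trial is a possible refinement. An optional `px_per_mm` calibration
converts pixel exports at read time; the core is unit-agnostic beyond mm/s.

Velocities use a running least-squares quadratic fit: the slope of a
quadratic fitted over a centered window, evaluated at the window center.
Defaults are a 50 ms window for the COM and 40 ms for tarsi. The filter is
exact for polynomials up to degree 2; on a sinusoid of angular frequency ω
it attenuates the derivative by the analytic factor `Σⱼ wⱼ sin(ω tⱼ)/ω`
(with `wⱼ = tⱼ/Σ tₖ²` the slope weights), about 6% at 6 Hz for the 40 ms
window at 500 frames/s — the tests use this closed form as their error
bound. Edge frames use truncated one-sided windows (linear fit if fewer
than three samples remain) so series stay frame-aligned; downstream
validity masks exclude the truncated region instead.

The comoving body frame translates the COM to the origin and rotates the
instantaneous COM velocity to +y. Frames with COM speed below 1 mm/s have
no defined heading and are flagged invalid (the threshold is arbitrary but
far below running speeds; it only matters at rest). The transform is a
rigid isometry per frame and is exactly invertible on valid frames.

## Kinematic measures

Path tortuosity is the straightness index τ = d/D. Both the displacement d
and the path length D are measured on the quadratic-fit-smoothed COM
trajectory: at hundreds of frames per second, summing raw per-frame steps
lets tracking jitter dominate D and biases τ toward 0; computing both
quantities from one smoothed path removes that bias and guarantees τ ≤ 1 by
the triangle inequality. Yaw is the signed angle from the instantaneous COM
velocity to the cranial-pointing body axis, positive when the axis lies
counterclockwise of the velocity in dorsal view (instantaneous, not
trial-mean, velocity is used).

Stride boundaries are successive peaks of a tarsus's velocity projected on
the COM motion direction; the stride period is their mean spacing. Peak
selection uses a minimum inter-peak distance of half the dominant period
(first autocorrelation peak) and a minimum prominence of half the series'
standard deviation. Velocity samples are quantized at 1e−9 of the series'
dynamic range beforehand so numerically flat plateaus (piecewise-linear
synthetic waveforms) become exact ties whose central sample is returned,
instead of float noise picking an arbitrary plateau sample. Stride length
is the COM displacement accumulated over each stride — the quantity is
named but not defined in the source literature, and this is the natural
reading.

A tarsus is in stance when it moves caudally relative to the COM: fore–aft
body-frame velocity below −2 mm/s, with runs shorter than 3 frames removed.
The threshold and debounce are repository choices (the caudal-motion
criterion itself is standard); 2 mm/s is far below typical retraction
speeds (~100 mm/s) yet above derivative noise at the stated tracking
uncertainty. A leg dragged passively — fixed relative to the body — never
moves caudally relative to the COM and correctly receives duty factor 0.
Duty factors are per-stride stance fractions using the detected stride
boundaries.

The allometric helper composes a speed–mass exponent `a ± σa` with a
mass–length exponent `b ± σb` into `a·b ± √(b²σa² + a²σb²)` (first-order
propagation, inputs independent).

## Static stability and posture

The support polygon is the convex hull of the stance tarsi (lab frame);
N_support counts them. SSM is the minimum distance from the COM projection
to the polygon edges: positive inside, zero on the boundary, and the
negated distance to the hull when outside or when fewer than three
non-collinear supports exist — a defined (negative) value in unstable
frames is required for median/MAD summaries. ISSM evaluates the same
margin with the COM at the area centroid (the wording of the source
definition; the Chebyshev center would maximize the margin for irregular
polygons, so SSM ≤ ISSM is guaranteed only for centrally symmetric hulls
and is reported, not asserted, in general).

Mean leg directions are circular means of per-frame tarsus bearings about
the COM; adjacent-leg angles are the gaps between neighbours in angular
order (summing to 360°), with the uniform-spacing expectation 360/N: 45°
for eight legs, 60° for six. Tarsal range of motion is the convex-hull
area of a leg's body-frame positions after removing points whose radial
distance from the coordinate-wise 2-D median deviates from the median
distance by more than 3 MAD (the 1-D ">3 MAD from the median" rule applied
to radial distances, the natural 2-D generalization). Leg extension is the
mean |fore–aft| and |lateral| body-frame tarsus offset from the COM.

## Gait space

The phase estimator treats each standardized fore–aft tarsus coordinate and
its derivative as a harmonic-oscillator pair: φ = atan2(−v̂, ŷ)/2π mod 1.
Standardization is over the whole trial (per-segment standardization would
track amplitude drift but fragments short trials). Phases feed adjacent-leg
differences Δφᵢ = φᵢ₊₁ − φᵢ mod 1 along the canonical circuit restricted to
present legs; the result is invariant to a common phase shift of all legs.

The metric tensor is derived by quotienting the flat unit-weight metric on
the N leg phases by the common phase: in difference coordinates,
`gᵢⱼ = min(N−i, N−j) − (N−i)(N−j)/N`. It is symmetric positive definite
with all entries positive; Σg = 17.5 for N = 6 and 42 for N = 8.

Distances use the *signed* minimal circular separation per coordinate in
the quadratic form. The magnitudes are the per-coordinate minimal circular
distances, but the signs matter: with them, the form equals the leg-space
distance minimized over a common phase shift exactly, for all pairs whose
separation vector lies within half the shortest lattice vector of
Z^(N−1) under g (the Voronoi cell guarantee); an unsigned form inflates
mixed-sign cross terms and matches no quotient construction. The test
suite verifies this against a brute-force grid minimization over the
common phase that never references g. Outside that near-field ball the
form is kept as the primary definition even though additional coordinate
wraps could shorten the true torus geodesic — the conventional d_max
normalization (`d_max = √(0.25 Σg)`, attained when every leg pair is in
antiphase) presumes the single-branch form. Coordinates separated by
exactly half a cycle have two equal-magnitude representatives; the branch
maximizing the form is used, which is symmetric in argument order and
keeps d_max attained at the all-antiphase separation. Normalized
distances Δ = d/d_max lie in [0, 1]; Δ(ABT, MT) = 0.29 for six legs.

Dataset-to-model distances are means of per-point Δ with percentile
bootstrap 95% CIs (1000 resamples, seeded generator).

## Clustering

Pairwise normalized gait distances (condensed form) feed Ward's linkage via
the Lance–Williams update. Ward's variance-minimization rationale assumes
Euclidean input; using it on the non-Euclidean gait distances mirrors
established practice and is validated empirically: on seeded von Mises
mixtures of the two six-leg model gaits at κ = 4 (1000 + 1000 samples),
cutting at k = 2 groups ≈ 98–99% of samples with their originating model,
and per-point nearest-model assignment reaches ≈ 95% — the suite asserts
≥ 95% for both. Dendrograms are cut below the k−1 highest merges; k
defaults to 3 for empirical datasets and 2 for two-model simulations, and
no automatic selection of k is attempted. Centroids are per-coordinate
circular means; clusters are named by nearest model with rank suffixes by
increasing centroid distance (MT1 closer than MT2), ties broken in the
canonical model order (ALT, ABT, MT) and logged. Circular histograms use
24 bins on [0, 1) by default and report the circular mean direction and
resultant length R.

## Synthetic data

The simulator closes the loop for testing. Gait-point clouds draw each
coordinate independently from a von Mises distribution about the model
gait (independence matches the per-coordinate construction; correlated
noise is out of scope). The concentration κ is recovered by inverting the
resultant-length equation A(κ) = R̄ with the Banerjee et al. approximation
polished by Newton steps on exponentially scaled Bessel ratios; per
coordinate, then averaged.

Ideal footfall patterns put leg k in stance when `(t·f + φₖ) mod 1 < duty`,
with φₖ the cumulative leg phases implied by the gait. At duty 0.5 this
yields the expected stance counts: constant 4 for the eight-leg alternating
tetrapod, constant 3 for the modified tripod, and a 50:50 alternation of
bipod and tetrapod for the ablated tetrapod.

Full synthetic trials advance the COM at constant speed along +y; each
tarsus oscillates fore–aft about a uniformly spread anchor (radius 0.75 BL)
with a piecewise-linear stride waveform: linear retraction over the stance
fraction — exactly ground-fixed when the amplitude takes its default
`speed·duty/f` — and linear protraction over the swing. The piecewise form
makes stance/swing ground truth exact. Optional per-stride von Mises phase
jitter and Gaussian tracking noise on every landmark complete the model.
Defaults describe the targeted recordings: body length 16 mm, 500
frames/s, 6 strides per bout at 6 Hz, duty factor 0.55, speed 8 BL/s
(stride length ≈ 1.3 BL), tracking noise sd 0.4 mm (a ±0.8 mm uncertainty
band read as 2σ), and no phase jitter unless requested — the concentration
fitted to real data in the source study is unpublished, so κ is left free
and validation accuracies are stated at explicit κ values.

What the simulator does *not* emulate: body yaw and heading error, turning
and tortuous paths, leg dragging, slipping, stumble-and-recovery
transients, amplitude/frequency drift within a bout, and correlated
tracking error. Pipeline tests passing on synthetic trials therefore
demonstrate correctness of the estimators under the stated signal model,
not robustness to every artifact of real footage.

## Problem sizes

Test and validation runs use desk-scale problems chosen to keep the suite
quick while leaving comfortable statistical margins: synthetic trials of 6
strides at 500 frames/s (~500 frames), clustering validation on 2000-point
mixtures, 100 oracle pairs on a 40001-point offset grid, and n = 1000–10000
for circular-statistics recovery.
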