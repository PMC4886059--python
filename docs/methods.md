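# Methods

## Outline model

A silhouette's closed boundary is treated as a discrete-time complex
periodic signal z_l = x_l + i·y_l (x = column, y = row, origin top-left,
0-based). The tracer follows the outer boundary of the first
raster-order foreground component: starting from the raster-first
foreground pixel with search direction d = 2 ("probe upward first"),
neighbours are probed counterclockwise in the cyclic direction order
DI[d], DI[d+1], …; after a step in direction DI[i] the search resumes at
d = (DI[i]+5) mod 8, and the walk stops when it returns to the start
pixel. Direction code 0 is east; codes increase counterclockwise in 45°
steps with "up" = decreasing row. The walk is bounded by 4·W·H steps; an
isolated pixel yields a length-1 contour flagged not closed.

Stopping at point coincidence (rather than the stricter entry-direction
criterion) can truncate boundaries that pass through the start pixel
twice; for the simply-connected silhouettes this package targets that
does not occur. Stroke drawings are converted to filled regions first
(morphological closing with a square footprint — a disk cannot bridge
1-px gaps in axis-aligned strokes — then hole filling).

The traced polygon is resampled to N uniform arc-length points
(default N = 256, a power of two so the FFT applies directly). Because
image rows grow downward, a traced boundary is clockwise in (x, y) plane
coordinates; the resampler reverses it (keeping the start point) whenever
the shoelace signed area is negative, so every signal is parameterized
counterclockwise and the fundamental coefficient Z_1 dominates — the
scale normalization divides by R_1 = |Z_1| and would otherwise divide by
noise.

## Descriptor and invariances

The unnormalized DFT Z_m = Σ_l z_l e^(−i2πlm/N) is indexed
m = −N/2 … N/2−1. Normalization sets Ẑ_0 = 0 (translation), divides all
moduli by R_1 (scale), and applies
θ̂_m = θ_m − (θ_{−1}+θ_1)/2 + m(θ_{−1}−θ_1)/2 (rotation + starting
point), which exactly cancels a rotation by θ_0 composed with a start
shift of l_0 positions. Phases are principal arguments in (−π, π], with
arg(0) := 0.

Two numerical conventions make this a deterministic function:

* **Half-turn ambiguity.** Worked with principal values, the phase rule
  leaves the residual group Ẑ_m → (−1)^(m+1)·Ẑ_m (sign flip of the
  even-index coefficients; geometrically a rotation by π with an N/2
  start shift). The package flips the even-index coefficients whenever
  the real part of the *strongest* even-index coefficient is negative.
  Anchoring on a fixed index would misfire for shapes where that one
  coefficient vanishes; the modulus-based anchor is transform-invariant
  and therefore stable.
* **Conditioning.** The phase reference uses θ_{−1}, and Z_{−1} is fed by
  the shape's ellipticity (the h = 2 radial harmonic). A shape with no
  ellipticity at all (a mathematically perfect circle-with-odd-harmonics)
  leaves θ_{−1} undefined and the start normalization ill-conditioned.
  Real silhouettes always carry some ellipticity; the synthetic templates
  all include an h = 2 component for the same reason.

Dimensionality selection computes the mean retained-energy curve
E(M)/E(N) over a shape collection, E(M) = Σ_{m=−M/2, m≠0}^{M/2−1}
|Z_m|² (the window is asymmetric exactly as defined), picks the smallest
even M reaching the target fraction, clamps to the descriptor minimum 4,
and rounds up to a power of two. The default M = 32 retains ≈ 99.99 % of
the energy on the synthetic benchmark shapes — they are smoother than
real traced organ models, whose curves flatten much later; the choice of
M matters more for real data than the synthetic tests can show.

Reconstruction is the inverse DFT of the truncated window,
ẑ_l = (1/M)·Σ Ẑ_m e^(i2πlm/M), giving M canonical outline points whose
coordinates are independent of the original position, size, orientation
and parameterization start.

## Features, FVT, MAXC

The feature vector is the sequence of distances r_t from the M outline
points to their centroid, in traversal order. The FVT cyclically rotates
it to begin at its minimum element (ties: smallest index; the recorded
anchor k is 1-based). The shift permutes values only, is idempotent, and
maps all cyclic rotations of a vector with a unique minimum to the same
canonical form — in particular it absorbs the half-turn flip (which
shifts the reconstruction start by M/2) and any residual start-point
misalignment the phase normalization leaves under noise.

The MAXC baseline ranks boundary points by a k-cosine turning-angle
curvature score (window k = max(2, n/50); score = π − interior angle
between the chords to the points k steps back/ahead) and keeps the M
highest-scoring points in boundary order, feeding the same radial
feature. Per the ablation design it uses raw boundary pixels — no
normalization — so it pays for scale and orientation changes; that is
the intended contrast with the descriptor path.

## Retrieval and evaluation

An index stores per-model, per-view feature vectors plus the pipeline
configuration (N, M, FVT flag, method, binarization options); queries
recompute their feature under the index's configuration and are rejected
on any mismatch. A model's score against a query is the minimum
Euclidean distance over its views (a sketch depicts one viewpoint); ties
break lexicographically by model id.

Evaluation uses the classical definitions — precision = relevant
retrieved / retrieved, recall = relevant retrieved / relevant, with
relevance = same category — summarized as 11-point interpolated
precision curves averaged over queries, and mean average precision
(AP = mean precision at the ranks of the relevant items). The comparison
harness indexes a labelled benchmark once per method (DRFVT, DR-NoFVT,
MAXC-FVT, MAXC) and queries every model's first view against the full
index (self-matches includable or excludable by flag; included by
default, which is why perfect separation gives MAP = 1.0).

## Synthetic data: what it emulates, and what not

Categories are harmonic signatures of a radial outline function
r(φ) = r0·(1 + Σ a_h cos(hφ + ψ_h)), rasterized as filled silhouettes
(amplitude sums < 1 keep r > 0, hence simple closed curves). Six
templates stand in for organ classes (body, heart, lung, ovary, kidney,
liver), chosen mutually well separated and each with a unique global
radius minimum. The body template stacks harmonics whose minima align on
the vertical axis, creating one sharp notch — the analogue of the
crotch/neck of an upright figure — so the minimum-radius anchor is
stable under horizontal widening and redraw noise, as it is for a real
body outline. Models within a category jitter the template's amplitudes
and phases (relative σ = 0.08); views of a model emulate how the same
object re-enters the system as a sketch: a random rotation, smooth
radial jitter (default amplitude 0.05), and, for the second and third
view, the default widening (+20 % horizontal) or cutting (truncation of
the outer part of a wedge covering 10 % of the boundary, radii clipped
to 75 % of the wedge maximum). With noise = 0 all view-level variation
is disabled and views are identical — the separable setting.

The generator exercises every code path (tracing, invariance, noise
robustness, ranking) but does **not** reproduce real anatomical
geometry, multi-part or self-occluding projections, stroke-width and
pen-pressure artefacts of real sketches, or outlines with fine
high-frequency detail; passing tests therefore demonstrate the method's
mechanics and its qualitative orderings, not clinical retrieval
accuracy. All randomness flows through explicitly seeded generators
(seeds derived via `numpy` seed sequences); identical seeds reproduce
identical image bytes and manifests.

## Noise-robustness experiment

Each of 100 trials draws a body-like base silhouette, produces a
*redrawn* distorted version — widened (+20 %) or cut (10 % of the
boundary), plus smooth radial redraw noise of amplitude 0.05, the same
level as the benchmark's view noise, since a transformed figure re-enters
as a fresh drawing, never a pixel-exact copy — and compares feature
distances with and without the FVT (pipeline N = 256, M = 64). When the
minimum anchor lands on the same index in both shapes, the two distances
are exactly equal (rolling both vectors by the same offset), so the FVT
can only help or tie unless the discretized argmin hops. Hops of ±1
position do occur — the M-coefficient reconstruction bandlimits even a
sharp notch into a smooth minimum — and cost the FVT a narrow loss in a
minority of trials; at the default settings the FVT wins or ties in
roughly 90 % (widen) and 85 % (cut) of trials, with a few points of
seed-to-seed variability. This argmin-hop sensitivity is the method's
main known limitation; shapes with a flat or ambiguous minimum (near
circles, symmetric doubles) degrade the FVT toward a coin flip.

## Problem sizes and numerical choices

Default sizes — benchmark 6 categories × 5 models × 3 views at 128 px,
N = 256, M = 32 (M = 64 in the robustness experiment), 200 invariance
pairs, 100 robustness trials — keep the full test suite and the
acceptance script in the seconds-to-a-minute range while leaving every
statistic stable to reruns. Rasterization facts the tests rely on, both
verified by enumeration: boundary pixels of a digitized disk lie within
1 px of the true radius (staircase inner corners reach ≈ 0.97 px
inside), and uniform resampling shortens a staircase polygon's perimeter
by ≈ 2.6 % at one sample per boundary pixel, converging below 1 % by
three samples per pixel.
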