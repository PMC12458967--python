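# Methods

## Posture representation

Body shape is represented as mean-subtracted tangent angles at the N−1
segments of an N-point midline resampled to equal arc-length spacing
(default N = 49 → 48 angles).  Tangent angles are the standard eigenworm
choice: they are one integral away from curvature, make the travelling-wave
algebra exact, and are invariant to translation and (after mean
subtraction) to global rotation.  Angles are unwrapped along the body
before the mean is removed so shapes crossing the ±π seam do not tear.  A
curvature representation (dθ/ds at interior joints) is available through
`RunConfig.representation = "curvature"` for users who prefer it; all
defaults use angles.

Head identity is not resolved — no intensity or behavioral cue is in
scope.  Only frame-to-frame consistency is enforced (`orient_frames`):
each frame keeps either its angle vector or the vector of the midline
traversed from the other end, whichever is closer to the previous retained
frame.  Note the flip transform differs by representation: reversing a
polyline *reverses* its mean-subtracted tangent-angle vector (each segment
angle gains π, absorbed by the mean), whereas signed curvature reverses
*and negates*.  All amplitude statistics are invariant to a global flip.

Re-orientation is applied by default only on the mask path, where the
skeleton's endpoint order is arbitrary.  Midline tables are declared
head-to-tail consistent and are not re-oriented: greedy matching is not a
no-op on them, because a travelling sinusoid is its own head/tail flip at
recurring phases (for integer wavenumber, reversal maps the mode-plane
point (a₁, a₂) to (a₁, −a₂)), and spurious flips would shift the pooled
mean and corrupt the radii.  That same degeneracy means orientation is
genuinely unrecoverable for pure-wave data; the orientation tests
therefore use generic smooth series.

## Eigenmode analysis

The PCA is fitted on the **pooled** frames of every worm in a comparison,
then amplitudes are projected per worm, so both groups live in one mode
plane and their radii are commensurable (per-group bases would not be).
Modes come from the SVD of the centered data matrix; the test suite keeps
an explicit covariance eigendecomposition as an independent oracle.
Determinism choices: eigenvector signs are fixed (largest-magnitude entry
positive, ties by lowest index) and degenerate eigenvalue ties are broken
by index — for noiseless wave data the two leading eigenvalues are equal
and any rotation of the (mode₁, mode₂) plane leaves √(a₁²+a₂²) invariant,
so the tie-break is inert for the statistic.

For a wave θ(sᵢ) = A·cos(2πκsᵢ/L − ωt) sampled at the N segment midpoints
with integer κ, Σᵢcos²(·) = N/2 exactly, giving the per-frame radius
A·√(N/2).  The synthetic generator's N counts tangent samples (its midline
has N+1 points), matching the analysis side's N−1 angles from N points, so
generator N = 48 and analysis N = 49 points describe the same vectors and
the closed form holds exactly.

The joint (a₁, a₂) density is a histogram normalized to parts-per-million
of all points; grid default 51×51 bins spanning ±1.1× the largest |a|.
Points outside an explicit grid are excluded with a logged warning.
Two-mode shapes are reconstructed as θ = r(cos φ·m₁ + sin φ·m₂) + mean,
integrated to unit body length; peak curvature grows monotonically with r,
which is what makes the ring radius legible as bend sharpness.

## Image path

Masks are skeletonized (scikit-image); the midline is the longest
endpoint-to-endpoint geodesic of the 8-connected skeleton graph.  Side
branches shorter than 10 % of that length (config `prune_frac`) are
tolerated as spurs; longer ones mark a coiled or self-intersecting posture
and the frame is dropped and counted rather than fatal, since no coiling
resolution rule is in scope.  The ordered skeleton polyline is smoothed
with a Gaussian along arc length (`smooth_sigma_px`, default 2) before
resampling; at a ≥5 px body width this brings the mean angle error of the
full raster round trip to ≈0.03 rad, well under the 0.05 rad acceptance
bound.  Skeleton endpoints retract ~half a body width from the true tips,
a known small bias of skeleton-based midlines.

## Ant arena statistics

Coordinates are in the arena frame (origin at arena centre, y up, cm).
Zone membership uses the closed disc (boundary inside) — a measure-zero
convention fixed for determinism.  "Total time of the recording" is
interpreted per ant as its frames-present: tracking dropouts leave the
numerator and denominator together, since no interpolation rule is in
scope.  The nearest-neighbour series gives frames with fewer than two
present ants a missing value, never zero; the rolling average (centered,
k = 5 default, k odd) skips missing values and, by default, averages the
partial window at the series edges ("strict" emits NaN there instead).
The difference series inner-joins two smoothed series on timestamps;
positivity means the treated group is more separated.

Antennation is a distance-and-duration proxy (no heading criterion, which
tracked centroids cannot support): an event is a maximal run of
inter-individual distance ≤ d_c (0.5 cm) with dwell ≥ τ (1 s), runs closer
than the refractory gap (0.5 s) merged first.  The thresholds are
conventions exposed in `RunConfig`, not measured values.

## Group comparisons

t-tests are computed from the textbook formulas (scipy supplies the t
distribution) and cross-checked against scipy's own routines to 1e-6 in p.
Welch is the default for the worm radial comparison (variances are not
known equal); Student, paired and one-sided variants cover the occupancy
and antennation designs.  Zero-variance degenerate inputs are flagged and
p resolved by sign convention rather than returned NaN.  Reported
p-values are formatted to 3 significant digits and never as exact zero.
No multiple-testing correction is applied (per-assay tests are reported
unadjusted), noted in the report footer.

For the clustering time series, the mixed model
`nn ~ group + time + group×time` with a random intercept per trial (ML
fit, statsmodels MixedLM; time scaled to [0, 1] per trial for
conditioning) is implemented and reported — but its Wald test assumes
within-trial conditional independence, which positionally autocorrelated
walks violate badly (empirically ~0.6 rejection at α = 0.05 on null
simulations).  The calibrated route, used wherever calibration matters and
offered as the fallback on non-convergence, is an exact trial-label
permutation test: statistic = difference in group means of per-trial OLS
slopes, enumerated over all label assignments (Monte-Carlo above 20,000),
exact under trial exchangeability regardless of autocorrelation.  Its
measured type-I error on null simulations is ≈0.044 at α = 0.05 (slightly
conservative, as the discrete exact p guarantees).

## Synthetic world

The worm generator drives θ(sᵢ, t) = A·cos(2πκsᵢ/L − ωt + φ₀) + ε,
ε ~ N(0, σ²) i.i.d., at segment midpoints, integrated to a midline of
exactly conserved arc length.  Defaults describe a crawling adult: L = 1
cm, one wavelength on the body (κ = 1), 0.5 Hz undulation (ω = π rad/s),
20 Hz video for 60 s, N = 48 segments.  At these defaults frames cover
whole wave periods, so the pooled mean posture vanishes and the ring is
numerically exact.  The generator emulates amplitude, wavelength,
frequency and angle noise; it does **not** emulate omega turns, reversals,
pauses, head-swing asymmetry or tracking noise in midline position — a
green recovery test establishes the pipeline's algebra, not robustness to
those behaviors (coiled-frame dropping is tested separately with grafted
spurs).

The ant generator is a Gaussian random walk (step SD 0.3 cm per 0.5 s
step, ~0.6 cm/s) in a 9 cm circular arena, reflected at the boundary by
radial mirroring (r → 2R − r), which preserves a near-uniform stationary
distribution for small steps — the baseline the occupancy calibration
(zone/arena area ratio 16/81) relies on.  Optional drifts: λ cm/step away
from the zone centre inside a shell of 1.5× the zone radius (any monotone
repulsion suffices for recovery tests; the shell factor is a convention),
and g cm/step toward the centroid of the other ants.  Durations, arena
size and ant number are conventions (10 ants, 10 min) since no recording
parameters are in scope; everything is configurable.  The generator does
not emulate identity swaps, wall-following, gaster-dragging or pheromone
fields.  The antennation dyad generator places two ants on a programmed
contact schedule so event counts have a known truth.

## Numerical and I/O choices

Sampling-interval uniformity tolerance 1e-6 s.  The trajectory reader is
strict about per-individual frame gaps by default (a gap is a sampling
error naming the offending frames) with `allow_gaps=True` for real tracker
exports, where times must still sit on the uniform Δt grid.  Nearest-
neighbour distances are computed with the explicit √(Δx²+Δy²) formula so
results match a brute-force enumeration bit-for-bit (no BLAS shortcut
reformulations).  Tabular outputs are written with fixed column order and
floats at 9 significant digits, so identical inputs give byte-identical
files; JSON outputs embed the config echo and package version.  Config
files are read from TOML (stdlib) and round-tripped losslessly via JSON.

## Known limitations

* Head/tail semantic assignment is out of scope; statistics are
  flip-invariant but mode signs are only determined up to the global flip.
* Skeleton-based midlines lose the body tips (~half body width) and cannot
  represent self-occluding postures; such frames are dropped, biasing
  against strongly coiled behavior if it correlates with treatment.
* The permutation test needs enough trials per group for useful power
  (5 vs 5 gives a minimum two-sided p of 2/252); the LMM is more powerful
  but anticonservative on autocorrelated series, as quantified above.
* Occupancy near-uniformity of the reflected walk holds for steps small
  relative to the arena; large steps bias the boundary region.
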