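# Methods

`drwpicp` aligns a noisy "floating" surface capture (e.g., a depth-sensor
scan of a patient's head) to a fixed "reference" model (e.g., a CT-derived
surface) with a strictly rigid transform. The pipeline has two halves:
cleaning the floating data (statistical outlier removal, then
moving-least-squares smoothing and fusion of two captures), and a robust
iterative-closest-point loop (trimmed-mean scale estimation, per-pair
weighting, closed-form weighted rigid fits with a line search, and a
perturbation mechanism that jumps out of local minima). This note records
the model, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Rigid registration model

A pose is a 4x4 homogeneous matrix `T` with orthonormal rotation block
(det +1) and translation column; no scaling or deformation is ever
introduced, so all pairwise distances are preserved. The registration
objective is the root-mean-square distance from each transformed floating
point to its nearest reference point,

    RMS(T) = sqrt( mean_i  || nearest_R(T f_i) - T f_i ||^2 ).

Given fixed correspondences and nonnegative per-pair weights, the optimal
rigid transform minimizing `sum_i w_i ||T f_i - r_i||^2` is computed in
closed form by the weighted Kabsch construction (SVD of the weighted
cross-covariance, with the sign of the smallest singular vector corrected so
a reflection is never returned). Iterative least squares would converge to
the same optimum; the closed form is exact and cheaper.

Nearest-neighbour queries run on a k-d tree; exact ties are broken toward
the lowest reference id so that every run is reproducible bit for bit.

## Denoising (statistical outlier removal)

For each point the mean distance `dbar_i` to its `k` nearest neighbours is
computed (default `k = 50`). Treating the `dbar` values as roughly Gaussian
for true surface points, the threshold

    d_max = mu + alpha * sigma

uses the mean and **population** standard deviation of all `dbar` values
(default `alpha = 1.0`); points with `dbar_i > d_max` (strictly greater) are
removed. One pass is blind to heavy contamination: when outliers are a
large fraction of the cloud they inflate `mu` and `sigma` and shield one
another. The fusion pipeline therefore re-applies the filter, re-estimating
the threshold on the survivors, `passes = 3` times by default; at 55%
contamination this takes the residual outlier fraction from roughly 45% to
roughly 22% without eating into the surface, while on clean clouds the
extra passes only shave the sparse tail of the sampling distribution.
`remove_outliers` itself is always a single pass, and a single threshold is
applied to the pooled distribution (not per-point z-scores).

## Resampling (normals + moving least squares)

Per-point normals come from the eigenvector with the smallest eigenvalue of
the local covariance of the `knn_for_normals = 30` nearest neighbours, and
are flipped so they point toward the sensor viewpoint (default `(0,0,0)`,
configurable): `n . (viewpoint - p) >= 0`.

MLS projection replaces each point by its height on a local polynomial fit:
neighbours within `search_radius` (default 4x the median nearest-neighbour
spacing — density-adaptive) are expressed in a frame whose height axis is
the point's normal; a bivariate polynomial of total degree `poly_order = 2`
is fitted by least squares with Gaussian weights `exp(-d^2/r^2)` (a standard
smooth, compactly-concentrated kernel); the point moves to the fitted height
at its own footprint. Points with fewer neighbours than polynomial
coefficients pass through unmodified and are flagged. Resampling is
realized as projection of existing points plus uniform random subsampling
to a target count (default: the mean of the two capture sizes); no new
points are synthesized inside holes. Exact planes are reproduced to 1e-9
at any order; gently curved exact quadratics to 1e-6 at order 2 (the local
frame is tilted by the estimated normal, so reproduction of curved surfaces
is exact only up to the frame's reparametrization error — negligible at the
curvatures used here).

Two captures of the same surface are fused by denoising each, pooling the
survivors, then smoothing and subsampling the pooled set; averaging two
independent noise realizations through the MLS kernel is what makes the
fused set `F` cleaner than either input.

## The alignment loop

Each iteration, starting from the current pose `T`:

1. **Correspond**: match every floating point to its nearest reference
   point; many-to-one matches are allowed.
2. **Scale**: the trimmed mean `a_mean` of the match distances — the mean of
   the `N_B - N_C` smallest, with `N_C = floor(trim_fraction * N_B)`
   (default `trim_fraction = 0.1`) — is a robust estimate of the current
   alignment scale that ignores the worst matches.
3. **Weights**: `w_i = d_i^t / a_mean` for `d_i` below a cutoff, else 0,
   then normalized to sum 1 (default exponent `t = 1`). The cutoff is
   `cutoff_scale * a_mean` with `cutoff_scale = 3` by default: cutting at
   `a_mean` itself (available as `cutoff_scale = 1`, and the default of the
   standalone `assign_weights`) discards the far half of the
   correspondences — precisely the pairs that carry the coarse-alignment
   signal — and measurably traps the search in partial-overlap minima
   (10-25 degrees of residual rotation on clean scenes), while `3 a_mean`
   keeps genuine surface points and still zeroes gross outliers. An
   `inverse` mode (`w = 1 - d/cutoff`) and a `uniform` mode (weights off)
   are provided.
4. **Fit + line search**: the weighted Kabsch fit gives a candidate `T'`;
   the RMS is evaluated along the path from `T` to `T'` (rotation
   interpolated geodesically in axis-angle, translation linearly) at step
   fractions `lambda in {1, 1/2, 1/4, 1/8}` and the best wins. The dyadic
   grid is cheap and, because `lambda` is chosen by explicit RMS
   evaluation, can never make an accepted step worse than the full step.
5. **Accept**: a candidate is recorded as the new best only if its RMS
   beats the best seen so far, so the accepted-RMS trace is non-increasing
   by construction. The descent itself proceeds on a separate "current"
   track so a perturbed restart can explore uphill before it beats the
   best.
6. **Stop / perturb**: the loop stops when the best RMS falls below
   `rms_tol` (default 1e-3 x the reference bounding-box diagonal) or the
   iteration budget is spent (`max_iterations = 200` — sized so the slowest
   legitimately converging descents on in-scope poses are not truncated).
   When a descent stalls above the tolerance and restarts remain
   (`max_restarts = 30`), the best transform is perturbed and iteration
   continues. Stall detection is two-tier: a track whose RMS is within 5%
   of the best-so-far stalls on the absolute `min_improvement` threshold
   (default 1e-6 x diagonal — full polish, because on hard instances the
   competing basins differ by only 1-5% in RMS), while a track still far
   above the best stalls once its per-iteration improvement drops below
   `stall_ratio = 0.5%` of its RMS, so a hopeless basin's slow crawl
   cannot absorb the whole budget. An `eager` flag instead perturbs after
   every accepted improvement (the literal flowchart reading).

### Perturbation

The search range is `r = |T_init - T_best|`, the elementwise absolute
difference of the initial and best homogeneous matrices: the less progress
the search has made from its starting pose, the wider the region worth
exploring. Sampling raw 4x4 entries would leave the rigid manifold, so `r`
collapses to six degrees of freedom: three translation deltas (the
translation column of `r`) and one rotation magnitude, recovered from the
rotation block via the identity `||R1 - R2||_F^2 = 4 (1 - cos delta)`
(elementwise absolute value preserves the Frobenius norm, so the relative
angle is recoverable from `r` alone). Each DOF draws a magnitude from the
density proportional to `theta^2` on `(-scale*r, +scale*r)`, normalized to
`p(theta) = 3 theta^2 / (2 (scale*r)^3)` and sampled by inverse CDF
(`theta = scale*r * cbrt(2u - 1)`); the quadratic shape pushes mass toward
the edges of the support, favouring jumps large enough to leave the current
basin. `scale` (default 1.0) widens the support when the range itself is
too narrow to escape; because the achieved range `|T_init - T_best|`
underestimates the distance to the true basin precisely when the search is
stuck near its starting pose, the effective scale escalates geometrically
(x2 per restart that fails to improve the best RMS at the basin level,
capped at 16x). Each restart draws `n_probes = 10` candidate perturbations
and descends only from the most promising one; probes are ranked by a
trimmed RMS (worst 30% of matches excluded), which separates basins far
better than the plain RMS when residual outliers contribute a large
constant term. The rotation draw is applied about a random axis and the
result re-orthonormalized by projection, so the output is always exactly
rigid. With perturbation enabled the iteration budget is split in half: an
exploration phase in which each track may spend at most
`explore_patience = 25` iterations (tracks within 5% of the best are
exempt — they are candidate winners), and a polish phase that refines the
final best transform on the absolute threshold, so a descent interrupted
by the cap is finished rather than lost. All randomness flows from one
seeded generator.

The plain baseline (`vanilla_icp`) is an independently coded loop with
every robust feature off — unweighted fits, full steps, no trimming, no
perturbation — and is reproduced bitwise by the robust loop when its
features are disabled, which pins down that the robust machinery is purely
additive.

## Synthetic scenes

The generator emulates a head-registration study at desk scale. The
reference surface is an ellipsoid (semi-axes 70/90/110 length units — about
a 220-unit head, read as millimetres) with a nose-like Gaussian bump, two
unequal eye depressions, and a broad oblique bulge. The features remove
mirror symmetry; the bulge removes the half-turn symmetries of the bare
ellipsoid, so no non-identity rotation maps the surface near itself and the
registration optimum is unique. Five fiducial markers sit at fixed surface
landmarks (nose tip, both eyes, forehead, chin); registration quality is
scored as the mean Euclidean error of the five markers after mapping them
through the recovered transform — the evaluation metric the benchmark
reports — with the full-cloud RMS also available.

Floating captures are degraded in this order: uniform subsampling to
`keep_fraction`; additive per-coordinate Gaussian noise of variance
`noise_variance` (the 1-D noise model applied isotropically, as the 3-D
covariance is a free choice); `n_outliers` uniform points in the
1.5x-expanded bounding box (the outlier-generation law is likewise a free
choice here). Default scene size is 5,000 points per cloud — large enough
that marker errors are sampling-stable, small enough for laptop-scale runs;
the full ~48.6k capture scale is reachable by config, and grid outlier
counts quoted at that scale are rescaled proportionally to the scene size.
Each floating capture is an independent sampling of the surface by default;
`resample_floating=False` reuses the reference samples, which is the
setting where "no degradation implies exact recovery" is well-posed (with
independent 5k-point samplings the point-to-point RMS valley is flat at the
~4-unit sampling spacing, and sub-half-degree agreement is decided by
sampling chance rather than by the algorithm).

What the scenes do **not** model: structured depth-sensor noise (axial /
lateral error profiles), occlusion holes, partial overlap between capture
and model, non-rigid soft-tissue motion, and CT segmentation artifacts.
Passing the benchmark therefore shows robustness to the modelled
degradations only.

## Benchmark protocol

For each degradation level and seed, a scene is built and every method
starts from the same random pose (rotation angle uniform on
[0, 180 degrees], translation uniform in a ball of radius 0.5 x the
bounding-box diagonal — both configurable); the mean 5-marker error is
recorded and aggregated as mean/min/max per condition, with wall time
reported but never asserted (hardware-bound). The combined worst condition
(maximum sparsity + noise + outliers simultaneously) is always included.
Five repeats per condition by default.

Degradation *trends* (how the error responds as one axis worsens) are
measured under conditions chosen so the effect is actually resolvable:
exact-overlap scenes, gentle starts (rotation up to 30 degrees,
translation up to 0.15 diagonal) and a near-zero RMS tolerance — under
wild starts the run-to-run variance of basin selection (several units)
swamps the sub-unit degradation effects, and the default tolerance stop
quantizes small errors. Two further consequences of the pipeline's own
effectiveness shape the protocol: at full density the iterated filter
removes the injected box outliers completely, leaving a flat response at
machine resolution, so the outlier axis is measured on a 10%-sparsity base
where contamination (11% to 55%) genuinely leaks through; and because a
rare basin failure (an error of 10-20 units in one run out of ten) would
dominate a mean in either direction, trends are compared by median and by
the fraction of paired seeds that degrade.

## Known limitations

- Point-to-point distances only; a point-to-plane metric would converge
  faster on smooth surfaces but is out of scope.
- The perturbation range collapses the 4x4 matrix difference to six DOF
  magnitudes; directional information in the translation column's signs is
  deliberately discarded (the density is symmetric).
- MLS passes isolated points through unmodified rather than rejecting them;
  heavy residual contamination after denoising therefore survives into the
  alignment stage, where trimming and the weight cutoff must absorb it.
- At high outlier fractions (>50%) the statistical filter's threshold is
  itself outlier-driven; iterated passes mitigate but do not eliminate
  this.
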