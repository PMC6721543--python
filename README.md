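# drwpicp

Robust rigid registration of 3D point-cloud surfaces, built for
surface-guided alignment problems in image-guided interventions: a noisy,
outlier-ridden "floating" capture of a patient's surface (e.g., from an
RGB-D sensor) must be aligned to a clean "reference" model (e.g., a
CT-derived head surface) with a strictly rigid transform, reliably, even
from a bad starting pose.

Plain iterative-closest-point (ICP) fails in exactly these conditions: it
needs a good initial pose, and noise or outliers corrupt its least-squares
fits. `drwpicp` implements a denoised, resampled, weighted and perturbed
ICP variant that addresses all three failure modes:

1. **Denoise** — statistical outlier removal: a point is dropped when its
   mean distance to its k nearest neighbours exceeds
   `d_max = μ + α·σ`, where μ, σ are the mean and standard deviation of
   that quantity over the cloud (defaults `k = 50`, `α = 1`).
2. **Resample** — per-point normals from local PCA (oriented toward the
   sensor viewpoint), then moving-least-squares smoothing: each point is
   projected onto a Gaussian-weighted local quadratic fit of its
   neighbourhood; two captures of the same surface are fused into one
   cleaner floating set `F`.
3. **Weight** — each ICP iteration matches every floating point to its
   nearest reference point, computes the trimmed mean `ᾱ` of the match
   distances `d_i` (worst 10% excluded), and fits the rigid transform by
   weighted closed-form least squares (Kabsch SVD) with weights
   `w_i = d_i^t / ᾱ` below a cutoff and 0 beyond it; a line search over
   step fractions λ ∈ {1, ½, ¼, ⅛} keeps every accepted step an RMS
   improvement.
4. **Perturb** — when progress stalls above tolerance, the best transform
   is jittered within the range `r = |T_init − T_best|`, with each degree
   of freedom drawn from the density `p(θ) ∝ θ²` on `(−αr, +αr)` — mass
   concentrated near the edges, favouring jumps that leave the current
   basin — and descent continues; the best-so-far transform is never lost.

The objective is the root-mean-square nearest-point distance; registration
quality on synthetic benchmarks is scored as the mean error of five
fiducial surface markers mapped through the recovered transform.

See `docs/methods.md` for the full model, parameter defaults, and the
synthetic-scene generator.

## Worked example

Generate a synthetic head scene (5,000-point reference surface, a
ground-truth pose 25° away, two degraded sensor captures with noise and
outliers), then register:

```python
import numpy as np
from drwpicp import SceneSpec, make_scene, register_captures, marker_error
from drwpicp.synthdata import random_rigid_transform

truth = random_rigid_transform(np.random.default_rng(7), np.deg2rad(25), 60.0)
scene = make_scene(SceneSpec(n_points=5000, noise_variance=2.0,
                             n_outliers=300, rng_seed=1,
                             true_transform=truth))
result, fused = register_captures(scene.floating_1, scene.reference,
                                  scene.floating_2)
delta = result.transform.compose(truth)
print(f"converged: {result.reason} after {result.iterations} iterations, "
      f"{result.restarts_used} restarts")
print(f"rotation error: {np.degrees(delta.rotation_angle()):.3f} deg")
print(f"marker error:   {marker_error(result.transform, scene.markers_true_floating, scene.markers_reference):.3f} units")
```

Output:

```
converged: max_iter after 140 iterations, 4 restarts
rotation error: 1.816 deg
marker error:   2.607 units
```

The recovered pose is within two degrees of the truth and the five
fiducial markers land within ~3 length units (read: millimetres) of their
true positions, despite the variance-2 noise on two independently sampled
5,000-point captures and the 300 injected outliers — close to the sampling
floor of clouds this sparse. The same run
with `vanilla_icp` (no denoising, weighting or perturbation) is the
baseline the benchmark compares against.

The same pipeline is scriptable from the shell:

```sh
drwpicp simulate --spec scene.json --outdir scene/
drwpicp denoise --in scene/floating1.ply --out clean.ply --k 50 --alpha 1.0
drwpicp register --floating scene/floating1.ply --floating2 scene/floating2.ply \
                 --reference scene/reference.ply --out T.txt
drwpicp benchmark --out report.csv
```

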