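"""The DRWP-ICP alignment loop.

Each iteration matches every floating point to its nearest reference point,
computes a trimmed mean of the match distances, assigns per-pair weights,
fits the weighted rigid transform in closed form, and line-searches along
the path from the current transform to the fitted one. A candidate is
accepted only if it lowers the best RMS seen so far, so the accepted-RMS
trace is non-increasing by construction. When progress stalls above the RMS
tolerance and restarts remain, the best transform is perturbed within the
range spanned by the initial and converged transforms — the perturbation
magnitude is drawn from a theta^2-shaped density, which favours large jumps
able to escape the current basin — and iteration continues from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DegenerateError,
    NeighborIndex,
    PointCloud,
    RigidTransform,
    RmsTrace,
    _rotation_from_axis_angle,
    build_neighbor_index,
    estimate_rigid_transform,
    rms_error,
    rotation_to_axis_angle,
)


class NoInliersError(DegenerateError):
    """All correspondence weights vanished — nothing to fit."""


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightParams:
    """Robust-weighting configuration.

    trim_fraction: fraction of the worst (largest-distance) correspondences
        excluded from the trimmed mean.
    t_exponent: exponent t in the weight rule w = d^t / a_mean.
    mode: "literal" (w = d^t / a_mean below the cutoff, else 0),
          "inverse" (w = 1 - d / (cutoff_scale * a_mean) below it, else 0), or
          "uniform" (weighting disabled — plain ICP fit).
    cutoff_scale: weights vanish for d >= cutoff_scale * a_mean. The strict
        reading of the weight rule cuts at a_mean itself (cutoff_scale = 1),
        but that discards the far half of the correspondences — exactly the
        pairs carrying the coarse-alignment signal — and traps the search in
        partial-overlap minima; 3x the trimmed mean keeps genuine surface
        points while still zeroing gross outliers.
    """

    trim_fraction: float = 0.1
    t_exponent: float = 1.0
    mode: str = "literal"
    cutoff_scale: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_fraction < 1.0):
            raise ValueError("trim_fraction must be in [0, 1)")
        if self.mode not in ("literal", "inverse", "uniform"):
            raise ValueError("mode must be literal, inverse or uniform")
        if self.cutoff_scale <= 0:
            raise ValueError("cutoff_scale must be positive")


@dataclass(frozen=True)
class PerturbParams:
    """Local-minimum escape configuration.

    scale: support-widening factor; the perturbation of each degree of
        freedom is drawn from (-scale*r, +scale*r) where r is that DOF's
        magnitude of the initial-to-converged transform difference. When
        consecutive restarts fail to improve the best RMS the effective
        scale escalates geometrically (x2 per fruitless restart, capped
        at 16x): the achieved range |T_init - T_best| underestimates the
        distance to the true basin whenever the search is stuck in a
        spurious minimum close to its starting pose.
    max_restarts: perturbation budget; 0 disables escape entirely.
    n_probes: candidate perturbations drawn per restart; each costs one RMS
        evaluation and the best one seeds the next descent, so a restart
        lands in a promising basin far more often than a single blind draw.
    eager: if True, jump to perturbation after every accepted improvement
        (the literal flowchart reading) instead of only at stalls.
    """

    scale: float = 1.0
    max_restarts: int = 30
    rng_seed: int = 0
    n_probes: int = 10
    eager: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.max_restarts < 0:
            raise ValueError("max_restarts must be >= 0")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")


@dataclass(frozen=True)
class StopParams:
    """Termination rules. ``rms_tol`` and ``min_improvement`` default to
    1e-3 and 1e-6 times the reference bounding-box diagonal.

    Tracks whose RMS is within 5% of the best-so-far stall on the absolute
    ``min_improvement`` threshold (full polish — on hard instances the
    competing basins differ by only 1-5% in RMS, so a near-best track may
    be descending into a marginally better basin). An exploration track
    still far above the best stalls when its improvement falls below
    max(min_improvement, stall_ratio * its current RMS): a hopeless basin
    can sustain a long "crawl" of slow improvements that never trips an
    absolute threshold and would starve the perturbation search of its
    iteration budget.

    ``explore_patience`` caps the iterations any single exploration track
    may consume (again excepting near-best tracks): wrong-basin descents
    can sustain slow but above-threshold progress for a hundred or more
    iterations, and without the cap the first such crawl absorbs the whole
    exploration budget. Interrupted tracks are not lost — whichever pose
    leads at the end of exploration is refined to the absolute threshold
    in the polish phase, which holds the second half of the iteration
    budget.
    """

    rms_tol: float | None = None
    max_iterations: int = 200
    min_improvement: float | None = None
    stall_ratio: float = 5e-3
    explore_patience: int = 25

    def __post_init__(self) -> None:
        if self.rms_tol is not None and self.rms_tol <= 0:
            raise ValueError("rms_tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_improvement is not None and self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")
        if self.stall_ratio < 0:
            raise ValueError("stall_ratio must be >= 0")

    def resolved(self, diagonal: float) -> tuple[float, float]:
        tol = self.rms_tol if self.rms_tol is not None else 1e-3 * diagonal
        imp = (self.min_improvement if self.min_improvement is not None
               else 1e-6 * diagonal)
        return tol, imp


@dataclass
class CorrespondenceSet:
    """Matched floating/reference pairs with distances and weights."""

    pairs: np.ndarray            # (n, 2) array of (floating id, reference id)
    distances: np.ndarray        # per-pair Euclidean distance
    ref_positions: np.ndarray    # positional indices into the reference cloud
    weights: np.ndarray | None = None


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_trace: RmsTrace
    iterations: int
    restarts_used: int
    converged: bool
    reason: str                  # "tolerance" | "max_iter" | "stalled"


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def correspond(floating: PointCloud, ref_index: NeighborIndex,
               t: RigidTransform) -> CorrespondenceSet:
    """One nearest-reference match per floating point under transform t.

    Many floating points may share a reference point; the weighting stage
    compensates. Ties go to the lowest reference id.
    """
    if len(floating) == 0 or len(ref_index) == 0:
        raise DegenerateError("empty input to correspondence search")
    mapped = t.transform_points(floating.points)
    d, pos = ref_index.nearest(mapped)
    pairs = np.column_stack([floating.ids, ref_index.cloud.ids[pos]])
    return CorrespondenceSet(pairs=pairs, distances=d, ref_positions=pos)


def trimmed_mean_distance(distances: np.ndarray, trim_fraction: float) -> float:
    """Mean of the N_B - N_C smallest distances, N_C = floor(f * N_B)."""
    d = np.sort(np.asarray(distances, float))
    n_b = len(d)
    if n_b == 0:
        raise DegenerateError("no distances to average")
    n_c = int(np.floor(trim_fraction * n_b))
    if n_c >= n_b:
        raise DegenerateError("all correspondences excluded by trimming")
    return float(d[: n_b - n_c].mean())


def assign_weights(distances: np.ndarray, alpha_mean: float,
                   t_exponent: float = 1.0, mode: str = "literal",
                   cutoff_scale: float = 1.0) -> np.ndarray:
    """Per-pair weights from distances and the trimmed mean alpha_mean.

    literal: w = d^t / alpha_mean for d < cutoff_scale * alpha_mean, else 0.
    inverse: w = 1 - d / (cutoff_scale * alpha_mean) below the cutoff, else 0.

    The default cutoff is alpha_mean itself; the alignment loop widens it
    (see :class:`WeightParams`). The nonzero weights are normalized to sum 1.
    Raises :class:`NoInliersError` when every weight vanishes.
    """
    if alpha_mean <= 0:
        raise ValueError("alpha_mean must be positive")
    d = np.asarray(distances, float)
    cutoff = cutoff_scale * alpha_mean
    inlier = d < cutoff
    w = np.zeros_like(d)
    if mode == "literal":
        w[inlier] = d[inlier] ** t_exponent / alpha_mean
    elif mode == "inverse":
        w[inlier] = 1.0 - d[inlier] / cutoff
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    total = w.sum()
    if total <= 0:
        raise NoInliersError("no inliers: all correspondence weights are zero")
    return w / total


def _interpolate(t_from: RigidTransform, t_to: RigidTransform,
                 lam: float) -> RigidTransform:
    """Geodesic interpolation in rotation, linear in translation."""
    delta = t_to.rotation @ t_from.rotation.T
    rotvec = rotation_to_axis_angle(delta)
    rot = _rotation_from_axis_angle(lam * rotvec) @ t_from.rotation
    trans = (1.0 - lam) * t_from.translation + lam * t_to.translation
    return RigidTransform.from_rotation_translation(rot, trans)


DEFAULT_LAMBDAS = (1.0, 0.5, 0.25, 0.125)


def line_search_step(floating: PointCloud, ref_index: NeighborIndex,
                     t_current: RigidTransform, corr: CorrespondenceSet,
                     lambdas=DEFAULT_LAMBDAS) -> tuple[RigidTransform, float]:
    """Fit the (weighted) rigid candidate, then pick the step fraction.

    The candidate transform T' is evaluated at each lambda along the path
    from ``t_current`` (rotation interpolated in axis-angle, translation
    linearly); the lambda with the lowest RMS wins. Requires >= 3 nonzero
    weights; degenerate fits propagate as :class:`DegenerateError`.
    """
    weights = corr.weights
    if weights is not None and np.count_nonzero(weights) < 3:
        raise DegenerateError("fewer than 3 nonzero correspondence weights")
    dst = ref_index.cloud.points[corr.ref_positions]
    candidate = estimate_rigid_transform(floating.points, dst, weights)
    best_t, best_rms = None, np.inf
    for lam in lambdas:
        t_lam = candidate if lam == 1.0 else _interpolate(t_current, candidate, lam)
        r = rms_error(floating, ref_index, t_lam)
        if r < best_rms:
            best_t, best_rms = t_lam, r
    return best_t, best_rms


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def perturbation_range(t_init: RigidTransform,
                       t_temp: RigidTransform) -> np.ndarray:
    """Elementwise |T_init - T_temp|: the 4x4 search range for perturbation."""
    return np.abs(t_init.matrix - t_temp.matrix)


def sample_perturbation(r_magnitude: float, scale: float,
                        rng: np.random.Generator) -> float:
    """Draw theta from the density proportional to theta^2 on
    (-scale*r, +scale*r), i.e. p(theta) = 3 theta^2 / (2 (scale*r)^3).

    Inverse-CDF sampling: theta = scale*r * cbrt(2u - 1) with u ~ U(0, 1).
    The quadratic shape concentrates mass near the edges of the support, so
    perturbations tend to be large enough to leave the current basin.
    Returns 0 when the range is empty (r = 0).
    """
    if r_magnitude < 0:
        raise ValueError("r_magnitude must be >= 0")
    if r_magnitude == 0:
        return 0.0
    u = rng.uniform()
    return float(scale * r_magnitude * np.cbrt(2.0 * u - 1.0))


def _rotation_magnitude_from_range(r: np.ndarray) -> float:
    """Relative-rotation angle encoded in the absolute-difference matrix r.

    For rotations R1, R2: ||R1 - R2||_F^2 = 4 (1 - cos delta), and the
    elementwise absolute value preserves the Frobenius norm, so the angle is
    recoverable from r's rotation block alone.
    """
    f2 = float(np.sum(r[:3, :3] ** 2))
    return float(np.arccos(np.clip(1.0 - f2 / 4.0, -1.0, 1.0)))


def perturb_transform(t_temp: RigidTransform, r: np.ndarray,
                      params: PerturbParams,
                      rng: np.random.Generator) -> RigidTransform:
    """Compose a random small rigid motion, bounded by the range r, with
    ``t_temp``.

    The 4x4 range collapses to six degrees of freedom: one rotation-angle
    magnitude (from the rotation block of r) and three translation deltas
    (the translation column of r). One theta is drawn per DOF; the rotation
    theta is applied about a random axis. The result is re-orthonormalized
    by projection so it always satisfies the rigidity invariants.
    """
    rot_mag = _rotation_magnitude_from_range(r)
    theta_rot = sample_perturbation(rot_mag, params.scale, rng)
    axis = rng.standard_normal(3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    theta_trans = np.array([
        sample_perturbation(float(r[i, 3]), params.scale, rng)
        for i in range(3)
    ])
    delta = RigidTransform.from_rotation_translation(
        _rotation_from_axis_angle(axis * theta_rot), theta_trans)
    return delta.compose(t_temp)


# ---------------------------------------------------------------------------
# Full algorithms
# ---------------------------------------------------------------------------

def drwp_icp(floating: PointCloud, reference: PointCloud,
             t_init: RigidTransform | None = None,
             weight: WeightParams = WeightParams(),
             stop: StopParams = StopParams(),
             perturb: PerturbParams = PerturbParams(),
             lambdas=DEFAULT_LAMBDAS,
             rng: np.random.Generator | None = None,
             log=None) -> RegistrationResult:
    """Weighted, line-searched ICP with perturbation escape.

    ``floating`` is assumed to be already denoised/resampled (see
    :func:`drwpicp.pipeline.register_captures` for the full pipeline).
    The returned transform maps floating coordinates onto the reference.
    """
    if len(floating) == 0 or len(reference) == 0:
        raise DegenerateError("empty input cloud")
    if t_init is None:
        t_init = RigidTransform.identity()
    if rng is None:
        rng = np.random.default_rng(perturb.rng_seed)

    ref_index = build_neighbor_index(reference)
    rms_tol, min_improvement = stop.resolved(reference.bounding_box_diagonal())

    t_best = t_init
    best_rms = rms_error(floating, ref_index, t_init)
    trace = RmsTrace([best_rms])
    # the current descent track: equals the best track until a perturbation
    # moves it elsewhere, after which it descends locally and feeds the best
    # track only when it actually beats it
    t_current, current_rms = t_init, best_rms
    iterations = 0
    restarts = 0
    fruitless = 0  # consecutive restarts without a new global best

    # With perturbation enabled the run has two phases: an exploration phase
    # in which every descent (including the first) stalls on the *relative*
    # threshold — a wrong basin can sustain a slow crawl that would otherwise
    # starve the restarts of iterations — and a reserved polish phase that
    # refines the best transform to the absolute threshold.
    perturbing = perturb.max_restarts > 0
    explore_cap = stop.max_iterations // 2 if perturbing else \
        stop.max_iterations
    reason = None
    track_iters = 0  # iterations spent on the current track

    def step(t_from):
        """One ICP iteration from t_from: (candidate, candidate RMS)."""
        try:
            corr = correspond(floating, ref_index, t_from)
            if weight.mode != "uniform":
                alpha_mean = trimmed_mean_distance(corr.distances,
                                                   weight.trim_fraction)
                corr.weights = assign_weights(corr.distances, alpha_mean,
                                              weight.t_exponent, weight.mode,
                                              weight.cutoff_scale)
            return line_search_step(floating, ref_index, t_from, corr,
                                    lambdas)
        except DegenerateError:
            return None, np.inf

    while reason is None:
        if best_rms < rms_tol:
            return RegistrationResult(t_best, trace, iterations, restarts,
                                      True, "tolerance")
        if iterations >= explore_cap:
            reason = "max_iter"
            break
        iterations += 1
        candidate, cand_rms = step(t_current)

        track_iters += 1
        threshold = min_improvement
        # the band is strictly above the best: a near-best *explorer* is a
        # candidate winner and polishes freely, while the best track's own
        # slow crawl is interruptible — the polish phase will finish it
        near_best = best_rms < current_rms < 1.05 * best_rms
        if perturbing and not near_best:
            threshold = max(threshold, stop.stall_ratio * current_rms)
        stalled = (candidate is None
                   or cand_rms > current_rms - threshold)
        if (perturbing and not near_best
                and track_iters >= stop.explore_patience):
            stalled = True
        accepted = candidate is not None and cand_rms < best_rms
        if candidate is not None and cand_rms < current_rms:
            t_current, current_rms = candidate, cand_rms
        if accepted:
            # only a basin-level improvement resets the escalation: tiny
            # polish gains inside the current basin are not evidence that
            # the perturbation range is wide enough
            if best_rms - cand_rms >= 0.05 * best_rms:
                fruitless = 0
            t_best, best_rms = candidate, cand_rms
            trace.append(best_rms)
        if log is not None:
            log(iteration=iterations, rms=best_rms, accepted=accepted,
                restarts=restarts)

        want_perturb = stalled or (accepted and perturb.eager)
        if want_perturb and best_rms >= rms_tol:
            if restarts < perturb.max_restarts:
                restarts += 1
                r = perturbation_range(t_init, t_best)
                widened = replace(perturb, scale=min(
                    perturb.scale * 2.0 ** fruitless, 16.0 * perturb.scale))
                fruitless += 1
                # best-of-n_probes screening; probes are ranked by trimmed
                # RMS (worst 30% of matches excluded), which separates
                # basins far better than the plain RMS when outliers
                # contribute a large constant term
                t_current, best_score = None, np.inf
                for _ in range(perturb.n_probes):
                    probe = perturb_transform(t_best, r, widened, rng)
                    mapped = probe.transform_points(floating.points)
                    d, _ = ref_index._tree.query(mapped, k=1)
                    d2 = np.sort(d ** 2)
                    score = float(np.sqrt(np.mean(
                        d2[: max(3, int(0.7 * len(d2)))])))
                    if score < best_score:
                        t_current, best_score = probe, score
                current_rms = rms_error(floating, ref_index, t_current)
                track_iters = 0
            elif stalled:
                reason = "stalled"
                break

    # polish phase: absolute-threshold refinement of the best transform
    # (part of the perturbation machinery's budget split; with perturbation
    # disabled the loop above already ran to the absolute threshold)
    converged = False
    while perturbing and iterations < stop.max_iterations and \
            best_rms >= rms_tol:
        iterations += 1
        candidate, cand_rms = step(t_best)
        accepted = candidate is not None and cand_rms < best_rms
        if accepted:
            improvement = best_rms - cand_rms
            t_best, best_rms = candidate, cand_rms
            trace.append(best_rms)
        if log is not None:
            log(iteration=iterations, rms=best_rms, accepted=accepted,
                restarts=restarts)
        if not accepted or improvement < min_improvement:
            break
    if best_rms < rms_tol:
        converged, reason = True, "tolerance"
    return RegistrationResult(t_best, trace, iterations, restarts,
                              converged, reason)


def vanilla_icp(floating: PointCloud, reference: PointCloud,
                t_init: RigidTransform | None = None,
                stop: StopParams = StopParams(),
                log=None) -> RegistrationResult:
    """Plain point-to-point ICP baseline: unweighted fit, full step, no
    trimming, no perturbation. Accepts an update only when it improves the
    best RMS, mirroring the robust loop with every feature disabled."""
    if len(floating) == 0 or len(reference) == 0:
        raise DegenerateError("empty input cloud")
    if t_init is None:
        t_init = RigidTransform.identity()
    ref_index = build_neighbor_index(reference)
    rms_tol, min_improvement = stop.resolved(reference.bounding_box_diagonal())

    t_best = t_init
    best_rms = rms_error(floating, ref_index, t_init)
    trace = RmsTrace([best_rms])
    t_current = t_init
    iterations = 0
    while True:
        if best_rms < rms_tol:
            return RegistrationResult(t_best, trace, iterations, 0,
                                      True, "tolerance")
        if iterations >= stop.max_iterations:
            return RegistrationResult(t_best, trace, iterations, 0,
                                      False, "max_iter")
        iterations += 1
        try:
            corr = correspond(floating, ref_index, t_current)
            dst = ref_index.cloud.points[corr.ref_positions]
            candidate = estimate_rigid_transform(floating.points, dst, None)
            cand_rms = rms_error(floating, ref_index, candidate)
        except DegenerateError:
            candidate, cand_rms = None, np.inf

        accepted = candidate is not None and cand_rms < best_rms
        stalled = candidate is None or cand_rms > best_rms - min_improvement
        if accepted:
            t_best, best_rms = candidate, cand_rms
            trace.append(best_rms)
            t_current = candidate
        if log is not None:
            log(iteration=iterations, rms=best_rms, accepted=accepted,
                restarts=0)
        if stalled and best_rms >= rms_tol:
            return RegistrationResult(t_best, trace, iterations, 0,
                                      False, "stalled")
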