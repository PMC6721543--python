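"""End-to-end convenience wrapper: denoise + fuse/resample, then align."""

from __future__ import annotations

import numpy as np

from .core import PointCloud, RigidTransform, apply_transform, fiducial_rms
from .denoise import DenoiseParams
from .register import (PerturbParams, RegistrationResult, StopParams,
                       WeightParams, drwp_icp)
from .resample import MlsParams, fuse_and_resample


def register_captures(floating_1: PointCloud,
                      reference: PointCloud,
                      floating_2: PointCloud | None = None,
                      t_init: RigidTransform | None = None,
                      denoise: DenoiseParams = DenoiseParams(),
                      mls: MlsParams = MlsParams(),
                      weight: WeightParams = WeightParams(),
                      stop: StopParams = StopParams(),
                      perturb: PerturbParams = PerturbParams(),
                      rng: np.random.Generator | None = None,
                      log=None) -> tuple[RegistrationResult, PointCloud]:
    """Run the full pipeline on raw captures: statistical outlier removal on
    each capture, fusion and MLS resampling into one clean floating set F,
    then the robust weighted/perturbed alignment of F to the reference.

    Returns the registration result and F itself.
    """
    if rng is None:
        rng = np.random.default_rng(perturb.rng_seed)
    fused = fuse_and_resample(floating_1, floating_2, denoise=denoise,
                              mls=mls, rng=rng)
    result = drwp_icp(fused, reference, t_init=t_init, weight=weight,
                      stop=stop, perturb=perturb, rng=rng, log=log)
    return result, fused


def marker_error(result_transform: RigidTransform,
                 markers_true_floating: PointCloud,
                 markers_reference: PointCloud) -> float:
    """Mean fiducial error after mapping the floating-frame markers back to
    the reference frame with a recovered transform."""
    mapped = apply_transform(markers_true_floating, result_transform)
    _, mean = fiducial_rms(markers_reference, mapped)
    return mean
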