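"""Benchmark harness: degradation grids, repeated seeded runs, reports.

Reproduces the structure of a sparsity / noise / outlier robustness study:
for every condition and repeat a synthetic scene is built, each method is
started from a random pose, and the mean error over the five fiducial
markers is recorded; rows aggregate mean / min / max error and mean wall
time. Outlier counts in the grid are quoted at the full sensor-capture
scale (~48.6k points) and are rescaled to the configured scene size.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import PointCloud
from .pipeline import marker_error, register_captures
from .register import (PerturbParams, StopParams, WeightParams, vanilla_icp)
from .synthdata import SceneSpec, make_scene, random_rigid_transform

PAPER_FLOATING_SIZE = 48596  # capture size the grid's outlier counts refer to

METHODS = ("drwp", "vanilla")


@dataclass(frozen=True)
class BenchmarkGrid:
    """The experimental grid: one sweep per degradation axis plus the
    combined worst-case condition (max sparsity + max noise + max outliers).

    Random starting poses: rotation angle uniform in
    [0, max_start_angle_deg], translation uniform in the ball of radius
    start_translation_frac x bounding-box diagonal.
    """

    sparsity_levels: tuple = (1.0, 0.7, 0.5, 0.25, 0.1)
    noise_variances: tuple = (1.0, 2.0, 5.0, 7.0)
    outlier_counts: tuple = (600, 1800, 3000, 6000)
    seeds: tuple = (0, 1, 2, 3, 4)
    max_start_angle_deg: float = 180.0
    start_translation_frac: float = 0.5
    include_combined: bool = True

    @property
    def n_repeats(self) -> int:
        return len(self.seeds)


@dataclass
class BenchmarkReport:
    runs: pd.DataFrame    # one row per (condition, repeat, method)
    table: pd.DataFrame   # aggregated mean/min/max per (condition, method)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        return self.table.to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}")


def scaled_outliers(count: int, n_points: int) -> int:
    return int(round(count * n_points / PAPER_FLOATING_SIZE))


def grid_conditions(grid: BenchmarkGrid, base: SceneSpec) -> list[tuple]:
    """(condition_type, condition_value, scene-spec overrides) triples."""
    conds = []
    for level in grid.sparsity_levels:
        conds.append(("sparsity", level, {"keep_fraction": level}))
    for var in grid.noise_variances:
        conds.append(("noise", var, {"noise_variance": var}))
    for count in grid.outlier_counts:
        conds.append(("outliers", count,
                      {"n_outliers": scaled_outliers(count, base.n_points)}))
    if grid.include_combined:
        conds.append(("combined",
                      f"{min(grid.sparsity_levels)}+"
                      f"{max(grid.noise_variances)}+"
                      f"{max(grid.outlier_counts)}",
                      {"keep_fraction": min(grid.sparsity_levels),
                       "noise_variance": max(grid.noise_variances),
                       "n_outliers": scaled_outliers(
                           max(grid.outlier_counts), base.n_points)}))
    return conds


def run_single(scene, method: str, t_init, seed: int,
               stop: StopParams = StopParams(),
               weight: WeightParams = WeightParams(),
               perturb: PerturbParams = PerturbParams()) -> float:
    """One registration run; returns the mean 5-marker error."""
    rng = np.random.default_rng(seed)
    if method == "drwp":
        result, _ = register_captures(
            scene.floating_1, scene.reference, scene.floating_2,
            t_init=t_init, weight=weight, stop=stop, perturb=perturb, rng=rng)
    elif method == "vanilla":
        result = vanilla_icp(scene.floating_1, scene.reference,
                             t_init=t_init, stop=stop)
    else:
        raise ValueError(f"unknown method {method!r}; expected {METHODS}")
    return marker_error(result.transform, scene.markers_true_floating,
                        scene.markers_reference)


def run_condition(grid: BenchmarkGrid, base: SceneSpec, overrides: dict,
                  methods, stop: StopParams = StopParams()) -> list[dict]:
    """All repeats of one condition; returns per-run records."""
    records = []
    for seed in grid.seeds:
        spec = replace(base, rng_seed=seed, **overrides)
        scene = make_scene(spec)
        diag = scene.reference.bounding_box_diagonal()
        start_rng = np.random.default_rng(seed + 10_000)
        t_init = random_rigid_transform(
            start_rng, np.deg2rad(grid.max_start_angle_deg),
            grid.start_translation_frac * diag)
        for method in methods:
            t0 = time.perf_counter()
            try:
                rms = run_single(scene, method, t_init, seed, stop=stop)
                err = None
            except Exception as exc:  # harness continues on row failure
                rms, err = np.nan, str(exc)
            records.append({
                "seed": seed, "method": method, "rms": rms,
                "time_s": time.perf_counter() - t0, "error": err,
            })
    return records


def run_benchmark(grid: BenchmarkGrid,
                  methods=METHODS,
                  scene_base: SceneSpec = SceneSpec(),
                  stop: StopParams = StopParams()) -> BenchmarkReport:
    """Execute the full grid and aggregate mean/min/max marker error and
    mean wall time per (condition, method)."""
    run_rows = []
    for cond_type, cond_value, overrides in grid_conditions(grid, scene_base):
        for rec in run_condition(grid, scene_base, overrides, methods, stop):
            rec.update(condition_type=cond_type, condition_value=cond_value)
            run_rows.append(rec)
    runs = pd.DataFrame(run_rows)

    rows = []
    for (ctype, cvalue, method), grp in runs.groupby(
            ["condition_type", "condition_value", "method"], sort=False):
        ok = grp[grp["error"].isna()]
        rows.append({
            "condition_type": ctype, "condition_value": cvalue,
            "method": method,
            "rms_mean": ok["rms"].mean(), "rms_min": ok["rms"].min(),
            "rms_max": ok["rms"].max(), "time_mean_s": ok["time_s"].mean(),
            "n_ok": len(ok), "n_fail": len(grp) - len(ok),
        })
    return BenchmarkReport(runs=runs, table=pd.DataFrame(rows))
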