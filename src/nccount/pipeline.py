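"""End-to-end pipelines: counting, joint optimization, and the benchmark
comparing the original detector with the fully optimized one.

The *original* configuration evaluates every sliding-window offset with the
full template library at the operating threshold.  The *optimized*
configuration prunes redundant templates under a loss budget, evaluates only
the offsets of a skip pattern, and lowers the threshold along the fitted
count-vs-threshold line to compensate the lost counts.  Runtime is reported
as the deterministic NCC evaluation count (evaluated offsets x library size),
which is hardware-independent; wall-clock timing is informational only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .detection import CountResult, count_cells
from .errors import ConfigurationError, InversionError
from .library import PruneResult, TemplateLibrary, prune_library
from .ncc import SampleImage
from .patterns import preset_pattern
from .synthetic import SceneParams, derive_library, generate_scene
from .threshold import ThresholdModel, compensate_threshold, fit_count_model

__all__ = ["run_count", "run_optimize", "OptimizeResult", "optimized_vs_original"]

log = logging.getLogger(__name__)


def run_count(
    config: RunConfig,
    samples: "list[SampleImage]",
    library: TemplateLibrary,
) -> "list[CountResult]":
    """Count every sample under one configuration; returns per-sample results."""
    if not samples:
        raise ConfigurationError("no input images")
    pattern = config.skip_pattern
    results = []
    for sample in samples:
        res = count_cells(
            sample,
            list(library.templates),
            config.threshold,
            pattern=pattern,
            max_cluster_shape=config.cluster_shape,
        )
        log.info("counted %d cells (%d NCC evaluations)", res.count, res.n_evaluations)
        results.append(res)
    return results


@dataclass(frozen=True)
class OptimizeResult:
    pruned: TemplateLibrary
    prune: PruneResult
    model: ThresholdModel
    compensated_threshold: float
    clamped: bool
    summary: pd.DataFrame


def run_optimize(
    config: RunConfig,
    calibration: "list[SampleImage]",
    library: TemplateLibrary,
) -> OptimizeResult:
    """Prune the library, fit C(T), and compensate the threshold.

    The compensation target is the original pipeline's total count at the
    operating threshold on the calibration samples.  If the fitted slope is
    (numerically) zero the counts are flat over the calibration band — there
    is nothing to compensate — and the original threshold is kept.
    """
    if not calibration:
        raise ConfigurationError("no calibration images")
    pattern = config.skip_pattern
    original = [
        count_cells(s, list(library.templates), config.threshold, max_cluster_shape=config.cluster_shape)
        for s in calibration
    ]
    target = sum(r.count for r in original)

    prune = prune_library(
        calibration,
        library,
        config.threshold,
        config.loss_budget_percent,
        max_cluster_shape=config.cluster_shape,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat counts are an expected regime here
        model = fit_count_model(
            calibration,
            list(prune.pruned.templates),
            thresholds=config.threshold_grid,
            pattern=pattern,
            max_cluster_shape=config.cluster_shape,
        )
    try:
        comp = compensate_threshold(model, target)
        t_star, clamped = comp.threshold, comp.clamped
    except InversionError:
        t_star, clamped = config.threshold, False
        log.info("counts flat over the calibration band; keeping threshold %.3f", t_star)

    optimized = [
        count_cells(
            s,
            list(prune.pruned.templates),
            t_star,
            pattern=pattern,
            max_cluster_shape=config.cluster_shape,
        )
        for s in calibration
    ]
    density = float(pattern.density) if pattern is not None else 1.0
    summary = pd.DataFrame(
        {
            "sample": range(len(calibration)),
            "original_count": [r.count for r in original],
            "optimized_count": [r.count for r in optimized],
            "original_evaluations": [r.n_evaluations for r in original],
            "optimized_evaluations": [r.n_evaluations for r in optimized],
        }
    )
    expected_ratio = density * len(prune.pruned) / len(library)
    realized_ratio = summary.optimized_evaluations.sum() / summary.original_evaluations.sum()
    log.info(
        "evaluation ratio optimized/original = %.4f (library %d->%d, pattern density %.3f; expected %.4f)",
        realized_ratio,
        len(library),
        len(prune.pruned),
        density,
        expected_ratio,
    )
    return OptimizeResult(
        pruned=prune.pruned,
        prune=prune,
        model=model,
        compensated_threshold=t_star,
        clamped=clamped,
        summary=summary,
    )


def optimized_vs_original(
    n_scenes: int = 10,
    seed: int = 1,
    scene_params: SceneParams | None = None,
    n_templates: int = 12,
    duplicate_fraction: float = 1 / 3,
    jitter_fraction: float = 1 / 3,
    loss_budget_percent: float = 8.5,
    threshold: float = 0.67,
    pattern_preset: int = 1,
) -> pd.DataFrame:
    """Benchmark the optimized pipeline against the original on seeded scenes.

    For each scene: derive a library containing exact duplicates and jittered
    near-duplicates from the scene's own cells, run the original pipeline
    (full library, all offsets, operating threshold), then optimize on that
    scene (prune + pattern + compensated threshold) and count again.  Returns
    a per-scene table with both counts, the absolute relative difference in
    percent, and the evaluation-count ratio.
    """
    base = SceneParams() if scene_params is None else scene_params
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_scenes) % (2**31)
    pattern = preset_pattern(pattern_preset)
    rows = []
    for k in range(n_scenes):
        scene = generate_scene(base, seed=int(seeds[2 * k]))
        library = derive_library(
            scene,
            n_templates=n_templates,
            duplicate_fraction=duplicate_fraction,
            jitter_fraction=jitter_fraction,
            seed=int(seeds[2 * k + 1]),
        )
        config = RunConfig(
            threshold=threshold,
            pattern=pattern.name,
            loss_budget_percent=loss_budget_percent,
        )
        original = count_cells(scene.image, list(library.templates), threshold)
        opt = run_optimize(config, [scene.image], library)
        optimized = count_cells(
            scene.image,
            list(opt.pruned.templates),
            opt.compensated_threshold,
            pattern=pattern,
        )
        diff = (
            100.0 * abs(optimized.count - original.count) / original.count
            if original.count
            else 0.0
        )
        rows.append(
            {
                "scene": k,
                "n_cells_true": len(scene.truth),
                "original_count": original.count,
                "optimized_count": optimized.count,
                "abs_rel_diff_percent": diff,
                "pruned_size": len(opt.pruned),
                "compensated_threshold": opt.compensated_threshold,
                "evaluation_ratio": optimized.n_evaluations / original.n_evaluations,
            }
        )
    return pd.DataFrame(rows)
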