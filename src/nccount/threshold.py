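"""Linear count-vs-threshold model and threshold compensation.

Lowering the detection threshold marks more offsets and thus counts more
cells; over the calibration band the relationship is well described by a
straight line C(T) = alpha * T + beta with alpha < 0.  Pruning the library or
skipping evaluations depresses NCC maxima and loses counts; inverting the
fitted line gives the threshold T* = (target - beta) / alpha that restores
the target count.  T* is clamped below at 0.60, the weakest threshold still
indicating strong correlation — loss that would require going lower is not
compensable this way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import cluster_and_count, mark_points
from .errors import ConfigurationError, InversionError
from .ncc import SampleImage, Template, max_over_library
from .patterns import SkipPattern

__all__ = [
    "ThresholdModel",
    "CompensationResult",
    "fit_line",
    "fit_count_model",
    "compensate_threshold",
    "THRESHOLD_FLOOR",
]

log = logging.getLogger(__name__)

#: Correlation below 0.6 is no longer "strong"; compensation never goes lower.
THRESHOLD_FLOOR = 0.60
#: Default calibration band (original operating threshold down to the floor).
DEFAULT_GRID = tuple(np.round(np.linspace(0.60, 0.67, 8), 4))


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted line C(T) ~= alpha * T + beta over ``fit_range``.

    ``residual`` is the root-mean-square fit error in cells.  ``fit_points``
    keeps the (threshold, count) pairs the fit saw, for reporting.
    """

    alpha: float
    beta: float
    fit_range: tuple[float, float]
    residual: float
    fit_points: tuple = field(default=(), compare=False, repr=False)

    def predict(self, threshold: float) -> float:
        return self.alpha * threshold + self.beta


@dataclass(frozen=True)
class CompensationResult:
    threshold: float
    clamped: bool


def fit_line(thresholds, counts) -> ThresholdModel:
    """Ordinary least-squares line through (threshold, count) pairs."""
    T = np.asarray(thresholds, dtype=float)
    C = np.asarray(counts, dtype=float)
    if T.ndim != 1 or T.shape != C.shape or np.unique(T).size < 2:
        raise ConfigurationError("need counts at >= 2 distinct thresholds")
    if len(set(C.tolist())) == 1:
        warnings.warn(
            "counts are identical at every threshold; slope is 0 and the model cannot be inverted",
            stacklevel=2,
        )
        alpha, beta = 0.0, float(C[0])
    else:
        alpha, beta = np.polyfit(T, C, 1)
    resid = float(np.sqrt(np.mean((alpha * T + beta - C) ** 2)))
    points = tuple(zip(T.tolist(), C.tolist()))
    return ThresholdModel(
        alpha=float(alpha),
        beta=float(beta),
        fit_range=(float(T.min()), float(T.max())),
        residual=resid,
        fit_points=points,
    )


def fit_count_model(
    samples: "list[SampleImage]",
    templates: "list[Template] | tuple[Template, ...]",
    thresholds=DEFAULT_GRID,
    pattern: SkipPattern | None = None,
    max_cluster_shape: tuple[int, int] = (3, 3),
) -> ThresholdModel:
    """Fit C(T) by counting the calibration samples over a threshold grid.

    Thresholds must lie within [0.60, 1]; the max-over-library surface is
    computed once per sample and re-thresholded, so a fine grid is cheap.
    """
    T = sorted(set(float(t) for t in np.atleast_1d(np.asarray(thresholds, dtype=float))))
    if len(T) < 2:
        raise ConfigurationError("need >= 2 distinct thresholds")
    if min(T) < THRESHOLD_FLOOR or max(T) > 1.0:
        raise ConfigurationError(f"calibration thresholds must lie in [{THRESHOLD_FLOOR}, 1]")
    if not samples:
        raise ConfigurationError("no calibration samples supplied")
    surfaces = [max_over_library(s, list(templates), pattern=pattern) for s in samples]
    counts = []
    for t in T:
        total = 0
        for surf in surfaces:
            marks = mark_points(surf, t)
            total += cluster_and_count(marks, max_cluster_shape, pattern=pattern).count
        counts.append(total)
    return fit_line(T, counts)


def calibration_table(model: ThresholdModel) -> pd.DataFrame:
    """The (threshold, count) pairs a model was fitted on, as a table."""
    return pd.DataFrame(model.fit_points, columns=["threshold", "count"])


def compensate_threshold(model: ThresholdModel, target_count: float) -> CompensationResult:
    """Invert the fitted line to the threshold that yields ``target_count``.

    The result is clamped into [0.60, T_hi]; ``clamped=True`` flags that the
    loss is not fully compensable within the strong-correlation band.
    """
    if model.alpha == 0:
        raise InversionError("model slope is zero; threshold cannot be inverted")
    t_star = (float(target_count) - model.beta) / model.alpha
    hi = model.fit_range[1]
    clamped = not (THRESHOLD_FLOOR <= t_star <= hi)
    if clamped:
        log.warning(
            "compensated threshold %.4f clamped into [%.2f, %.2f]; loss not fully compensable",
            t_star,
            THRESHOLD_FLOOR,
            hi,
        )
    t_star = float(np.clip(t_star, THRESHOLD_FLOOR, hi))
    return CompensationResult(threshold=t_star, clamped=clamped)
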