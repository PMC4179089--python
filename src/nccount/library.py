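"""Template library handling, influence scoring, and redundancy pruning.

Libraries built by manually cropping cells from sample images inevitably
contain exact duplicates and near-duplicates; those templates add NCC
evaluations (runtime/energy) without adding counted cells.  *Influence* makes
this measurable: iterating templates in library order, a cluster found by
template k is attributed to k only if no earlier template already found an
overlapping cluster.  A template whose every detection overlaps earlier ones
has zero influence and can be dropped at zero cost; low-influence templates
can be dropped while a loss budget holds, after which the detection threshold
can be re-calibrated to compensate (see :mod:`nccount.threshold`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import cluster_and_count, mark_points
from .errors import ConfigurationError
from .ncc import (
    CorrelationSurface,
    SampleImage,
    Template,
    _single_surface_values,
    ncc_at_point,
)

__all__ = [
    "TemplateLibrary",
    "InfluenceReport",
    "PruneResult",
    "influence",
    "prune_library",
    "template_similarity",
    "evaluation_reduction",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemplateLibrary:
    """Ordered collection of uniform-shape templates with a metadata manifest.

    Order is significant: influence attribution iterates templates in library
    order, so reordering changes which of two near-duplicates is credited.
    """

    templates: tuple[Template, ...]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        templates = tuple(self.templates)
        if not templates:
            raise ConfigurationError("template library is empty")
        ids = [t.id for t in templates]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("template ids must be unique")
        shapes = {t.pixels.shape for t in templates}
        if len(shapes) != 1:
            raise ConfigurationError(f"templates have mixed shapes: {sorted(shapes)}")
        object.__setattr__(self, "templates", templates)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.templates)

    @property
    def template_shape(self) -> tuple[int, int]:
        return self.templates[0].pixels.shape  # type: ignore[return-value]

    def subset(self, ids: "list[str] | tuple[str, ...]") -> "TemplateLibrary":
        keep = set(ids)
        templates = tuple(t for t in self.templates if t.id in keep)
        manifest = {k: v for k, v in self.manifest.items() if k in keep}
        return TemplateLibrary(templates=templates, manifest=manifest)

    def save(self, directory: "str | Path") -> None:
        """Write patches as 16-bit grayscale PNGs plus a CSV manifest."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for order, tpl in enumerate(self.templates):
            fname = f"{tpl.id}.png"
            scaled = np.clip(tpl.pixels * 256.0, 0, 65535).astype(np.uint16)
            iio.imwrite(directory / fname, scaled)
            meta = dict(self.manifest.get(tpl.id, {}))
            rows.append({"id": tpl.id, "filename": fname, "order": order, **meta})
        pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)

    @classmethod
    def load(cls, directory: "str | Path") -> "TemplateLibrary":
        """Load a library directory written by :meth:`save`."""
        import imageio.v3 as iio

        directory = Path(directory)
        manifest_path = directory / "manifest.csv"
        if not manifest_path.exists():
            raise ConfigurationError(f"no manifest.csv in {directory}")
        table = pd.read_csv(manifest_path).sort_values("order")
        templates = []
        manifest = {}
        for row in table.itertuples(index=False):
            px = np.asarray(iio.imread(directory / row.filename), dtype=np.float64)
            if px.ndim == 3:
                px = px.mean(axis=2)
            templates.append(Template(id=str(row.id), pixels=px / 256.0))
            manifest[str(row.id)] = {
                k: v for k, v in row._asdict().items() if k not in ("id", "filename", "order")
            }
        return cls(templates=tuple(templates), manifest=manifest)


@dataclass(frozen=True)
class InfluenceReport:
    """Per-template attributed cell counts under sequential attribution."""

    attributed: dict  # id -> int
    total_cells: int

    def influence_percent(self, tpl_id: str) -> float:
        if self.total_cells == 0:
            return 0.0
        return 100.0 * self.attributed[tpl_id] / self.total_cells

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "template_id": list(self.attributed),
                "attributed_cells": list(self.attributed.values()),
                "influence_percent": [self.influence_percent(i) for i in self.attributed],
            }
        )


@dataclass(frozen=True)
class PruneResult:
    pruned: TemplateLibrary
    projected_loss_percent: float
    removal_log: pd.DataFrame
    original_count: int
    pruned_count: int


class DetectionCache:
    """Per-template NCC surfaces for a fixed (samples, library, threshold).

    Influence scoring and greedy pruning repeatedly re-count with template
    subsets; template surfaces do not change when other templates are removed,
    so they are computed once and subset counts become cheap maxima.
    """

    def __init__(
        self,
        samples: "list[SampleImage]",
        library: TemplateLibrary,
        threshold: float,
        max_cluster_shape: tuple[int, int] = (3, 3),
    ) -> None:
        if not samples:
            raise ConfigurationError("no calibration samples supplied")
        if not -1.0 <= threshold <= 1.0:
            raise ConfigurationError(f"threshold must lie in [-1, 1], got {threshold}")
        self.library = library
        self.threshold = float(threshold)
        self.max_cluster_shape = max_cluster_shape
        self._stacks = []  # per sample: (n_templates, H, W)
        for sample in samples:
            stack = np.stack([_single_surface_values(sample, t) for t in library.templates])
            self._stacks.append(stack)
        self._cluster_cache: dict[int, list] = {}

    def count_subset(self, indices: "list[int]") -> int:
        """Total cell count over all samples using only the given templates."""
        idx = list(indices)
        if not idx:
            return 0
        total = 0
        for stack in self._stacks:
            vals = stack[idx].max(axis=0)
            surface = CorrelationSurface(values=vals, evaluated=np.ones(vals.shape, dtype=bool))
            marks = mark_points(surface, self.threshold)
            total += cluster_and_count(marks, self.max_cluster_shape).count
        return total

    def template_clusters(self, index: int) -> list:
        """Per-sample cluster member arrays detected by one template alone."""
        if index not in self._cluster_cache:
            per_sample = []
            for stack in self._stacks:
                vals = stack[index]
                surface = CorrelationSurface(values=vals, evaluated=np.ones(vals.shape, dtype=bool))
                marks = mark_points(surface, self.threshold)
                clusters = cluster_and_count(marks, self.max_cluster_shape)
                per_sample.append([cl.members for cl in clusters.clusters])
            self._cluster_cache[index] = per_sample
        return self._cluster_cache[index]

    def attribute(self, indices: "list[int]") -> InfluenceReport:
        """Sequential first-detector attribution over a template subset.

        Templates are visited in library order; a cluster is credited to a
        template only if none of its marked offsets lies within Chebyshev
        distance max(m, n) - 1 of a cluster already credited to an earlier
        template.  (Proximity is tested against the cluster body, not its
        centroid: real clusters can exceed the nominal m x n extent, in which
        case two templates seeing the same cell may centre differently.)
        """
        m, n = self.max_cluster_shape
        radius = max(max(m, n) - 1, 1)
        attributed = {self.library.templates[i].id: 0 for i in sorted(indices)}
        total = 0
        for s, stack in enumerate(self._stacks):
            H, W = stack.shape[1:]
            claimed = np.zeros((H, W), dtype=bool)
            for i in sorted(indices):
                for members in self.template_clusters(i)[s]:
                    if claimed[members[:, 0], members[:, 1]].any():
                        continue
                    for r, c in members:  # claim the cluster, dilated by the merge radius
                        claimed[
                            max(r - radius, 0) : r + radius + 1,
                            max(c - radius, 0) : c + radius + 1,
                        ] = True
                    attributed[self.library.templates[i].id] += 1
                    total += 1
        return InfluenceReport(attributed=attributed, total_cells=total)


def influence(
    samples: "list[SampleImage]",
    library: TemplateLibrary,
    threshold: float,
    max_cluster_shape: tuple[int, int] = (3, 3),
    attribution: str = "first",
) -> InfluenceReport:
    """Score each template's influence on the total count.

    ``attribution="first"`` is sequential first-detector attribution (the
    default; duplicates of an earlier template score zero).  ``"argmax"``
    instead credits each cluster of the max-over-library detector to the
    template with the highest NCC at the cluster peak — useful as a
    sensitivity check on the ordering convention.
    """
    if attribution == "first":
        cache = DetectionCache(samples, library, threshold, max_cluster_shape)
        report = cache.attribute(list(range(len(library))))
    elif attribution == "argmax":
        from .detection import count_cells

        attributed = {t.id: 0 for t in library.templates}
        total = 0
        for sample in samples:
            res = count_cells(sample, list(library.templates), threshold, max_cluster_shape=max_cluster_shape)
            for cl in res.clusters.clusters:
                attributed[cl.template_id] += 1
                total += 1
        report = InfluenceReport(attributed=attributed, total_cells=total)
    else:
        raise ConfigurationError(f"unknown attribution mode {attribution!r}")
    if report.total_cells == 0:
        log.warning("no cells detected on the calibration samples; influences are all zero")
    return report


def prune_library(
    samples: "list[SampleImage]",
    library: TemplateLibrary,
    threshold: float,
    loss_budget_percent: float,
    max_cluster_shape: tuple[int, int] = (3, 3),
) -> PruneResult:
    """Remove redundant templates while total-count loss stays within budget.

    First drops every zero-influence template (their detections are all
    already claimed by earlier templates, so removal is projected lossless),
    then greedily removes the lowest-influence remaining template —
    recomputing influence after each removal — while the realized cumulative
    count loss against the full library stays within ``loss_budget_percent``.
    Ties break by library order.  The result never goes empty: at worst the
    single highest-influence template survives.
    """
    if loss_budget_percent < 0:
        raise ConfigurationError("loss budget must be >= 0")
    cache = DetectionCache(samples, library, threshold, max_cluster_shape)
    all_idx = list(range(len(library)))
    original_count = cache.count_subset(all_idx)
    log_rows = []
    step = 0

    def loss_percent(count: int) -> float:
        if original_count == 0:
            return 0.0
        return 100.0 * abs(original_count - count) / original_count

    current = list(all_idx)
    # Stage 1: zero-influence templates are projected lossless; drop them all.
    report = cache.attribute(current)
    zero = [i for i in current if report.attributed[library.templates[i].id] == 0]
    if zero and len(zero) < len(current):
        tentative = [i for i in current if i not in zero]
        realized = loss_percent(cache.count_subset(tentative))
        if realized <= loss_budget_percent + 1e-12:
            for i in zero:
                step += 1
                log_rows.append(
                    {
                        "step": step,
                        "template_id": library.templates[i].id,
                        "influence_percent": 0.0,
                        "cumulative_loss_percent": realized,
                    }
                )
            current = tentative

    # Stage 2: greedy lowest-influence removal under the budget.
    while len(current) > 1:
        report = cache.attribute(current)
        candidate = min(
            current,
            key=lambda i: (report.attributed[library.templates[i].id], i),
        )
        tentative = [i for i in current if i != candidate]
        realized = loss_percent(cache.count_subset(tentative))
        if realized > loss_budget_percent + 1e-12:
            break
        step += 1
        log_rows.append(
            {
                "step": step,
                "template_id": library.templates[candidate].id,
                "influence_percent": report.influence_percent(library.templates[candidate].id),
                "cumulative_loss_percent": realized,
            }
        )
        current = tentative

    pruned = library.subset([library.templates[i].id for i in current])
    pruned_count = cache.count_subset(current)
    return PruneResult(
        pruned=pruned,
        projected_loss_percent=loss_percent(pruned_count),
        removal_log=pd.DataFrame(
            log_rows,
            columns=["step", "template_id", "influence_percent", "cumulative_loss_percent"],
        ),
        original_count=original_count,
        pruned_count=pruned_count,
    )


def template_similarity(library: TemplateLibrary) -> pd.DataFrame:
    """Pairwise full-overlap NCC between templates (diagnostic for redundancy).

    Symmetric with unit diagonal; entries near +/-1 flag duplicated or
    affine-equivalent templates.
    """
    n = len(library)
    mat = np.eye(n)
    for a in range(n):
        sample = SampleImage(pixels=library.templates[a].pixels)
        for b in range(a + 1, n):
            val = ncc_at_point(sample, library.templates[b], 0, 0)
            mat[a, b] = mat[b, a] = val
    return pd.DataFrame(mat, index=library.ids, columns=library.ids)


def evaluation_reduction(n_original: int, n_pruned: int) -> int:
    """Percent reduction in NCC evaluations from shrinking the library.

    Per-template evaluations are library-size-linear, so a shrink from
    ``n_original`` to ``n_pruned`` templates cuts evaluations by
    ``100 * (1 - n_pruned / n_original)``, rounded to the nearest percent.
    """
    if n_original < 1 or n_pruned < 0 or n_pruned > n_original:
        raise ConfigurationError("invalid library sizes")
    from fractions import Fraction

    return int(round(float(100 * (1 - Fraction(n_pruned, n_original)))))
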