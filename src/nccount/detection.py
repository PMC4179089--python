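"""Turn a correlation surface into marked points, clusters, and a cell count.

An offset is *marked* when its max-over-library NCC strictly exceeds the
threshold.  A physical cell spans several adjacent offsets, so marked points
come in clusters; the count is the number of clusters, not marks.  Without a
skip pattern, clusters are 8-connected components.  With a pattern active the
surviving marks of one cell can sit further apart (skipping breaks
8-adjacency inside the cell footprint), so the merge radius widens to
Chebyshev distance ``max(m, n) - 1`` for an expected cluster extent of
``m x n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .ncc import CorrelationSurface, SampleImage, Template, max_over_library
from .patterns import SkipPattern

__all__ = [
    "MarkMatrix",
    "Cluster",
    "ClusterSet",
    "CountResult",
    "mark_points",
    "cluster_and_count",
    "count_cells",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkMatrix:
    """Boolean marks over the offset grid plus the threshold that made them."""

    marks: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "marks", np.asarray(self.marks, dtype=bool))


@dataclass(frozen=True)
class Cluster:
    """One connected group of marked offsets — one counted cell."""

    members: np.ndarray  # (k, 2) row/col offsets
    centroid: tuple[float, float]
    template_id: str | None = None

    @property
    def size(self) -> int:
        return int(self.members.shape[0])

    @property
    def extent(self) -> tuple[int, int]:
        span = self.members.max(axis=0) - self.members.min(axis=0) + 1
        return int(span[0]), int(span[1])


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    max_cluster_shape: tuple[int, int]

    @property
    def count(self) -> int:
        return len(self.clusters)

    def centroids(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 2))
        return np.array([c.centroid for c in self.clusters])


@dataclass(frozen=True)
class CountResult:
    """End-to-end result of counting one sample image."""

    count: int
    clusters: ClusterSet
    marks: MarkMatrix
    surface: CorrelationSurface
    n_evaluations: int  # evaluated offsets x library size


def mark_points(surface: CorrelationSurface, threshold: float) -> MarkMatrix:
    """Mark evaluated offsets whose value strictly exceeds ``threshold``.

    Skipped offsets are never marked.  The comparison is strict (``>``); an
    offset exactly at the threshold is not a cell.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must lie in [-1, 1], got {threshold}")
    marks = surface.evaluated & (surface.values > threshold)
    return MarkMatrix(marks=marks, threshold_used=float(threshold))


def _components_label(marks: np.ndarray) -> list[np.ndarray]:
    """8-connected components via scipy.ndimage."""
    labels, n = ndimage.label(marks, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return []
    flat = np.argwhere(labels > 0)
    order = labels[flat[:, 0], flat[:, 1]]
    out: list[list] = [[] for _ in range(n)]
    for (r, c), lab in zip(flat, order):
        out[lab - 1].append((r, c))
    return [np.array(members) for members in out]


def _components_radius(coords: np.ndarray, radius: int) -> list[np.ndarray]:
    """Union-find components with Chebyshev-distance-<=radius adjacency."""
    n = coords.shape[0]
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(coords)
    for a, b in tree.query_pairs(r=radius + 1e-9, p=np.inf):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for idx in range(n):
        groups.setdefault(find(idx), []).append(idx)
    return [coords[idxs] for idxs in groups.values()]


def cluster_and_count(
    marks: MarkMatrix,
    max_cluster_shape: tuple[int, int] = (3, 3),
    pattern: SkipPattern | None = None,
    surface: CorrelationSurface | None = None,
) -> ClusterSet:
    """Group marked offsets into clusters; one cluster is one counted cell.

    Connectivity is 8-adjacency (Chebyshev radius 1) without a pattern; when
    a pattern is active the Chebyshev merge radius widens to cover both the
    expected cluster extent (``max(m, n) - 1``) and the pattern's evaluated
    lattice spacing, so that the surviving marks of a single cell still
    merge.  Clusters wider than the
    expected ``m x n`` extent are still counted once — the cap is a physical
    expectation, not a splitting rule — but their number is logged.

    When ``surface`` (a max-over-library surface) is supplied, each cluster
    is annotated with the arg-max template at its highest-valued member.
    """
    m, n = max_cluster_shape
    if m < 1 or n < 1:
        raise ConfigurationError(f"invalid cluster shape {max_cluster_shape}")
    if pattern is None:
        radius = 1
    else:
        # Bridge both the expected cluster extent and the pattern's lattice
        # spacing, so one cell's surviving marks always merge.
        radius = max(max(m, n) - 1, *pattern.lattice_gaps(), 1)

    grid = marks.marks
    if not grid.any():
        return ClusterSet(clusters=(), max_cluster_shape=(m, n))
    if radius == 1:
        member_lists = _components_label(grid)
    else:
        member_lists = _components_radius(np.argwhere(grid), radius)

    clusters = []
    oversized = 0
    for members in member_lists:
        centroid = (float(members[:, 0].mean()), float(members[:, 1].mean()))
        tpl_id = None
        if surface is not None and surface.best_template is not None and surface.template_ids:
            vals = surface.values[members[:, 0], members[:, 1]]
            peak = members[int(np.argmax(vals))]
            tpl_id = surface.template_ids[int(surface.best_template[peak[0], peak[1]])]
        cl = Cluster(members=members, centroid=centroid, template_id=tpl_id)
        if cl.extent[0] > m or cl.extent[1] > n:
            oversized += 1
        clusters.append(cl)
    if oversized:
        log.warning("%d of %d clusters exceed the expected %dx%d extent", oversized, len(clusters), m, n)
    # Stable presentation order: by centroid row, then column.
    clusters.sort(key=lambda c: c.centroid)
    return ClusterSet(clusters=tuple(clusters), max_cluster_shape=(m, n))


def count_cells(
    sample: SampleImage,
    templates: "list[Template] | tuple[Template, ...]",
    threshold: float,
    pattern: SkipPattern | None = None,
    max_cluster_shape: tuple[int, int] = (3, 3),
) -> CountResult:
    """Count cells: max-over-library NCC -> threshold marks -> clusters.

    The count is monotonically non-increasing in the threshold, and under any
    skip pattern the marks are a subset of the unpatterned marks.
    """
    surface = max_over_library(sample, templates, pattern=pattern)
    marks = mark_points(surface, threshold)
    clusters = cluster_and_count(marks, max_cluster_shape, pattern=pattern, surface=surface)
    return CountResult(
        count=clusters.count,
        clusters=clusters,
        marks=marks,
        surface=surface,
        n_evaluations=surface.n_evaluated * len(list(templates)),
    )
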