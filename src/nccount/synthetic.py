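"""Seeded synthetic lensless blood-sample scenes with ground truth.

Real acquisitions image cell "shadows" produced by in-line holography: each
cell appears as a small dark disk surrounded by a brighter diffraction-like
ring, on a background with slow intensity gradients and sensor noise.  The
generator emulates exactly those features — a radially symmetric
disk-plus-ring profile drawn from a few morphology variants, a linear
background plane, and i.i.d. Gaussian noise — and records every planted cell
centre, so detection, pruning and calibration can all be tested against known
truth without any acquisition hardware.

Default conditions: a 300 x 400 image with 60 cells at Chebyshev separation
>= 20, background 140 with a gentle gradient, and noise sigma 3.0 — mild
enough that a template cropped from one cell correlates above 0.8 with every
other cell of its variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .library import TemplateLibrary
from .ncc import SampleImage, Template

__all__ = ["CellShape", "SceneParams", "SyntheticScene", "generate_scene", "derive_library"]


@dataclass(frozen=True)
class CellShape:
    """Radial shadow profile: dark Gaussian core plus bright ring."""

    disk_sigma: float
    ring_radius: float
    ring_sigma: float = 1.2
    disk_depth: float = 70.0
    ring_gain: float = 35.0

    def profile(self, d: np.ndarray) -> np.ndarray:
        core = -self.disk_depth * np.exp(-0.5 * (d / self.disk_sigma) ** 2)
        ring = self.ring_gain * np.exp(-0.5 * ((d - self.ring_radius) / self.ring_sigma) ** 2)
        return core + ring


#: Morphology variants observed across a sample: small/medium/large shadows.
DEFAULT_VARIANTS: tuple[CellShape, ...] = (
    CellShape(disk_sigma=1.8, ring_radius=4.6),
    CellShape(disk_sigma=2.6, ring_radius=6.0),
    CellShape(disk_sigma=3.4, ring_radius=7.4),
)


@dataclass(frozen=True)
class SceneParams:
    shape: tuple[int, int] = (300, 400)
    n_cells: int = 60
    min_separation: int = 20
    margin: int = 12
    background: float = 140.0
    gradient: tuple[float, float] = (-0.03, 0.04)  # intensity per row / per col
    noise_sigma: float = 3.0
    variants: tuple[CellShape, ...] = DEFAULT_VARIANTS
    seed: int = 0


@dataclass(frozen=True)
class SyntheticScene:
    image: SampleImage
    truth: tuple  # of (row, col, shape_id)
    params: SceneParams

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth, columns=["row", "col", "shape_id"])


def _place_centers(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    H, W = params.shape
    lo_r, hi_r = params.margin, H - params.margin
    lo_c, hi_c = params.margin, W - params.margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise GenerationError("margins leave no usable image area")
    capacity = ((hi_r - lo_r) // params.min_separation + 1) * ((hi_c - lo_c) // params.min_separation + 1)
    if params.n_cells > capacity:
        raise GenerationError(
            f"cannot pack {params.n_cells} cells at separation {params.min_separation} "
            f"into a {H}x{W} image (capacity ~{capacity})"
        )
    centers: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 1000 * max(params.n_cells, 1)
    while len(centers) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"failed to place {params.n_cells} cells after {max_attempts} attempts"
            )
        r = int(rng.integers(lo_r, hi_r))
        c = int(rng.integers(lo_c, hi_c))
        if all(max(abs(r - rr), abs(c - cc)) >= params.min_separation for rr, cc in centers):
            centers.append((r, c))
    return np.array(centers, dtype=int).reshape(-1, 2)


def generate_scene(params: SceneParams | None = None, **overrides) -> SyntheticScene:
    """Render a scene: background plane + planted shadows + Gaussian noise.

    Deterministic for a fixed seed (bit-identical images).  Keyword overrides
    patch individual fields of :class:`SceneParams`.
    """
    if params is None:
        params = SceneParams()
    if overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    H, W = params.shape
    rows = np.arange(H)[:, None] - H / 2.0
    cols = np.arange(W)[None, :] - W / 2.0
    image = params.background + params.gradient[0] * rows + params.gradient[1] * cols

    truth = []
    if params.n_cells > 0:
        centers = _place_centers(params, rng)
        shape_ids = rng.integers(0, len(params.variants), size=len(centers))
        reach = params.margin  # profile support stays within the border margin
        yy, xx = np.mgrid[-reach : reach + 1, -reach : reach + 1]
        dist = np.hypot(yy, xx)
        stamps = [v.profile(dist) for v in params.variants]
        for (r, c), sid in zip(centers, shape_ids):
            image[r - reach : r + reach + 1, c - reach : c + reach + 1] += stamps[int(sid)]
            truth.append((int(r), int(c), int(sid)))
    image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    return SyntheticScene(image=SampleImage(pixels=image), truth=tuple(truth), params=params)


def derive_library(
    scene: SyntheticScene,
    n_templates: int = 12,
    duplicate_fraction: float = 0.0,
    jitter_fraction: float = 0.0,
    jitter: int = 2,
    patch_shape: tuple[int, int] = (17, 17),
    seed: int = 0,
) -> TemplateLibrary:
    """Crop a template library from a scene's true cells.

    Mimics manual library construction: ``n_templates`` patches of which a
    ``duplicate_fraction`` are exact copies of earlier crops and a
    ``jitter_fraction`` are crops offset by up to ``jitter`` pixels
    (near-duplicates).  The distinct crops are taken round-robin across the
    morphology variants present in the scene so every variant is represented,
    and the final ordering is shuffled under ``seed``.
    """
    if n_templates < 1:
        raise ConfigurationError("n_templates must be >= 1")
    K, L = patch_shape
    if K % 2 == 0 or L % 2 == 0:
        raise ConfigurationError("patch_shape must be odd so crops centre on a cell")
    if not scene.truth:
        raise ConfigurationError("scene has no planted cells to crop from")
    n_dup = int(round(duplicate_fraction * n_templates))
    n_jit = int(round(jitter_fraction * n_templates))
    n_distinct = n_templates - n_dup - n_jit
    if n_distinct < 1:
        raise ConfigurationError("duplicate/jitter fractions leave no distinct templates")
    if n_distinct > len(scene.truth):
        raise ConfigurationError(
            f"{n_distinct} distinct templates requested but scene has only {len(scene.truth)} cells"
        )

    rng = np.random.default_rng(seed)
    px = scene.image.pixels
    hk, hl = K // 2, L // 2

    def crop(r: int, c: int) -> np.ndarray:
        if not (hk <= r < px.shape[0] - hk and hl <= c < px.shape[1] - hl):
            raise ConfigurationError(f"cell ({r}, {c}) too close to the border for a {K}x{L} crop")
        return px[r - hk : r + hk + 1, c - hl : c + hl + 1].copy()

    # Round-robin over variants so the distinct crops cover every morphology.
    by_variant: dict[int, list[tuple[int, int, int]]] = {}
    for rec in scene.truth:
        by_variant.setdefault(rec[2], []).append(rec)
    pools = []
    for sid in sorted(by_variant):
        cells = by_variant[sid]
        pools.append([cells[i] for i in rng.permutation(len(cells))])
    sources = []
    lane = 0
    while len(sources) < n_distinct:
        pool = pools[lane % len(pools)]
        if pool:
            sources.append(pool.pop())
        lane += 1
        if all(not p for p in pools):
            raise ConfigurationError("ran out of distinct cells")

    entries = []  # (pixels, manifest meta)
    for k, (r, c, sid) in enumerate(sources):
        entries.append((crop(r, c), {"kind": "distinct", "source_row": r, "source_col": c, "shape_id": sid}))
    # Duplicate sources without replacement while possible, so k duplicates of
    # k distinct crops give exactly k identical pairs.
    if n_dup:
        dup_sources = rng.permutation(n_distinct)[:n_dup].tolist()
        while len(dup_sources) < n_dup:
            dup_sources.append(int(rng.integers(0, n_distinct)))
        for src in dup_sources:
            pixels, meta = entries[int(src)]
            entries.append((pixels.copy(), {**meta, "kind": "duplicate"}))
    for _ in range(n_jit):
        if jitter < 1:
            raise ConfigurationError("jitter_fraction > 0 requires jitter >= 1")
        r, c, sid = sources[int(rng.integers(0, n_distinct))]
        dr = dc = 0
        while dr == 0 and dc == 0:
            dr = int(rng.integers(-jitter, jitter + 1))
            dc = int(rng.integers(-jitter, jitter + 1))
        entries.append(
            (
                crop(r + dr, c + dc),
                {"kind": "jittered", "source_row": r, "source_col": c, "shape_id": sid,
                 "jitter_row": dr, "jitter_col": dc},
            )
        )

    order = rng.permutation(len(entries))
    templates = []
    manifest = {}
    for rank, idx in enumerate(order):
        pixels, meta = entries[idx]
        tpl_id = f"tpl{rank:03d}"
        templates.append(Template(id=tpl_id, pixels=pixels))
        manifest[tpl_id] = meta
    return TemplateLibrary(templates=tuple(templates), manifest=manifest)
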