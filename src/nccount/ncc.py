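"""Normalized cross-correlation (NCC) between a sample image and templates.

The NCC score at sliding-window offset ``(i, j)`` between an ``M x N`` sample
``f`` and a ``K x L`` template ``w`` is

    R(i, j) = sum[(w - mean(w)) * (f_win - mean(f_win))]
              / sqrt(sum[(w - mean(w))^2] * sum[(f_win - mean(f_win))^2])

with ``f_win`` the ``K x L`` window of ``f`` whose top-left corner sits at
``(i, j)``, for ``0 <= i <= M-K`` and ``0 <= j <= N-L`` (valid-mode, row-major,
0-based, origin top-left).  R lies in [-1, 1] and is invariant to affine
intensity changes of either image; values near 0 mean the window and template
are unrelated.

Two routes are provided: :func:`ncc_at_point` evaluates the definition
directly at one offset (the slow reference), while :func:`ncc_surface` covers
the whole offset grid efficiently using one cross-correlation for the
numerator plus integral-image window sums for the denominator.  The two agree
to better than 1e-6 everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate

from .errors import ConfigurationError, InvalidTemplateError, RangeError, SizeError
from .patterns import SkipPattern

__all__ = [
    "SampleImage",
    "Template",
    "CorrelationSurface",
    "ncc_at_point",
    "ncc_surface",
    "max_over_library",
]

log = logging.getLogger(__name__)

#: Windows whose deviation energy falls below this are treated as constant;
#: NCC is undefined there and defined to be 0 (maximally uninformative).
_ZERO_VAR_EPS = 1e-10


@dataclass(frozen=True)
class SampleImage:
    """An M x N grayscale intensity grid (arbitrary units, float64)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.ascontiguousarray(np.asarray(self.pixels, dtype=np.float64))
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ConfigurationError(f"sample image must be 2-D and non-empty, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ConfigurationError("sample image contains non-finite intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def M(self) -> int:
        return self.pixels.shape[0]

    @property
    def N(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Template:
    """A K x L grayscale patch with an identifier.

    A constant patch has undefined NCC (zero deviation energy) and is
    rejected at construction.
    """

    id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.ascontiguousarray(np.asarray(self.pixels, dtype=np.float64))
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidTemplateError(f"template {self.id!r} must be 2-D and non-empty")
        if not np.isfinite(px).all():
            raise InvalidTemplateError(f"template {self.id!r} contains non-finite values")
        if px.size > 1 and float(((px - px.mean()) ** 2).sum()) <= 0.0:
            raise InvalidTemplateError(f"template {self.id!r} is constant; NCC undefined")
        if px.size == 1:
            raise InvalidTemplateError(f"template {self.id!r} is a single pixel; NCC undefined")
        object.__setattr__(self, "pixels", px)

    @property
    def K(self) -> int:
        return self.pixels.shape[0]

    @property
    def L(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CorrelationSurface:
    """NCC values on the (M-K+1) x (N-L+1) offset grid.

    ``evaluated`` is False where a skip pattern suppressed evaluation; such
    entries hold 0.0 and must never be read as correlation values.  For a
    max-over-library surface, ``best_template`` holds the index (into
    ``template_ids``) of the arg-max template at each evaluated offset.
    """

    values: np.ndarray
    evaluated: np.ndarray
    template_ids: tuple[str, ...] = ()
    best_template: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.evaluated = np.asarray(self.evaluated, dtype=bool)
        if self.values.shape != self.evaluated.shape:
            raise ConfigurationError("values/evaluated shape mismatch")
        vals = self.values[self.evaluated]
        if vals.size and (vals.min() < -1 - 1e-9 or vals.max() > 1 + 1e-9):
            raise ConfigurationError("evaluated NCC values outside [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())


def ncc_at_point(sample: SampleImage, template: Template, i: int, j: int) -> float:
    """NCC at one offset by direct summation over the window (reference path).

    Raises :class:`RangeError` if ``(i, j)`` falls outside the valid offset
    grid.  A constant sample window returns 0.0.
    """
    M, N, K, L = sample.M, sample.N, template.K, template.L
    if K > M or L > N:
        raise SizeError(f"template {K}x{L} larger than sample {M}x{N}")
    if not (0 <= i <= M - K and 0 <= j <= N - L):
        raise RangeError(f"offset ({i}, {j}) outside valid grid ({M - K + 1}x{N - L + 1})")
    win = sample.pixels[i : i + K, j : j + L]
    dw = template.pixels - template.pixels.mean()
    df = win - win.mean()
    w_energy = float((dw * dw).sum())
    f_energy = float((df * df).sum())
    if f_energy <= _ZERO_VAR_EPS:
        return 0.0
    r = float((dw * df).sum()) / np.sqrt(w_energy * f_energy)
    return float(np.clip(r, -1.0, 1.0))


def _window_sums(a: np.ndarray, K: int, L: int) -> np.ndarray:
    """Sum of ``a`` over every K x L valid window via an integral image."""
    ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(a, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    return ii[K:, L:] - ii[:-K, L:] - ii[K:, :-L] + ii[:-K, :-L]


def _window_deviation_energy(sample: SampleImage, K: int, L: int) -> np.ndarray:
    """sum[(f_win - mean)^2] for every valid window, clipped at 0."""
    px = sample.pixels
    s1 = _window_sums(px, K, L)
    s2 = _window_sums(px * px, K, L)
    energy = s2 - s1 * s1 / (K * L)
    np.clip(energy, 0.0, None, out=energy)
    return energy


def _template_numerator(sample: SampleImage, template: Template) -> np.ndarray:
    """Valid-mode cross-correlation of the sample with the zero-mean template.

    Because the template is zero-mean, subtracting the window mean from the
    sample changes nothing: this is exactly the NCC numerator.
    """
    dw = template.pixels - template.pixels.mean()
    return correlate(sample.pixels, dw, mode="valid", method="auto")


def _single_surface_values(sample: SampleImage, template: Template) -> np.ndarray:
    num = _template_numerator(sample, template)
    dw = template.pixels - template.pixels.mean()
    w_energy = float((dw * dw).sum())
    f_energy = _window_deviation_energy(sample, template.K, template.L)
    denom = np.sqrt(w_energy * f_energy)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(f_energy > _ZERO_VAR_EPS, num / denom, 0.0)
    return np.clip(vals, -1.0, 1.0)


def ncc_surface(
    sample: SampleImage, template: Template, pattern: SkipPattern | None = None
) -> CorrelationSurface:
    """Full NCC surface of one template over the sample (fast path).

    Offsets suppressed by ``pattern`` carry ``evaluated=False`` and value 0.
    """
    if template.K > sample.M or template.L > sample.N:
        raise SizeError(
            f"template {template.K}x{template.L} larger than sample {sample.M}x{sample.N}"
        )
    vals = _single_surface_values(sample, template)
    if pattern is None:
        evaluated = np.ones(vals.shape, dtype=bool)
    else:
        evaluated = pattern.mask_for_shape(vals.shape)
        vals = np.where(evaluated, vals, 0.0)
    return CorrelationSurface(values=vals, evaluated=evaluated, template_ids=(template.id,))


def max_over_library(
    sample: SampleImage,
    templates: "list[Template] | tuple[Template, ...]",
    pattern: SkipPattern | None = None,
) -> CorrelationSurface:
    """Pointwise maximum of per-template NCC surfaces, with arg-max identity.

    All templates must share one (K, L) shape.  The arg-max template index at
    each offset feeds influence attribution downstream.
    """
    templates = list(templates)
    if not templates:
        raise ConfigurationError("template library is empty")
    shapes = {t.pixels.shape for t in templates}
    if len(shapes) != 1:
        raise ConfigurationError(f"templates have mixed shapes: {sorted(shapes)}")
    K, L = templates[0].K, templates[0].L
    if K > sample.M or L > sample.N:
        raise SizeError(f"templates {K}x{L} larger than sample {sample.M}x{sample.N}")

    # Window sums depend only on the sample and (K, L): compute them once.
    f_energy = _window_deviation_energy(sample, K, L)
    nonconstant = f_energy > _ZERO_VAR_EPS
    denom_base = np.sqrt(np.where(nonconstant, f_energy, 1.0))

    best_vals = np.full(f_energy.shape, -np.inf)
    best_idx = np.zeros(f_energy.shape, dtype=np.intp)
    for idx, tpl in enumerate(templates):
        num = _template_numerator(sample, tpl)
        dw = tpl.pixels - tpl.pixels.mean()
        vals = num / (denom_base * np.sqrt(float((dw * dw).sum())))
        vals = np.where(nonconstant, np.clip(vals, -1.0, 1.0), 0.0)
        better = vals > best_vals
        best_vals[better] = vals[better]
        best_idx[better] = idx

    if pattern is None:
        evaluated = np.ones(best_vals.shape, dtype=bool)
    else:
        evaluated = pattern.mask_for_shape(best_vals.shape)
        best_vals = np.where(evaluated, best_vals, 0.0)
    return CorrelationSurface(
        values=best_vals,
        evaluated=evaluated,
        template_ids=tuple(t.id for t in templates),
        best_template=best_idx,
    )
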