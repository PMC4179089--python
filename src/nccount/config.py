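"""Run configuration and pattern resolution for the pipeline and CLI."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .patterns import PRESET_NAMES, SkipPattern, pattern_by_name

__all__ = ["RunConfig", "resolve_pattern"]


def resolve_pattern(spec: "str | None") -> SkipPattern | None:
    """Turn a pattern spec into a mask: ``none``, a preset name, or a file.

    Custom mask files are either JSON (a list of 0/1 rows) or whitespace-free
    text rows of ``0``/``1`` characters.
    """
    if spec is None or spec.lower() in ("none", "full"):
        return None
    if spec.lower() in PRESET_NAMES:
        return pattern_by_name(spec)
    path = Path(spec)
    if not path.exists():
        raise ConfigurationError(
            f"pattern {spec!r} is neither a preset ({', '.join(PRESET_NAMES)}) nor a readable file"
        )
    text = path.read_text().strip()
    if path.suffix == ".json":
        grid = json.loads(text)
    else:
        grid = [[int(ch) for ch in line.strip()] for line in text.splitlines() if line.strip()]
    mask = np.asarray(grid, dtype=int)
    if mask.ndim != 2 or not np.isin(mask, (0, 1)).all():
        raise ConfigurationError(f"custom mask {spec!r} must be a rectangular grid of 0/1")
    return SkipPattern(name=path.stem, mask=mask.astype(bool))


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration shared by the CLI subcommands."""

    threshold: float = 0.67
    pattern: "str | None" = None
    cluster_shape: tuple[int, int] = (3, 3)
    library_path: "str | None" = None
    loss_budget_percent: float = 8.5
    threshold_grid: tuple = tuple(np.round(np.linspace(0.60, 0.67, 8), 4))
    seed: int = 0
    output_dir: str = "nccount-out"

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must lie in [-1, 1], got {self.threshold}")
        m, n = self.cluster_shape
        if m < 1 or n < 1:
            raise ConfigurationError(f"invalid cluster shape {self.cluster_shape}")
        if self.loss_budget_percent < 0:
            raise ConfigurationError("loss budget must be >= 0")
        resolve_pattern(self.pattern)  # fail fast on bad pattern specs

    @property
    def skip_pattern(self) -> SkipPattern | None:
        return resolve_pattern(self.pattern)
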