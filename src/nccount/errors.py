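"""Exception hierarchy shared across the package."""


class CellCountError(Exception):
    """Base class for all nccount errors."""


class ConfigurationError(CellCountError, ValueError):
    """Invalid user-facing configuration (threshold, pattern, library...)."""


class InvalidTemplateError(CellCountError, ValueError):
    """A template violates its invariants (e.g. zero pixel variance)."""


class SizeError(CellCountError, ValueError):
    """Template does not fit inside the sample image."""


class RangeError(CellCountError, IndexError):
    """Sliding-window offset outside the valid (M-K+1)x(N-L+1) grid."""


class GenerationError(CellCountError, RuntimeError):
    """Synthetic scene generation failed (e.g. infeasible cell packing)."""


class InversionError(CellCountError, ValueError):
    """Threshold model cannot be inverted (zero slope)."""
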