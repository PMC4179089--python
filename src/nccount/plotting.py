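"""Small plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["bland_altman"]


def bland_altman(counts_a, counts_b, ax=None):
    """Generic Bland-Altman agreement plot between two count series.

    Plots the per-sample difference against the per-sample mean, with the
    bias line and the 1.96-sigma limits of agreement.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts_a and counts_b must be 1-D arrays of equal length")
    mean = (a + b) / 2.0
    diff = a - b
    bias = float(diff.mean())
    spread = 1.96 * float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=18)
    ax.axhline(bias, color="k", lw=1, label=f"bias {bias:.2f}")
    for lim in (bias + spread, bias - spread):
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of the two counts")
    ax.set_ylabel("difference between counts")
    ax.legend(loc="best")
    return ax
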