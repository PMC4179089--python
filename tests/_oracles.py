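"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: NCC is a
per-pixel double loop over the definition, and connected components is a
plain breadth-first flood fill.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def ncc_brute(sample: np.ndarray, template: np.ndarray, i: int, j: int) -> float:
    """NCC at one offset by explicit per-pixel mean/variance computation."""
    K, L = template.shape
    wsum = fsum = 0.0
    for x in range(K):
        for y in range(L):
            wsum += template[x, y]
            fsum += sample[i + x, j + y]
    wbar = wsum / (K * L)
    fbar = fsum / (K * L)
    num = wvar = fvar = 0.0
    for x in range(K):
        for y in range(L):
            dw = template[x, y] - wbar
            df = sample[i + x, j + y] - fbar
            num += dw * df
            wvar += dw * dw
            fvar += df * df
    if fvar <= 1e-10:
        return 0.0
    return num / math.sqrt(wvar * fvar)


def flood_components(marks: np.ndarray) -> int:
    """Count 8-connected components of a boolean grid by BFS flood fill."""
    marks = np.asarray(marks, dtype=bool)
    seen = np.zeros_like(marks)
    count = 0
    H, W = marks.shape
    for r in range(H):
        for c in range(W):
            if marks[r, c] and not seen[r, c]:
                count += 1
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if 0 <= nr < H and 0 <= nc < W and marks[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                queue.append((nr, nc))
    return count
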