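"""Exhaustive pairwise LD audit used by the acceptance script."""

from __future__ import annotations

import math

import numpy as np


def prune_audit(
    X: np.ndarray, pos: np.ndarray, kept_idx: list[int], window: int, r2_max: float
) -> bool:
    """True iff no kept pair within `window` bp has r^2 > r2_max."""
    for a in range(len(kept_idx)):
        for b in range(a + 1, len(kept_idx)):
            i, j = kept_idx[a], kept_idx[b]
            if abs(pos[j] - pos[i]) > window:
                continue
            xi = X[:, i] - X[:, i].mean()
            xj = X[:, j] - X[:, j].mean()
            den = math.sqrt((xi @ xi) * (xj @ xj))
            if den == 0:
                continue
            if ((xi @ xj) / den) ** 2 > r2_max:
                return False
    return True
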