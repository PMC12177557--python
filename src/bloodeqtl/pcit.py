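"""Co-expression network by Partial Correlation and Information Theory.

PCIT examines every trio of variables (genes, optionally traits).  For a
trio (x, y, z) the first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

are combined into an information-theoretic tolerance

    eps_xyz = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3

and the edge (x, y) is removed when, for *every* third variable z, the
correlation is dominated by the indirect paths:
|r_xy| < |eps * r_xz| and |r_xy| < |eps * r_yz|.  Edges surviving against
at least one z are kept as significant co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcitNetwork", "pcit_network", "partial_correlation"]

_DENOM_TINY = 1e-12


@dataclass
class PcitNetwork:
    """Full correlation matrix plus the kept-edge mask."""

    nodes: list[str]
    corr: np.ndarray
    kept: np.ndarray  # boolean mask, symmetric, False on the diagonal

    def edges(self) -> pd.DataFrame:
        """Long-format edge table: var1, var2, r, kept."""
        n = len(self.nodes)
        rows = [
            {
                "var1": self.nodes[i],
                "var2": self.nodes[j],
                "r": self.corr[i, j],
                "kept": bool(self.kept[i, j]),
            }
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return pd.DataFrame(rows, columns=["var1", "var2", "r", "kept"])


def _pairwise_corr(data: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlations of rows (variables)."""
    n = data.shape[0]
    if not np.isnan(data).any():
        return np.corrcoef(data)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(data[i]) & ~np.isnan(data[j])
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for variables {i}, {j}")
            xi, xj = data[i, ok], data[j, ok]
            if xi.std() == 0 or xj.std() == 0:
                raise ValueError(f"zero variance in pairwise-complete subset ({i}, {j})")
            C[i, j] = C[j, i] = np.corrcoef(xi, xj)[0, 1]
    return C


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z."""
    den = (1 - r_xz**2) * (1 - r_yz**2)
    if den <= 0:
        raise ValueError("|r| = 1 between distinct variables; partial correlation undefined")
    return (r_xy - r_xz * r_yz) / np.sqrt(den)


def _trio_tolerance(C: np.ndarray, x: int, y: int, z: int) -> float:
    """Average ratio of partial to marginal correlation over the trio.

    Ratios whose marginal |r| is below 1e-12 are skipped; if all three
    are skipped the tolerance defaults to 1 (no shrinkage information).
    """
    pairs = ((x, y, z), (x, z, y), (y, z, x))
    ratios = []
    for a, b, c in pairs:
        r_ab = C[a, b]
        if abs(r_ab) < _DENOM_TINY:
            continue
        ratios.append(partial_correlation(r_ab, C[a, c], C[b, c]) / r_ab)
    if not ratios:
        return 1.0
    return float(sum(ratios)) / len(ratios)


def pcit_network(
    data: np.ndarray,
    nodes: list[str] | None = None,
) -> PcitNetwork:
    """Build the PCIT co-expression network of a variables x samples matrix.

    Missing entries are allowed (pairwise-complete correlations).  Raises
    on zero-variance variables and on perfectly correlated pairs, where
    partial correlations are undefined.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 variables")
    if X.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    nodes = nodes if nodes is not None else [f"v{i}" for i in range(X.shape[0])]
    sd = np.nanstd(X, axis=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance variable(s): {[nodes[i] for i in dead]}")

    C = _pairwise_corr(X)
    n = C.shape[0]
    off = np.abs(C - np.eye(n))
    if np.any(off >= 1 - 1e-12):
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"|r| = 1 between {nodes[i]} and {nodes[j]}; partial correlations undefined"
        )

    kept = np.ones((n, n), dtype=bool)
    np.fill_diagonal(kept, False)
    for x in range(n):
        for y in range(x + 1, n):
            removed = True
            for z in range(n):
                if z == x or z == y:
                    continue
                eps = _trio_tolerance(C, x, y, z)
                dominated = abs(C[x, y]) < abs(eps * C[x, z]) and abs(C[x, y]) < abs(
                    eps * C[y, z]
                )
                if not dominated:
                    removed = False
                    break
            if n > 2 and removed:
                kept[x, y] = kept[y, x] = False
    return PcitNetwork(nodes=list(nodes), corr=C, kept=kept)
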