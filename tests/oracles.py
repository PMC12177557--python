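"""Brute-force / closed-form reference implementations used only by tests.

Each oracle re-derives the published rule or formula by the most direct
route available (explicit loops, exhaustive enumeration, linear-space
sums), independently of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def grm_oracle(dosages: np.ndarray) -> np.ndarray:
    """Element-wise double loop over the GRM formula."""
    X = dosages
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    use = [i for i in range(m) if 0 < p[i] < 1]
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            s = 0.0
            for i in use:
                s += (X[j, i] - 2 * p[i]) * (X[k, i] - 2 * p[i]) / (2 * p[i] * (1 - p[i]))
            G[j, k] = s / len(use)
    return G


def tmm_oracle(counts: np.ndarray) -> np.ndarray:
    """Direct evaluation of the trimmed weighted-mean-of-M normalization.

    Written as scalar loops with sort-based trimming, sharing no code
    with the package implementation.
    """
    Y = counts.astype(float)
    G, S = Y.shape
    lib = [sum(Y[:, j]) for j in range(S)]
    q75 = [float(np.quantile(Y[:, j] / lib[j], 0.75)) for j in range(S)]
    mean_q = sum(q75) / S
    ref = min(range(S), key=lambda j: abs(q75[j] - mean_q))

    factors = []
    for j in range(S):
        genes = [g for g in range(G) if Y[g, j] > 0 and Y[g, ref] > 0]
        if not genes:
            factors.append(1.0)
            continue
        M, A, W = {}, {}, {}
        for g in genes:
            po, pr = Y[g, j] / lib[j], Y[g, ref] / lib[ref]
            M[g] = math.log2(po / pr)
            A[g] = 0.5 * (math.log2(po) + math.log2(pr))
            W[g] = (lib[j] - Y[g, j]) / (lib[j] * Y[g, j]) + (lib[ref] - Y[g, ref]) / (
                lib[ref] * Y[g, ref]
            )
        if max(abs(M[g]) for g in genes) < 1e-6:
            factors.append(1.0)
            continue
        n = len(genes)
        lo_m = math.floor(n * 0.30) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        def avg_ranks(vals: dict) -> dict:
            """1-based ranks with ties sharing their average rank."""
            ordered = sorted(vals, key=lambda g: vals[g])
            ranks = {}
            i = 0
            while i < len(ordered):
                j = i
                while j + 1 < len(ordered) and vals[ordered[j + 1]] == vals[ordered[i]]:
                    j += 1
                r = (i + 1 + j + 1) / 2.0
                for k in range(i, j + 1):
                    ranks[ordered[k]] = r
                i = j + 1
            return ranks

        rank_m = avg_ranks(M)
        rank_a = avg_ranks(A)
        kept = [
            g
            for g in genes
            if lo_m <= rank_m[g] <= hi_m and lo_a <= rank_a[g] <= hi_a
        ]
        if not kept:
            factors.append(1.0)
            continue
        num = sum(M[g] / W[g] for g in kept)
        den = sum(1.0 / W[g] for g in kept)
        factors.append(2.0 ** (num / den))
    gm = math.exp(sum(math.log(f) for f in factors) / S)
    return np.array([f / gm for f in factors])


def region_oracle(
    positions: list[int],
    pvals: list[float],
    gap: int = 1_000_000,
    min_snps: int = 3,
    ext: int = 500_000,
) -> list[dict]:
    """Gap-scan re-implementation of eQTL region grouping (one chromosome)."""
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    clusters: list[list[int]] = []
    for i in order:
        if clusters and positions[i] - positions[clusters[-1][-1]] < gap:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    out = []
    for cl in clusters:
        if len(cl) < min_snps:
            continue
        best = min(cl, key=lambda i: (pvals[i], positions[i]))
        out.append(
            {
                "core_start": positions[cl[0]],
                "core_end": positions[cl[-1]],
                "ext_start": max(positions[cl[0]] - ext, 1),
                "ext_end": positions[cl[-1]] + ext,
                "n_snps": len(cl),
                "top_idx": best,
            }
        )
    return out


def overlap_oracle(qtls: list[tuple], regions: list[tuple]) -> set[tuple]:
    """Quadratic closed-interval intersection; tuples (name, chrom, start, end)."""
    pairs = set()
    for qn, qc, qs, qe in qtls:
        for rn, rc, rs, re_ in regions:
            if qc == rc and qs <= re_ and rs <= qe:
                pairs.add((qn, rn))
    return pairs


def pcit_oracle(data: np.ndarray) -> np.ndarray:
    """Independent triple-loop PCIT: returns the kept-edge boolean mask."""
    C = np.corrcoef(data)
    n = C.shape[0]
    kept = np.ones((n, n), dtype=bool)
    np.fill_diagonal(kept, False)

    def pc(a, b, c):
        return (C[a, b] - C[a, c] * C[b, c]) / math.sqrt(
            (1 - C[a, c] ** 2) * (1 - C[b, c] ** 2)
        )

    for x in range(n):
        for y in range(x + 1, n):
            dominated_everywhere = True
            for z in range(n):
                if z in (x, y):
                    continue
                ratios = []
                for a, b, c in ((x, y, z), (x, z, y), (y, z, x)):
                    if abs(C[a, b]) >= 1e-12:
                        ratios.append(pc(a, b, c) / C[a, b])
                eps = sum(ratios) / len(ratios) if ratios else 1.0
                if not (
                    abs(C[x, y]) < abs(eps * C[x, z]) and abs(C[x, y]) < abs(eps * C[y, z])
                ):
                    dominated_everywhere = False
                    break
            if n > 2 and dominated_everywhere:
                kept[x, y] = kept[y, x] = False
    return kept


def coloc_enum_oracle(
    l1: np.ndarray, l2: np.ndarray, p1: float, p2: float, p12: float
) -> np.ndarray:
    """Log evidence of H0..H4 by explicit enumeration of causal configs.

    Linear-space sums over all single-SNP (H1, H2, H4) and ordered
    distinct-pair (H3) configurations; valid for small |logABF|.
    """
    b1 = np.exp(l1)
    b2 = np.exp(l2)
    n = len(b1)
    e1 = p1 * sum(b1[i] for i in range(n))
    e2 = p2 * sum(b2[j] for j in range(n))
    e3 = p1 * p2 * sum(b1[i] * b2[j] for i in range(n) for j in range(n) if i != j)
    e4 = p12 * sum(b1[i] * b2[i] for i in range(n))
    return np.array([0.0, math.log(e1), math.log(e2), math.log(e3) if e3 > 0 else -math.inf, math.log(e4)])


def credible_oracle(post: np.ndarray, coverage: float = 0.95) -> list[int]:
    """Minimal descending-prefix search for the credible set (index ties by order)."""
    order = sorted(range(len(post)), key=lambda i: (-post[i], i))
    total = 0.0
    out = []
    for i in order:
        out.append(i)
        total += post[i]
        if total >= coverage:
            break
    return out


def prune_audit(X: np.ndarray, pos: np.ndarray, kept_idx: list[int], window: int, r2_max: float) -> bool:
    """Exhaustive check: no kept pair within `window` bp has r^2 > r2_max."""
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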