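"""Variant-level QC, windowed LD pruning and the Bonferroni threshold.

The pruning routine reduces the marker panel to an approximately
independent subset: within 0.5 Mb windows, one member of every pair with
r^2 above the cut-off is removed, and the surviving count feeds the
Bonferroni correction (alpha / n_independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "PruneParams",
    "filter_variants",
    "ld_prune",
    "bonferroni_threshold",
    "pairwise_r2",
]


@dataclass
class PruneParams:
    """Windowed-pruning parameters: 0.5 Mb window, r^2 cut-off 0.7,
    sidestep of 10 (retained) SNPs."""

    window: int = 500_000
    r2_max: float = 0.7
    step: int = 10

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must be in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def filter_variants(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants with MAF < maf_min or missing fraction > miss_max.

    MAF is computed on non-missing calls; the missingness rule is strict
    ('more than 10%'), so exactly 10% missing is kept.  All-missing
    variants are dropped with reason ``all-missing``.  Returns the
    filtered matrix and a per-variant report (id, maf, miss, reason; the
    reason is empty for retained variants).
    """
    maf = geno.maf()
    miss = geno.missing_fraction()
    reason = np.full(geno.n_variants, "", dtype=object)
    reason[miss > miss_max] = "missingness"
    reason[np.nan_to_num(maf, nan=0.0) < maf_min] = "maf"
    reason[np.isnan(maf)] = "all-missing"
    keep = reason == ""
    report = pd.DataFrame(
        {"id": geno.variants["id"], "maf": maf, "missing": miss, "reason": reason}
    )
    return geno.take_variants(np.nonzero(keep)[0]), report


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two (mean-imputed) dosage vectors."""
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return 0.0
    return float((xc @ yc) / den) ** 2


def _prune_pass(
    X: np.ndarray,
    pos: np.ndarray,
    maf: np.ndarray,
    kept: list[int],
    params: PruneParams,
    step: int,
) -> tuple[list[int], bool]:
    """One sweep of greedy windowed pruning over the kept list.

    Windows are anchored at kept variants and span ``params.window`` bp;
    within a window the later-positioned member of each violating pair is
    removed (equal positions: the lower-MAF member).  The anchor advances
    by ``step`` kept variants.
    """
    removed_any = False
    alive = dict.fromkeys(kept, True)
    order = list(kept)
    i = 0
    while i < len(order):
        a = order[i]
        if not alive[a]:
            i += 1
            continue
        window_ids = []
        for j in order[i:]:
            if pos[j] > pos[a] + params.window:
                break
            if alive[j]:
                window_ids.append(j)
        changed = True
        while changed:
            changed = False
            live = [j for j in window_ids if alive[j]]
            for u in range(len(live)):
                for v in range(u + 1, len(live)):
                    j, k = live[u], live[v]
                    if not (alive[j] and alive[k]):
                        continue
                    if pairwise_r2(X[:, j], X[:, k]) > params.r2_max:
                        if pos[j] == pos[k] and maf[j] < maf[k]:
                            drop = j
                        else:
                            drop = k  # later-positioned (lists are position-sorted)
                        alive[drop] = False
                        removed_any = True
                        changed = True
        # advance anchor by `step` still-alive variants
        advanced = 0
        while i < len(order) and advanced < step:
            i += 1
            if i < len(order) and alive[order[i]]:
                advanced += 1
    return [j for j in order if alive[j]], removed_any


def ld_prune(geno: GenotypeMatrix, params: PruneParams | None = None) -> list[str]:
    """Greedy windowed LD pruning; returns surviving variant ids.

    Sweeps with the configured sidestep repeat until stable, then a final
    step-1 audit sweep enforces the postcondition that no surviving pair
    within any window has r^2 above the cut-off.  Processing is per
    chromosome; positions must be sorted within each chromosome.
    """
    params = params or PruneParams()
    X = geno.mean_imputed()
    pos = geno.variants["pos"].to_numpy()
    chrom = geno.variants["chrom"].to_numpy()
    maf = np.nan_to_num(geno.maf(), nan=0.0)

    survivors: list[int] = []
    for c in pd.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError(f"positions unsorted on chromosome {c}")
        kept = list(idx)
        while True:
            kept, removed = _prune_pass(X, pos, maf, kept, params, params.step)
            if not removed:
                break
        kept, _ = _prune_pass(X, pos, maf, kept, params, 1)
        survivors.extend(kept)

    ids = geno.variants["id"].to_numpy()
    return [str(ids[i]) for i in sorted(survivors)]


def bonferroni_threshold(alpha: float, n_independent: int) -> float:
    """Per-test significance threshold alpha / n_independent."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    return alpha / n_independent
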