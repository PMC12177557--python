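"""Bayesian colocalization of two association scans over one region.

Given per-SNP effect estimates and standard errors from a trait GWAS and
a gene's eQTL scan over the same variant panel, each SNP's evidence of
association is summarized by a Wakefield approximate Bayes factor; the
five-hypothesis posterior is then

    H0  no causal variant for either trait
    H1  causal variant for trait 1 only
    H2  causal variant for trait 2 only
    H3  two distinct causal variants
    H4  one shared causal variant

assuming at most one causal variant per trait in the region.
Colocalization is typically declared at PP(H4) > 0.95; probabilities are
emitted as fractions in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocPriors", "ColocResult", "log_abf", "coloc_posteriors", "credible_set", "coloc_scans"]


@dataclass
class ColocPriors:
    """Per-SNP priors: p1/p2 causal for trait 1/2 only, p12 shared."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= p1, p2 < 1")

    def check_region(self, n_snps: int) -> None:
        if n_snps * (self.p1 + self.p2 + self.p12) >= 1:
            raise ValueError("priors too large for region SNP count (probabilities exceed 1)")


@dataclass
class ColocResult:
    """Posterior probabilities, per-SNP shared-causal posteriors, credible set."""

    pp: pd.Series  # index PP.H0 .. PP.H4
    snp_h4: pd.Series  # per-SNP posterior under H4, indexed by variant id
    credible: list[str] = field(default_factory=list)
    n_snps: int = 0


def log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float = 0.15) -> np.ndarray:
    """Wakefield log approximate Bayes factor (association vs null).

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se:
    log ABF = 0.5 log(1 - r) + z^2 r / 2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + (z**2) * r / 2.0


def coloc_posteriors(
    l1: np.ndarray,
    l2: np.ndarray,
    priors: ColocPriors | None = None,
    variant_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
    coverage: float = 0.95,
) -> ColocResult:
    """Five-hypothesis posterior from aligned per-SNP log ABFs.

    ``l1`` and ``l2`` must be aligned on the same variants.  All sums run
    in log space; the H3 evidence uses log(exp(S1+S2) - exp(S12)) over
    the sums S1, S2, S12 of the single- and joint-SNP Bayes factors.
    """
    priors = priors or ColocPriors()
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("log-ABF vectors must be aligned 1-D arrays")
    n = l1.size
    if n == 0:
        raise ValueError("zero shared SNPs in region")
    priors.check_region(n)

    S1 = logsumexp(l1)
    S2 = logsumexp(l2)
    S12 = logsumexp(l1 + l2)

    # H3 = sum over ordered pairs i != j of BF1_i * BF2_j
    if S12 >= S1 + S2:
        if n > 1 and S12 > S1 + S2 + 1e-12:
            warnings.warn("H3 evidence numerically negative; floored at -inf")
        h3_ev = -np.inf if n == 1 else -np.inf
    else:
        h3_ev = (S1 + S2) + np.log1p(-np.exp(S12 - (S1 + S2)))

    ev = np.array(
        [
            0.0,
            np.log(priors.p1) + S1,
            np.log(priors.p2) + S2,
            np.log(priors.p1) + np.log(priors.p2) + h3_ev,
            np.log(priors.p12) + S12,
        ]
    )
    denom = logsumexp(ev[np.isfinite(ev)])
    pp = np.where(np.isfinite(ev), np.exp(ev - denom), 0.0)
    pp = pp / pp.sum()

    joint = l1 + l2
    snp_post = np.exp(joint - logsumexp(joint))
    ids = variant_ids if variant_ids is not None else [f"snp{i}" for i in range(n)]
    snp_h4 = pd.Series(snp_post, index=ids)
    cs = credible_set(snp_post, ids, positions=positions, coverage=coverage)
    return ColocResult(
        pp=pd.Series(pp, index=[f"PP.H{i}" for i in range(5)]),
        snp_h4=snp_h4,
        credible=cs,
        n_snps=n,
    )


def credible_set(
    posterior: np.ndarray,
    variant_ids: list[str],
    positions: np.ndarray | None = None,
    coverage: float = 0.95,
) -> list[str]:
    """Smallest descending-posterior prefix with cumulative mass >=
    ``coverage``; posterior ties broken by genomic position."""
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    post = np.asarray(posterior, dtype=float)
    if abs(post.sum() - 1.0) > 1e-8:
        raise ValueError("posterior vector must sum to 1 within 1e-8")
    tie = positions if positions is not None else np.arange(post.size)
    order = np.lexsort((np.asarray(tie), -post))
    cum = np.cumsum(post[order])
    k = int(np.searchsorted(cum, coverage - 1e-15)) + 1
    return [variant_ids[i] for i in order[:k]]


def coloc_scans(
    scan1: pd.DataFrame,
    scan2: pd.DataFrame,
    priors: ColocPriors | None = None,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    region: tuple[str, int, int] | None = None,
    coverage: float = 0.95,
) -> ColocResult:
    """Colocalize two association tables (columns id, chrom, pos, beta, se).

    Variants are inner-joined on id; an optional ``region``
    (chrom, start, end) restricts both scans first.  Degenerate records
    (missing or non-positive se) are dropped before the join.
    """

    def prep(df: pd.DataFrame) -> pd.DataFrame:
        d = df.copy()
        if region is not None:
            chrom, start, end = region
            d = d[(d["chrom"].astype(str) == str(chrom)) & d["pos"].between(start, end)]
        d = d[np.isfinite(d["se"]) & (d["se"] > 0)]
        return d.drop_duplicates(subset="id")

    a = prep(scan1)
    b = prep(scan2)
    merged = a.merge(b, on="id", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("zero shared SNPs between the two scans")
    merged = merged.sort_values("pos_1", kind="mergesort").reset_index(drop=True)
    l1 = log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), prior_sd1)
    l2 = log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), prior_sd2)
    return coloc_posteriors(
        l1,
        l2,
        priors=priors,
        variant_ids=merged["id"].tolist(),
        positions=merged["pos_1"].to_numpy(),
        coverage=coverage,
    )
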