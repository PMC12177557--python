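"""Count normalization and expression-level filtering.

Implements TMM (trimmed mean of M-values) between-sample scaling,
log2-cpm transformation with the raw-zero -> missing rule, the
low-expression filter (cpm above 10 / min library size in millions in
more than 35% of samples), and leave-one-out Shapiro-Wilk outlier
masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "tmm_factors",
    "log_cpm",
    "filter_genes",
    "remove_outliers",
    "NormalizationResult",
    "normalize_counts",
]


@dataclass
class NormalizationResult:
    """Output bundle of the normalization + filtering chain."""

    factors: np.ndarray  # per-sample TMM factor, geometric mean 1
    effective_libsize: np.ndarray  # library size x factor
    log2cpm: ExpressionMatrix  # retained genes only, missing mask propagated
    filter_report: pd.DataFrame  # gene, pass_fraction, retained
    outliers: pd.DataFrame  # gene, sample masked by the normality screen


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> float:
    """TMM factor of one column against the reference column.

    M (log2 expression ratio) and A (mean log2 abundance) are computed
    over genes positive in both columns; 30% of each M tail and 5% of
    each A tail are trimmed; the factor is 2**(weighted mean of the
    remaining M) with inverse delta-method binomial variances as weights.
    """
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    if np.max(np.abs(M)) < 1e-6:  # identical profiles up to depth
        return 1.0

    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: ExpressionMatrix) -> np.ndarray:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the column whose 75th-percentile cpm is
    closest to the mean 75th percentile across samples.
    """
    Y = np.asarray(counts.values, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("tmm_factors expects raw counts without missing values")
    if (Y < 0).any():
        raise ValueError("negative counts")
    if Y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = Y.sum(axis=0)
    zero_lib = np.nonzero(lib == 0)[0]
    if zero_lib.size:
        raise ValueError(f"sample(s) with all-zero counts: {[counts.samples[i] for i in zero_lib]}")

    q75 = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = Y[:, ref_idx]

    f = np.array(
        [_tmm_pair(Y[:, j], ref, lib[j], lib[ref_idx]) for j in range(Y.shape[1])]
    )
    f = f / np.exp(np.mean(np.log(f)))  # geometric mean 1
    return f


def log_cpm(counts: ExpressionMatrix, factors: np.ndarray, prior: float = 0.0) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    Raw zeros become missing (NA) *before* the transform, so no -inf is
    produced and no pseudo-count is needed by default.
    """
    Y = np.asarray(counts.values, dtype=float)
    if (Y < 0).any():
        raise ValueError("negative counts")
    lib = np.nansum(Y, axis=0)
    eff = lib * np.asarray(factors, dtype=float)
    vals = np.where(Y == 0, np.nan, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        cpm = vals / eff[None, :] * 1e6
        out = np.log2(cpm + prior)
    return ExpressionMatrix(values=out, genes=list(counts.genes), samples=list(counts.samples))


def filter_genes(
    log2cpm: ExpressionMatrix,
    min_lib_millions: float,
    min_fraction: float = 0.35,
) -> pd.DataFrame:
    """Low-expression filter: keep genes with cpm > 10 / L_min in more
    than ``min_fraction`` of samples.

    The threshold is on the cpm scale (t = 10 / min library size in
    millions); values are compared on the log2 scale.  The pass fraction
    is computed over non-missing entries; the '> 35%' rule is strict, so
    a gene passing in exactly 35% of samples is removed.

    Returns a per-gene report with columns ``gene, pass_fraction,
    retained``.
    """
    if min_lib_millions <= 0:
        raise ValueError("min_lib_millions must be positive")
    V = log2cpm.values
    if V.size == 0:
        raise ValueError("empty expression matrix")
    t = np.log2(10.0 / min_lib_millions)
    ok = ~np.isnan(V)
    n_ok = ok.sum(axis=1)
    n_pass = np.sum((V > t) & ok, axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_ok > 0, n_pass / np.maximum(n_ok, 1), 0.0)
    retained = frac > min_fraction
    return pd.DataFrame(
        {"gene": log2cpm.genes, "pass_fraction": frac, "retained": retained}
    )


def remove_outliers(
    values: np.ndarray,
    alpha_sw: float = 0.01,
    max_removals: int = 3,
) -> tuple[np.ndarray, list[int]]:
    """Leave-one-out Shapiro-Wilk outlier masking for one gene.

    If the Shapiro-Wilk p-value of the non-missing values is >= alpha_sw
    the vector is returned unchanged.  Otherwise the sample whose removal
    maximizes the leave-one-out p-value is masked, provided that best p
    reaches alpha_sw; this repeats up to ``max_removals`` times.

    Returns the cleaned vector (masked entries set to nan) and the list
    of masked sample indices.
    """
    x = np.asarray(values, dtype=float).copy()
    removed: list[int] = []
    for _ in range(max_removals):
        idx = np.nonzero(~np.isnan(x))[0]
        if idx.size < 8:
            raise ValueError("need at least 8 non-missing values for the normality screen")
        p_full = stats.shapiro(x[idx]).pvalue
        if p_full >= alpha_sw:
            break
        loo_p = np.empty(idx.size)
        for k in range(idx.size):
            loo_p[k] = stats.shapiro(np.delete(x[idx], k)).pvalue
        best = int(np.argmax(loo_p))
        if loo_p[best] < alpha_sw:
            break  # no single sample explains the non-normality
        x[idx[best]] = np.nan
        removed.append(int(idx[best]))
    return x, removed


def normalize_counts(
    counts: ExpressionMatrix,
    min_lib_millions: float | None = None,
    min_fraction: float = 0.35,
    alpha_sw: float = 0.01,
    max_removals: int = 3,
    outlier_screen: bool = True,
) -> NormalizationResult:
    """Full chain: TMM -> log2-cpm (zeros -> NA) -> expression filter ->
    per-gene leave-one-out normality screen.

    ``min_lib_millions`` defaults to the smallest observed library size
    in millions, reproducing the 10 / L_min rule on the data at hand.
    """
    factors = tmm_factors(counts)
    lib = np.asarray(counts.values).sum(axis=0)
    if min_lib_millions is None:
        min_lib_millions = float(lib.min() / 1e6)
    lc = log_cpm(counts, factors)
    report = filter_genes(lc, min_lib_millions, min_fraction)
    keep = report["retained"].to_numpy()
    vals = lc.values[keep]
    genes = [g for g, k in zip(lc.genes, keep) if k]

    outlier_rows = []
    if outlier_screen:
        for i, g in enumerate(genes):
            n_ok = int(np.sum(~np.isnan(vals[i])))
            if n_ok < 8:
                continue
            cleaned, removed = remove_outliers(vals[i], alpha_sw, max_removals)
            vals[i] = cleaned
            outlier_rows.extend({"gene": g, "sample": lc.samples[j]} for j in removed)

    return NormalizationResult(
        factors=factors,
        effective_libsize=lib * factors,
        log2cpm=ExpressionMatrix(values=vals, genes=genes, samples=list(lc.samples)),
        filter_report=report,
        outliers=pd.DataFrame(outlier_rows, columns=["gene", "sample"]),
    )
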