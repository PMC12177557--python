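"""Synthetic genotype / expression / trait generator with planted truth.

The generator emulates the data structure of a genotyped, blood-RNA-seq'd
outbred pig cohort: LD-structured biallelic SNPs on an autosome,
negative-binomially distributed gene counts with library-size variation,
planted cis effects near gene TSSs, trans hotspot variants driving many
genes, polygenic background through the genomic relationship matrix, and
quantitative traits optionally sharing a causal variant with a gene's
expression.  Every planted effect is recorded in a :class:`TruthTable` so
downstream stages have a recoverable answer.

LD model
--------
Each diploid individual is two mosaics of ``n_founder_haplotypes`` founder
haplotypes.  Mosaic blocks have exponentially distributed physical lengths
(mean ``block_length_mean``); within a block the individual copies one
founder haplotype chosen uniformly.  This produces blockwise r^2 = 1
structure with decay across block boundaries, the regime that windowed LD
pruning and top-SNP tie-breaking need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneTable, GenotypeMatrix


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design this package targets: 255 samples,
    MAF >= 0.05 biallelic SNPs, six batches, balanced sexes.
    """

    n_samples: int = 255
    n_variants: int = 2000
    chrom_length: int = 50_000_000
    n_founder_haplotypes: int = 30
    block_length_mean: float = 500_000.0
    maf_min: float = 0.05
    n_genes: int = 100
    cis_fraction: float = 0.5
    cis_beta_sd: float = 0.6
    cis_beta_fixed: float | None = None  # when set: planted cis betas are +/- this value
    # when set: per-gene cis beta is scaled so the causal variant explains
    # (approximately) this fraction of the gene's log2-expression variance
    cis_r2_target: float | None = None
    hotspot_spec: list[tuple[int, int, float]] = field(default_factory=list)
    h2_polygenic: float = 0.2
    libsize_range: tuple[float, float] = (20e6, 60e6)
    nb_dispersion: float = 0.05
    seed: int = 0
    # beyond the core design: founder-allele persistence length (bp) that
    # creates high-LD blocks, missing-call injection, residual log2 noise
    ld_decay: float = 300_000.0
    missing_rate: float = 0.01
    log_resid_sd: float = 0.4
    n_batches: int = 6
    chrom: str = "1"

    def validate(self) -> None:
        if not (0 < self.maf_min <= 0.5):
            raise ValueError("maf_min must be in (0, 0.5]")
        if not (0 <= self.h2_polygenic < 1):
            raise ValueError("h2_polygenic must be in [0, 1)")
        for name in ("n_samples", "n_variants", "chrom_length", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes < 2: no polymorphism possible")
        if not (0 <= self.cis_fraction <= 1):
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hotspot_spec"] = [list(h) for h in self.hotspot_spec]
        d["libsize_range"] = list(self.libsize_range)
        return d


@dataclass
class TruthTable:
    """Planted regulatory architecture of one simulated dataset.

    cis_effects : per-gene causal variant id and log2-scale effect.
    hotspots    : per-hotspot variant id and its target gene list.
    traits      : per-trait causal variant id and effect.
    """

    cis_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "variant", "beta"])
    )
    hotspots: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant", "genes", "beta"])
    )
    traits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trait", "variant", "effect"])
    )

    def validate_against(self, geno: GenotypeMatrix) -> None:
        """Every causal variant id must resolve in the genotype matrix."""
        known = set(geno.variants["id"])
        planted = set(self.cis_effects["variant"]) | set(self.hotspots["variant"]) | set(
            self.traits["variant"]
        )
        unknown = planted - known
        if unknown:
            raise ValueError(f"truth table references unknown variants: {sorted(unknown)}")


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    positions: np.ndarray,
    n_haplotypes: int,
    block_length_mean: float,
    chrom_length: int,
) -> np.ndarray:
    """Draw ``n_haplotypes`` founder mosaics over the given variant positions."""
    n_founders, n_variants = founders.shape
    out = np.empty((n_haplotypes, n_variants), dtype=np.int8)
    for h in range(n_haplotypes):
        pos = 0.0
        breaks = [0.0]
        while pos < chrom_length:
            pos += rng.exponential(block_length_mean)
            breaks.append(pos)
        breaks = np.asarray(breaks)
        # founder choice per block, then map variants to blocks
        choice = rng.integers(0, n_founders, size=len(breaks))
        block_of_variant = np.searchsorted(breaks, positions, side="right") - 1
        out[h] = founders[choice[block_of_variant], np.arange(n_variants)]
    return out


def _draw_positions(rng: np.random.Generator, chrom_length: int, n: int) -> np.ndarray:
    """Sorted distinct 1-based positions, without materializing the range."""
    if n > chrom_length:
        raise ValueError("more variants than base pairs")
    pos: np.ndarray = np.unique(rng.integers(1, chrom_length + 1, size=2 * n))
    while pos.size < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, chrom_length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate an LD-structured biallelic dosage matrix.

    Variants whose realized sample MAF falls below ``cfg.maf_min`` are
    dropped (the founder frequency spectrum is drawn wide enough that most
    survive).  Missing calls are injected at ``cfg.missing_rate`` after
    the MAF screen, so the screen itself sees complete data.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    positions = _draw_positions(rng, cfg.chrom_length, cfg.n_variants)
    # founder allele frequencies away from the boundaries so sample MAF >= maf_min is common
    founder_freq = rng.uniform(max(cfg.maf_min * 2, 0.15), 0.85, size=cfg.n_variants)
    # founder alleles persist along the chromosome (Markov chain with
    # persistence length ld_decay), so nearby variants sit on shared
    # ancestral backgrounds and form high-r^2 blocks
    K = cfg.n_founder_haplotypes
    founders = np.empty((K, cfg.n_variants), dtype=np.int8)
    founders[:, 0] = rng.random(K) < founder_freq[0]
    for i in range(1, cfg.n_variants):
        p_switch = 1.0 - np.exp(-(positions[i] - positions[i - 1]) / cfg.ld_decay)
        switch = rng.random(K) < p_switch
        fresh = rng.random(K) < founder_freq[i]
        founders[:, i] = np.where(switch, fresh, founders[:, i - 1])

    haps = _mosaic_haplotypes(
        rng, founders, positions, 2 * cfg.n_samples, cfg.block_length_mean, cfg.chrom_length
    )
    dosages = (haps[0::2] + haps[1::2]).astype(float)

    p = dosages.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = maf >= cfg.maf_min
    dosages = dosages[:, keep]
    positions = positions[keep]

    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan

    n_kept = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": positions,
            "id": [f"snp_{cfg.chrom}_{p}" for p in positions],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"s{i:04d}" for i in range(cfg.n_samples)]
    geno = GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)
    # realized founder-pool allele frequency per kept variant, for
    # allele-frequency-recovery diagnostics
    geno.founder_allele_freq = founders.mean(axis=0)[keep]  # type: ignore[attr-defined]
    return geno


def simulate_covariates(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sex (0/1, balanced) and batch (categorical) per sample."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    sex = np.zeros(cfg.n_samples, dtype=int)
    sex[: cfg.n_samples // 2] = 1
    rng.shuffle(sex)
    batch = rng.integers(0, cfg.n_batches, size=cfg.n_samples)
    return pd.DataFrame(
        {"sample": [f"s{i:04d}" for i in range(cfg.n_samples)], "sex": sex, "batch": batch}
    )


def _polygenic_draws(
    rng: np.random.Generator, geno: GenotypeMatrix, n_draws: int
) -> np.ndarray:
    """Draw ``n_draws`` vectors from N(0, G) with G the Yang-style GRM,
    each standardized to unit empirical variance (zeros if degenerate)."""
    from .assoc import compute_grm

    G = compute_grm(geno).matrix
    vals, vecs = np.linalg.eigh(G)
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    draws = root @ rng.standard_normal((len(vals), n_draws))
    sd = draws.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return draws / sd


def simulate_expression(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    covariates: pd.DataFrame,
) -> tuple[ExpressionMatrix, GeneTable, TruthTable]:
    """Simulate NB-distributed counts with planted cis/trans architecture.

    Counts for gene g in sample j are NegBin with mean
    ``libsize_j / 1e6 * 2**eta_gj`` and dispersion ``cfg.nb_dispersion``
    (variance = m + disp * m^2), where ``eta`` collects the baseline
    log2-cpm, planted cis and hotspot effects, sex/batch effects, the
    polygenic term and residual log2 noise.  Planted betas are therefore
    directly on the log2-cpm analysis scale.
    """
    cfg.validate()
    if geno.n_samples != len(covariates):
        raise ValueError("genotype sample count does not match covariate rows")
    for idx, _, _ in cfg.hotspot_spec:
        if not (0 <= idx < geno.n_variants):
            raise ValueError(f"hotspot_spec variant index {idx} outside genotype matrix")

    rng = np.random.default_rng(cfg.seed + 2)
    n, m = geno.n_samples, geno.n_variants
    pos = geno.variants["pos"].to_numpy()
    vid = geno.variants["id"].to_numpy()

    # gene bodies: TSS uniform, modest gene length
    tss = np.sort(rng.integers(1, cfg.chrom_length, size=cfg.n_genes))
    length = rng.integers(5_000, 100_000, size=cfg.n_genes)
    genes = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    gene_table = GeneTable(
        pd.DataFrame(
            {
                "gene": genes,
                "chrom": cfg.chrom,
                "start": tss,
                "end": np.minimum(tss + length, cfg.chrom_length),
                "strand": rng.choice(["+", "-"], size=cfg.n_genes),
            }
        )
    )

    X = geno.mean_imputed()
    Xc = X - X.mean(axis=0)

    eta = np.empty((cfg.n_genes, n))
    base = rng.normal(5.0, 1.5, size=cfg.n_genes)  # baseline log2-cpm
    sex_eff = rng.normal(0.0, 0.1, size=cfg.n_genes)
    batch_eff = rng.normal(0.0, 0.1, size=(cfg.n_genes, cfg.n_batches))
    sex = covariates["sex"].to_numpy()
    batch = covariates["batch"].to_numpy().astype(int)

    eta[:] = base[:, None] + sex_eff[:, None] * sex[None, :] + batch_eff[:, batch]

    # polygenic background, scaled against residual log2 noise
    if cfg.h2_polygenic > 0 and cfg.log_resid_sd > 0:
        u = _polygenic_draws(rng, geno, cfg.n_genes).T  # genes x samples
        sigma_u = cfg.log_resid_sd * np.sqrt(cfg.h2_polygenic / (1 - cfg.h2_polygenic))
        eta += sigma_u * u
    eta += rng.normal(0.0, cfg.log_resid_sd, size=(cfg.n_genes, n))

    # planted trans hotspots (before cis, so cis calibration can account
    # for any hotspot effect already on the gene)
    hot_rows = []
    for v_idx, n_targets, beta in cfg.hotspot_spec:
        far = np.nonzero(np.abs(tss - pos[v_idx]) > 2_000_000)[0]
        if far.size < n_targets:
            raise ValueError("not enough distal genes for requested hotspot targets")
        targets = rng.choice(far, size=n_targets, replace=False)
        for g in targets:
            sign = rng.choice([-1.0, 1.0])
            eta[g] += sign * beta * Xc[:, v_idx]
        hot_rows.append(
            {"variant": vid[v_idx], "genes": ",".join(genes[g] for g in sorted(targets)), "beta": beta}
        )

    # planted cis effects: causal variant within 1 Mb of the TSS
    cis_rows = []
    n_cis = int(round(cfg.cis_fraction * cfg.n_genes))
    cis_genes = rng.choice(cfg.n_genes, size=n_cis, replace=False) if n_cis else np.array([], int)
    lib_mean = 0.5 * (cfg.libsize_range[0] + cfg.libsize_range[1])
    for g in cis_genes:
        near = np.nonzero(np.abs(pos - tss[g]) <= 1_000_000)[0]
        if near.size == 0:
            continue
        v = int(rng.choice(near))
        if cfg.cis_r2_target is not None:
            # calibrate beta against the gene's realized non-cis log2
            # variance plus the delta-method NB counting noise, so the
            # variant explains ~cis_r2_target of the expression variance
            r2t = cfg.cis_r2_target
            m_bar = lib_mean / 1e6 * 2.0 ** base[g]
            nb_var = (1.0 / m_bar + cfg.nb_dispersion) / np.log(2) ** 2
            noise = float(np.var(eta[g])) + nb_var
            var_x = Xc[:, v].var()
            beta = float(rng.choice([-1.0, 1.0]) * np.sqrt(r2t / (1 - r2t) * noise / var_x))
        elif cfg.cis_beta_fixed is not None:
            beta = float(rng.choice([-1.0, 1.0]) * cfg.cis_beta_fixed)
        else:
            beta = rng.normal(0.0, cfg.cis_beta_sd)
        eta[g] += beta * Xc[:, v]
        cis_rows.append({"gene": genes[g], "variant": vid[v], "beta": beta})

    libsize = rng.uniform(cfg.libsize_range[0], cfg.libsize_range[1], size=n)
    mean = libsize[None, :] / 1e6 * np.exp2(eta)
    r = 1.0 / cfg.nb_dispersion  # NB shape: var = m + disp*m^2
    counts = rng.negative_binomial(r, r / (r + mean)).astype(float)

    expr = ExpressionMatrix(values=counts, genes=genes, samples=list(geno.samples))
    truth = TruthTable(
        cis_effects=pd.DataFrame(cis_rows, columns=["gene", "variant", "beta"]),
        hotspots=pd.DataFrame(hot_rows, columns=["variant", "genes", "beta"]),
    )
    truth.validate_against(geno)
    return expr, gene_table, truth


def simulate_trait(
    geno: GenotypeMatrix,
    shared_variant: str | None,
    effect: float,
    h2: float,
    seed: int,
) -> np.ndarray:
    """Quantitative trait = effect * dosage + polygenic + residual, unit variance.

    ``shared_variant`` is a variant id in ``geno`` (or None for no direct
    effect).  The polygenic term follows N(0, G); component variances are
    set so the polygenic fraction of the non-SNP variance equals ``h2``.
    The returned vector is standardized to mean 0, variance 1 (the SNP
    effect is applied on the standardized-residual scale, so ``effect`` is
    in residual-SD units per alt allele before the final standardization).
    """
    if not (0 <= h2 < 1):
        raise ValueError("h2 must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = geno.n_samples

    y = rng.standard_normal(n) * np.sqrt(1 - h2)
    if h2 > 0:
        u = _polygenic_draws(rng, geno, 1)[:, 0]
        y = y + np.sqrt(h2) * u
    if shared_variant is not None and effect != 0.0:
        idx = np.nonzero(geno.variants["id"].to_numpy() == shared_variant)[0]
        if idx.size == 0:
            raise ValueError(f"shared_variant {shared_variant!r} not in genotype matrix")
        x = geno.mean_imputed()[:, idx[0]]
        y = y + effect * (x - x.mean())
    y = y - y.mean()
    sd = y.std(ddof=1)
    if sd > 0:
        y = y / sd
    return y
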