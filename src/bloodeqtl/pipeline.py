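"""End-to-end pipeline driver.

Chains the stages in the order of the underlying study design:
normalization -> genotype QC -> mixed-model eGWAS -> eQTL region and
hotspot calling -> QTL overlap -> colocalization -> PCIT co-expression.
Every stage writes its artifact as TSV and the resolved configuration is
dumped to a machine-readable run log, so re-running a config reproduces
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as bio
from .assoc import GRMKernel, MixedModel, compute_grm
from .coloc import ColocPriors, coloc_scans
from .containers import GeneTable, GenotypeMatrix
from .eqtl import call_all_regions, detect_hotspots, detect_top_hotspots, overlap_intervals
from .normalize import normalize_counts
from .pcit import pcit_network
from .qc import PruneParams, bonferroni_threshold, filter_variants, ld_prune
from .simulate import SimConfig, simulate_covariates, simulate_expression, simulate_genotypes


@dataclass
class PipelineConfig:
    """All file paths, thresholds and stage toggles of one run."""

    # inputs (ignored when simulation is enabled)
    vcf: str | None = None
    counts: str | None = None
    gene_bed: str | None = None
    covariates: str | None = None
    traits: str | None = None  # optional TSV: sample + one column per trait
    qtl_intervals: str | None = None  # optional TSV: trait, chrom, start, end

    # simulation
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    # thresholds
    maf_min: float = 0.05
    miss_max: float = 0.10
    prune_window: int = 500_000
    prune_r2: float = 0.7
    prune_step: int = 10
    alpha: float = 0.05
    min_fraction: float = 0.35
    min_lib_millions: float | None = None
    alpha_sw: float = 0.01
    max_removals: int = 3
    outlier_screen: bool = True
    eqtl_gap: int = 1_000_000
    eqtl_min_snps: int = 3
    eqtl_ext: int = 500_000
    cis_window: int = 1_000_000
    hotspot_min_genes: int = 10
    tophotspot_min: int = 10
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_prior_sd: float = 0.15
    coloc_coverage: float = 0.95
    run_pcit: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.maf_min <= 0.5):
            raise ValueError("maf_min must be in (0, 0.5]")
        if not (0 <= self.miss_max <= 1):
            raise ValueError("miss_max must be in [0, 1]")
        if not (0 < self.min_fraction < 1):
            raise ValueError("min_fraction must be in (0, 1)")
        PruneParams(self.prune_window, self.prune_r2, self.prune_step)
        ColocPriors(self.coloc_p1, self.coloc_p2, self.coloc_p12)
        if self.simulate:
            self.sim.validate()
        elif not (self.vcf and self.counts and self.gene_bed):
            raise ValueError("without simulation, vcf, counts and gene_bed paths are required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "hotspot_spec" in sim_raw:
            sim_raw["hotspot_spec"] = [tuple(h) for h in sim_raw["hotspot_spec"]]
        if "libsize_range" in sim_raw:
            sim_raw["libsize_range"] = tuple(sim_raw["libsize_range"])
        cfg = cls(**raw)
        cfg.sim = SimConfig(**sim_raw) if sim_raw else SimConfig(seed=cfg.seed)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every enabled stage; returns the run directory.

    Intermediate artifacts are written as headered TSVs; the run log
    (``run_log.json``) records the resolved configuration, seed and
    package version.  Identical configs reproduce identical outputs.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}

    def fail(stage: str, exc: Exception) -> RuntimeError:
        err = RuntimeError(f"pipeline stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    # -- stage: inputs ----------------------------------------------------
    try:
        if config.simulate:
            sim = config.sim
            geno = simulate_genotypes(sim)
            cov = simulate_covariates(sim)
            expr, gene_table, truth = simulate_expression(geno, sim, cov)
            bio.write_vcf(geno, out / "genotypes.vcf")
            bio.write_counts(expr, out / "counts.tsv")
            bio.write_gene_bed(gene_table, out / "genes.bed")
            bio.write_table(cov, out / "covariates.tsv")
            bio.write_table(truth.cis_effects, out / "truth_cis.tsv")
            bio.write_table(truth.hotspots, out / "truth_hotspots.tsv")
        else:
            geno = bio.read_genotypes(config.vcf)
            expr = bio.read_counts(config.counts)
            gene_table = bio.read_gene_bed(config.gene_bed)
            cov = bio.read_table(config.covariates) if config.covariates else None
            if cov is not None and len(cov) != geno.n_samples:
                raise ValueError("covariate rows do not match VCF samples")
        log["stages"]["inputs"] = {"n_samples": geno.n_samples, "n_variants": geno.n_variants}
    except Exception as e:  # noqa: BLE001
        raise fail("inputs", e)

    # -- stage: normalization ---------------------------------------------
    try:
        norm = normalize_counts(
            expr,
            min_lib_millions=config.min_lib_millions,
            min_fraction=config.min_fraction,
            alpha_sw=config.alpha_sw,
            max_removals=config.max_removals,
            outlier_screen=config.outlier_screen,
        )
        bio.write_counts(norm.log2cpm, out / "log2cpm.tsv", value_format="%.6g")
        bio.write_table(norm.filter_report, out / "gene_filter_report.tsv")
        bio.write_table(norm.outliers, out / "expression_outliers.tsv")
        log["stages"]["normalize"] = {
            "n_genes_retained": norm.log2cpm.n_genes,
            "tmm_factors": [round(float(f), 6) for f in norm.factors],
        }
    except Exception as e:  # noqa: BLE001
        raise fail("normalize", e)

    # -- stage: genotype QC + pruning -------------------------------------
    try:
        geno_f, qc_report = filter_variants(geno, config.maf_min, config.miss_max)
        bio.write_table(qc_report, out / "variant_qc_report.tsv")
        params = PruneParams(config.prune_window, config.prune_r2, config.prune_step)
        independent = ld_prune(geno_f, params)
        pd.DataFrame({"id": independent}).to_csv(out / "independent_variants.tsv", sep="\t", index=False)
        threshold = bonferroni_threshold(config.alpha, len(independent))
        log["stages"]["qc"] = {
            "n_variants_kept": geno_f.n_variants,
            "n_independent": len(independent),
            "p_threshold": threshold,
        }
    except Exception as e:  # noqa: BLE001
        raise fail("qc", e)

    # -- stage: eGWAS ------------------------------------------------------
    try:
        kernel = GRMKernel(compute_grm(geno_f))
        sig_frames = []
        top_rows = []
        L = norm.log2cpm
        for gi, gene in enumerate(L.genes):
            y = L.values[gi]
            if np.sum(~np.isnan(y)) < 10 or np.nanstd(y) == 0:
                continue
            fit = MixedModel(y, cov, kernel, phenotype_id=gene).fit()
            scan = fit.scan(geno_f, threshold=threshold)
            top = scan.loc[scan["p"].idxmin()]
            top_rows.append(
                {
                    "gene": gene,
                    "lambda": fit.lam,
                    "ols_fallback": fit.ols_fallback,
                    "top_id": top["id"],
                    "top_p": top["p"],
                }
            )
            sig = scan[scan["significant"]]
            if not sig.empty:
                sig_frames.append(sig)
        significant = (
            pd.concat(sig_frames, ignore_index=True)
            if sig_frames
            else pd.DataFrame(columns=["phenotype", "id", "chrom", "pos", "beta", "se", "p"])
        )
        bio.write_table(significant, out / "egwas_significant.tsv")
        bio.write_table(pd.DataFrame(top_rows), out / "egwas_gene_summary.tsv")
        log["stages"]["egwas"] = {
            "n_genes_scanned": len(top_rows),
            "n_significant_records": len(significant),
            "n_grm_decompositions": kernel.n_decompositions,
        }
    except Exception as e:  # noqa: BLE001
        raise fail("egwas", e)

    # -- stage: eQTL regions + hotspots ------------------------------------
    try:
        regions = call_all_regions(
            significant,
            gene_table.table,
            gap=config.eqtl_gap,
            min_snps=config.eqtl_min_snps,
            ext=config.eqtl_ext,
            window=config.cis_window,
        )
        hotspots = detect_hotspots(
            significant, gene_table.table, min_genes=config.hotspot_min_genes, window=config.cis_window
        )
        tophot = detect_top_hotspots(regions, min_top=config.tophotspot_min)
        bio.write_table(regions, out / "eqtl_regions.tsv")
        bio.write_table(hotspots, out / "hotspots.tsv")
        bio.write_table(tophot, out / "top_hotspots.tsv")
        log["stages"]["eqtl"] = {
            "n_regions": len(regions),
            "n_cis": int((regions["label"] == "cis").sum()) if len(regions) else 0,
            "n_hotspots": len(hotspots),
            "n_top_hotspots": len(tophot),
        }
    except Exception as e:  # noqa: BLE001
        raise fail("eqtl", e)

    # -- stage: trait GWAS, overlap, colocalization -------------------------
    traits_df = None
    if config.traits:
        traits_df = bio.read_table(config.traits)
    try:
        coloc_rows = []
        if traits_df is not None:
            qtls = (
                bio.read_table(config.qtl_intervals)
                if config.qtl_intervals
                else pd.DataFrame(columns=["trait", "chrom", "start", "end"])
            )
            overlaps = overlap_intervals(qtls, regions[regions["label"] == "cis"]) if len(qtls) else pd.DataFrame()
            if len(overlaps):
                bio.write_table(overlaps, out / "qtl_eqtl_overlap.tsv")
            trait_cols = [c for c in traits_df.columns if c != "sample"]
            gene_scans: dict[str, pd.DataFrame] = {}
            for trait in trait_cols:
                yt = traits_df[trait].to_numpy(dtype=float)
                t_fit = MixedModel(yt, cov, kernel, phenotype_id=trait).fit()
                t_scan = t_fit.scan(geno_f)
                bio.write_table(t_scan, out / f"gwas_{trait}.tsv")
                pairs = (
                    overlaps[overlaps["trait"] == trait][["gene", "ext_start", "ext_end"]]
                    if len(overlaps)
                    else pd.DataFrame(columns=["gene", "ext_start", "ext_end"])
                )
                for _, pr in pairs.iterrows():
                    gene = pr["gene"]
                    if gene not in gene_scans:
                        gi = L.genes.index(gene)
                        g_fit = MixedModel(L.values[gi], cov, kernel, phenotype_id=gene).fit()
                        gene_scans[gene] = g_fit.scan(geno_f)
                    q = qtls[qtls["trait"] == trait].iloc[0]
                    lo = min(int(pr["ext_start"]), int(q["start"]))
                    hi = max(int(pr["ext_end"]), int(q["end"]))
                    res = coloc_scans(
                        t_scan,
                        gene_scans[gene],
                        priors=ColocPriors(config.coloc_p1, config.coloc_p2, config.coloc_p12),
                        prior_sd1=config.coloc_prior_sd,
                        prior_sd2=config.coloc_prior_sd,
                        region=(str(q["chrom"]), lo, hi),
                        coverage=config.coloc_coverage,
                    )
                    row = {"trait": trait, "gene": gene, "n_snps": res.n_snps}
                    row.update({k: float(v) for k, v in res.pp.items()})
                    row["credible_set"] = ",".join(res.credible)
                    coloc_rows.append(row)
        if coloc_rows:
            bio.write_table(pd.DataFrame(coloc_rows), out / "coloc_results.tsv")
        log["stages"]["coloc"] = {"n_tests": len(coloc_rows)}
    except Exception as e:  # noqa: BLE001
        raise fail("coloc", e)

    # -- stage: PCIT -------------------------------------------------------
    try:
        if config.run_pcit and len(hotspots):
            hot = hotspots.sort_values("n_genes", ascending=False).iloc[0]
            genes = [g for g in hot["genes"].split(",") if g in L.genes][:30]
            if len(genes) >= 3:
                idx = [L.genes.index(g) for g in genes]
                net = pcit_network(L.values[idx], nodes=genes)
                bio.write_table(net.edges(), out / "pcit_edges.tsv")
                log["stages"]["pcit"] = {
                    "regulator": hot["id"],
                    "n_nodes": len(genes),
                    "n_kept_edges": int(net.kept.sum() // 2),
                }
    except Exception as e:  # noqa: BLE001
        raise fail("pcit", e)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
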