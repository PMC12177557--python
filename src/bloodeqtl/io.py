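"""Readers and writers for the standard interchange formats.

Conventions: VCF and all association/eQTL tables are 1-based inclusive;
BED is 0-based half-open and converted at the boundary.  Genotype VCFs
are read with cyvcf2; writing uses plain text (the files this pipeline
emits are small enough not to need bgzip).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneTable, GenotypeMatrix, ExpressionMatrix


def read_genotypes(path: str | Path, use_dosage: bool = False) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix.

    Dosage is the alt-allele count from GT (``./.`` -> missing), or the
    DS field when ``use_dosage``.  Multiallelic records are skipped with
    a counter reported on the returned matrix as ``n_multiallelic_skipped``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples in VCF {path}")
    rows = []
    dosages = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if use_dosage:
            ds = rec.format("DS")
            if ds is None:
                raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks DS field")
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotypes)  # (n, ploidy+1), -1 = missing
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            d = alleles.sum(axis=1)
        dosages.append(d)
        rows.append(
            {
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    if not rows:
        raise ValueError(f"no biallelic records in VCF {path}")
    geno = GenotypeMatrix(
        dosages=np.column_stack(dosages),
        variants=pd.DataFrame(rows),
        samples=samples,
    )
    geno.n_multiallelic_skipped = n_multi  # type: ignore[attr-defined]
    return geno


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as a minimal VCFv4.2 text file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bloodeqtl\n")
        for c in pd.unique(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        D = geno.dosages
        for j in range(geno.n_variants):
            v = geno.variants.iloc[j]
            calls = [
                "./." if np.isnan(D[i, j]) else gt_codes[int(round(D[i, j]))]
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_counts(expr: ExpressionMatrix, path: str | Path, value_format: str = "%.0f") -> None:
    """Genes x samples TSV with a ``gene`` id column; nan written as NA."""
    df = expr.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=value_format)


def read_counts(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix.from_frame(df)


def write_gene_bed(genes: GeneTable, path: str | Path) -> None:
    """6-column BED (0-based half-open) from the 1-based gene table."""
    t = genes.table
    bed = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["start"].astype(int) - 1,
            "end": t["end"].astype(int),
            "name": t["gene"],
            "score": 0,
            "strand": t["strand"] if "strand" in t.columns else "+",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path: str | Path) -> GeneTable:
    """Read a 4+ column BED into the 1-based inclusive gene table."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError("gene BED needs at least 4 columns (chrom start end name)")
    t = pd.DataFrame(
        {
            "gene": bed[3].astype(str),
            "chrom": bed[0].astype(str),
            "start": bed[1].astype(int) + 1,
            "end": bed[2].astype(int),
        }
    )
    if bed.shape[1] >= 6:
        t["strand"] = bed[5].astype(str)
    return GeneTable(t)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
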