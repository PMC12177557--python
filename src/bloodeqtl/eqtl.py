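"""eQTL region calling, cis/trans labels, hotspots and QTL overlap.

Rules
-----
* Regions: consecutive significant SNPs for the same gene are grouped
  while gaps stay under 1 Mb (a gap of exactly 1,000,000 bp splits);
  clusters with fewer than 3 SNPs are discarded; surviving cores are
  extended 0.5 Mb on each side (floored at position 1).
* cis/trans: a variant is cis to a gene when it lies on the same
  chromosome within 1 Mb (inclusive) of the nearest gene-body boundary
  (distance 0 inside the gene); a region is labelled cis if any member
  significant SNP is cis.
* Hotspots: a variant associated with >= 10 distinct genes; top-hotspot:
  a variant that is the top (smallest-p) SNP of >= 10 eQTL regions.
* Overlap: closed-interval intersection of QTL intervals with extended
  eQTL intervals on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EqtlRegion",
    "call_regions",
    "classify_cis_trans",
    "call_all_regions",
    "detect_hotspots",
    "detect_top_hotspots",
    "overlap_intervals",
    "CIS_WINDOW",
]

CIS_WINDOW = 1_000_000


@dataclass
class EqtlRegion:
    """One gene's merged significant interval."""

    gene: str
    chrom: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    n_snps: int
    top_variant: str
    top_p: float
    label: str  # 'cis' | 'trans'


def call_regions(
    records: pd.DataFrame,
    gap: int = 1_000_000,
    min_snps: int = 3,
    ext: int = 500_000,
    chrom_length: int | None = None,
) -> list[dict]:
    """Group one gene's significant SNPs into eQTL regions.

    ``records`` needs columns gene, id, chrom, pos, p and must contain a
    single gene.  Splitting happens at inter-SNP gaps >= ``gap``; the top
    variant is the member with the smallest p (ties: smallest position).
    Extension never goes below position 1 or past ``chrom_length``.
    Returns one dict per region (no cis/trans label yet).
    """
    if records.empty:
        return []
    if records["gene"].nunique() > 1:
        raise ValueError("call_regions operates on a single gene")
    gene = records["gene"].iloc[0]
    out: list[dict] = []
    for chrom, sub in records.groupby("chrom", sort=False):
        sub = sub.sort_values(["pos", "id"], kind="mergesort").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        split = np.nonzero(np.diff(pos) >= gap)[0]
        starts = np.concatenate([[0], split + 1])
        ends = np.concatenate([split, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            cluster = sub.iloc[s : e + 1]
            if len(cluster) < min_snps:
                continue
            top = cluster.sort_values(["p", "pos"], kind="mergesort").iloc[0]
            ext_end = int(cluster["pos"].max()) + ext
            if chrom_length is not None:
                ext_end = min(ext_end, chrom_length)
            out.append(
                {
                    "gene": gene,
                    "chrom": str(chrom),
                    "core_start": int(cluster["pos"].min()),
                    "core_end": int(cluster["pos"].max()),
                    "ext_start": max(int(cluster["pos"].min()) - ext, 1),
                    "ext_end": ext_end,
                    "n_snps": int(len(cluster)),
                    "top_variant": str(top["id"]),
                    "top_p": float(top["p"]),
                    "member_pos": cluster["pos"].tolist(),
                }
            )
    return out


def classify_cis_trans(
    variant_chrom: str,
    variant_pos: int,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    window: int = CIS_WINDOW,
) -> str:
    """'cis' when on the gene's chromosome within ``window`` bp of the
    gene body (inclusive boundary; distance 0 inside the gene), else
    'trans'."""
    if str(variant_chrom) != str(gene_chrom):
        return "trans"
    if gene_start <= variant_pos <= gene_end:
        return "cis"
    dist = min(abs(variant_pos - gene_start), abs(variant_pos - gene_end))
    return "cis" if dist <= window else "trans"


def call_all_regions(
    significant: pd.DataFrame,
    gene_table: pd.DataFrame,
    gap: int = 1_000_000,
    min_snps: int = 3,
    ext: int = 500_000,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Region calling + cis/trans labelling over every gene in a long
    significant-association table.

    ``gene_table`` needs columns gene, chrom, start, end.  The region
    label is 'cis' when any member significant SNP is cis to the gene.
    """
    gt = gene_table.set_index("gene")
    rows = []
    for gene, sub in significant.groupby("phenotype", sort=False):
        regions = call_regions(
            sub.rename(columns={"phenotype": "gene"}), gap=gap, min_snps=min_snps, ext=ext
        )
        if gene in gt.index:
            g = gt.loc[gene]
            gchrom, gstart, gend = str(g["chrom"]), int(g["start"]), int(g["end"])
        else:
            gchrom, gstart, gend = "?", -1, -1
        for r in regions:
            labels = [
                classify_cis_trans(r["chrom"], p, gchrom, gstart, gend, window)
                for p in r["member_pos"]
            ]
            r = {k: v for k, v in r.items() if k != "member_pos"}
            r["label"] = "cis" if "cis" in labels else "trans"
            rows.append(r)
    cols = [
        "gene", "chrom", "core_start", "core_end", "ext_start", "ext_end",
        "n_snps", "top_variant", "top_p", "label",
    ]
    return pd.DataFrame(rows, columns=cols)


def detect_hotspots(
    significant: pd.DataFrame,
    gene_table: pd.DataFrame | None = None,
    min_genes: int = 10,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Variants associated with >= ``min_genes`` distinct genes.

    ``significant`` is a long table with columns phenotype (gene), id,
    chrom, pos.  The cis flag marks hotspots cis to at least one of
    their associated genes (requires ``gene_table``).
    """
    if significant.empty:
        return pd.DataFrame(columns=["id", "chrom", "pos", "n_genes", "genes", "cis"])
    dedup = significant.drop_duplicates(subset=["id", "phenotype"])
    grp = dedup.groupby("id", sort=False)
    rows = []
    gt = gene_table.set_index("gene") if gene_table is not None else None
    for vid, sub in grp:
        genes = sorted(sub["phenotype"].unique())
        if len(genes) < min_genes:
            continue
        chrom = str(sub["chrom"].iloc[0])
        pos = int(sub["pos"].iloc[0])
        cis = False
        if gt is not None:
            for g in genes:
                if g in gt.index:
                    row = gt.loc[g]
                    if (
                        classify_cis_trans(
                            chrom, pos, str(row["chrom"]), int(row["start"]), int(row["end"]), window
                        )
                        == "cis"
                    ):
                        cis = True
                        break
        rows.append(
            {
                "id": vid,
                "chrom": chrom,
                "pos": pos,
                "n_genes": len(genes),
                "genes": ",".join(genes),
                "cis": cis,
            }
        )
    out = pd.DataFrame(rows, columns=["id", "chrom", "pos", "n_genes", "genes", "cis"])
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def detect_top_hotspots(regions: pd.DataFrame, min_top: int = 10) -> pd.DataFrame:
    """Variants that are the top SNP of >= ``min_top`` eQTL regions."""
    if regions.empty:
        return pd.DataFrame(columns=["id", "n_top_regions", "genes"])
    grp = regions.groupby("top_variant", sort=False)
    rows = [
        {
            "id": vid,
            "n_top_regions": len(sub),
            "genes": ",".join(sorted(sub["gene"].unique())),
        }
        for vid, sub in grp
        if len(sub) >= min_top
    ]
    return pd.DataFrame(rows, columns=["id", "n_top_regions", "genes"])


def overlap_intervals(qtls: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """(QTL, eQTL) pairs whose extended eQTL interval intersects the QTL
    interval on the same chromosome (closed intervals; one shared bp
    counts).

    ``qtls`` needs columns trait, chrom, start, end; ``regions`` is the
    output of :func:`call_all_regions`.
    """
    for df, (a, b) in ((qtls, ("start", "end")), (regions, ("ext_start", "ext_end"))):
        if not df.empty and (df[a] > df[b]).any():
            raise ValueError("malformed interval: start > end")
    rows = []
    for _, q in qtls.iterrows():
        same = regions[regions["chrom"].astype(str) == str(q["chrom"])]
        hit = same[(same["ext_start"] <= q["end"]) & (same["ext_end"] >= q["start"])]
        for _, r in hit.iterrows():
            rows.append(
                {
                    "trait": q["trait"],
                    "qtl_chrom": q["chrom"],
                    "qtl_start": int(q["start"]),
                    "qtl_end": int(q["end"]),
                    "gene": r["gene"],
                    "ext_start": int(r["ext_start"]),
                    "ext_end": int(r["ext_end"]),
                    "label": r.get("label", ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["trait", "qtl_chrom", "qtl_start", "qtl_end", "gene", "ext_start", "ext_end", "label"],
    )
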