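"""In-memory containers shared by every pipeline stage.

Dosages are stored as floats with ``nan`` marking missing calls so that a
single matrix representation serves hard genotypes (0/1/2) and rounded
imputed dosages alike.  All genomic positions are 1-based inclusive, the
convention of VCF and of the association/eQTL tables this package writes;
BED input/output converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array with values in {0, 1, 2}
        (or fractional dosages) and ``nan`` for missing calls.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (``pos``
        1-based), one row per column of ``dosages``, position-sorted
        within each chromosome.
    samples
        Sample identifiers, one per row of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.samples)} samples"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant, over non-missing calls.

        Variants with every call missing get frequency ``nan``.
        """
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant (nan where all-missing)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the variant mean.

        All-missing variants impute to 0.
        """
        X = self.dosages.copy()
        nan_mask = np.isnan(X)
        if nan_mask.any():
            col_mean = np.where(
                nan_mask.all(axis=0), 0.0, np.nanmean(np.where(nan_mask, np.nan, X), axis=0)
            )
            X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        return X

    def take_variants(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
        )

    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in index],
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit missing mask.

    ``values`` holds raw counts (integers) or normalized log2-cpm floats;
    ``nan`` marks missing entries (raw zeros after the zero->NA rule, or
    values masked by outlier removal).
    """

    values: np.ndarray
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(values=df.to_numpy(dtype=float), genes=list(df.index), samples=list(df.columns))


@dataclass
class GeneTable:
    """Gene coordinates (1-based inclusive start/end, as used internally)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene", "chrom", "start", "end")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene table lacks columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def interval(self, gene: str) -> tuple[str, int, int]:
        row = self.table.loc[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(f"unknown gene {gene!r}")
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])
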