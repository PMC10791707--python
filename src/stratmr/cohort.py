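"""The in-memory cohort container and its on-disk text formats.

A cohort is a pair of row-aligned tables: an individuals × variants dosage
matrix (integer 0/1/2, NaN only if missingness was configured) and a
phenotype/covariate/outcome table. Both are indexed by individual ID and kept
consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd


class CohortError(ValueError):
    """Invalid cohort input (unknown column, misaligned tables, ...)."""


@dataclass
class Cohort:
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    variant_meta: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise CohortError("genotype and phenotype tables have mismatched row identity")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def subset(self, index: pd.Index) -> "Cohort":
        return Cohort(
            genotypes=self.genotypes.loc[index],
            phenotypes=self.phenotypes.loc[index],
            variant_meta=self.variant_meta,
        )

    def require_columns(self, names: Iterable[str]) -> None:
        missing = [c for c in names if c not in self.phenotypes.columns]
        if missing:
            raise CohortError(f"unknown phenotype column(s): {missing}")

    # ---- text I/O ------------------------------------------------------

    def write_tsv(self, genotypes_path: str | Path, phenotypes_path: str | Path) -> None:
        self.genotypes.to_csv(genotypes_path, sep="\t", index_label="iid")
        self.phenotypes.to_csv(phenotypes_path, sep="\t", index_label="iid")

    @classmethod
    def read_tsv(
        cls,
        genotypes_path: str | Path,
        phenotypes_path: str | Path,
        variant_meta_path: str | Path | None = None,
    ) -> "Cohort":
        geno = pd.read_csv(genotypes_path, sep="\t", index_col="iid")
        pheno = pd.read_csv(phenotypes_path, sep="\t", index_col="iid")
        meta = None
        if variant_meta_path is not None:
            meta = pd.read_csv(variant_meta_path, sep="\t")
        return cls(genotypes=geno, phenotypes=pheno, variant_meta=meta)

    def write_vcf(self, path: str | Path) -> None:
        """Minimal GT-only VCF (unphased; dosage = number of ALT alleles)."""
        meta = self.variant_meta
        lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
        if meta is not None:
            for chrom in dict.fromkeys(meta["chrom"].astype(str)):
                lines.append(f"##contig=<ID={chrom}>")
        samples = [str(i) for i in self.genotypes.index]
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for vid in self.genotypes.columns:
            chrom, pos = "NA", 0
            if meta is not None and vid in set(meta["variant_id"]):
                row = meta.loc[meta["variant_id"] == vid].iloc[0]
                chrom, pos = str(row["chrom"]), int(row["pos"])
            dosages = self.genotypes[vid].to_numpy()
            gts = ["./." if not np.isfinite(d) else gt_code[int(d)] for d in dosages]
            lines.append(f"{chrom}\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts))
        Path(path).write_text("\n".join(lines) + "\n")


def parse_region(spec: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chrom:start-end`` region string."""
    try:
        chrom, span = spec.split(":")
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise CohortError(f"malformed region spec {spec!r}; expected 'chrom:start-end'") from exc
    if start > end:
        raise CohortError(f"region start {start} exceeds end {end}")
    return chrom, start, end


def variants_in_region(
    variant_meta: pd.DataFrame, region: str, flank: int = 500_000
) -> list[str]:
    """Variant IDs within ``region`` extended by ``flank`` bp on each side.

    Mirrors the gene ± flank windowing used for cis instrument selection
    (default flank 500 kb). Coordinates are 1-based inclusive.
    """
    chrom, start, end = parse_region(region)
    lo, hi = max(1, start - flank), end + flank
    mask = (
        (variant_meta["chrom"].astype(str) == chrom)
        & (variant_meta["pos"] >= lo)
        & (variant_meta["pos"] <= hi)
    )
    return list(variant_meta.loc[mask, "variant_id"])
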