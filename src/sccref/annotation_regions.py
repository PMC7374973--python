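"""Gene annotation parsing and sex-chromosome region assignment.

Genes are read from GTF (feature type "gene" only, matching how count
matrices are typically built) and each gene is assigned exactly one region
label — PAR1, XTR, PAR2, other-X, Y, autosome or mito — plus a coarser
chromosome class used to partition differential-expression results.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from gffutils.feature import feature_from_line

from .reference_builder import MaskInterval

logger = logging.getLogger("sccref")


class RegionLabel(str, Enum):
    PAR1 = "PAR1"
    XTR = "XTR"
    PAR2 = "PAR2"
    X_OTHER = "X_other"
    Y = "Y"
    AUTOSOME = "autosome"
    MITO = "mito"


class ChromClass(str, Enum):
    X_LINKED = "X-linked"
    Y_LINKED = "Y-linked"
    AUTOSOMAL = "autosomal"
    MITO = "mito"


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with a 1-based inclusive genomic span."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class RegionMap:
    """X/Y/mito record names plus the PAR1/XTR/PAR2 intervals on X.

    No default XTR interval ships: unlike the PARs, XTR coordinates are not
    part of the standard PAR definitions, so callers (or the toy simulator)
    must supply one to get XTR labels.
    """

    x_chrom_name: str = "X"
    y_chrom_name: str = "Y"
    mito_name: str = "MT"
    par1: MaskInterval | None = None
    xtr: MaskInterval | None = None
    par2: MaskInterval | None = None
    extra_regions: dict[str, MaskInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = [iv for iv in (self.par1, self.xtr, self.par2) if iv is not None]
        for a, b in zip(ivs, ivs[1:]):
            if not a.end < b.start:
                raise ValueError(
                    "PAR1/XTR/PAR2 intervals must be non-overlapping and ordered "
                    f"along X: {a} !< {b}"
                )

    @classmethod
    def grch38(cls, x: str = "X", y: str = "Y", mito: str = "MT",
               xtr: MaskInterval | None = None) -> "RegionMap":
        return cls(
            x_chrom_name=x, y_chrom_name=y, mito_name=mito,
            par1=MaskInterval(x, 10_001, 2_781_479, "PAR1"),
            xtr=xtr,
            par2=MaskInterval(x, 155_701_383, 156_030_895, "PAR2"),
        )


def parse_gtf(path: str | Path) -> list[GeneRecord]:
    """Parse gene features from a GTF file.

    Only rows whose feature type is "gene" are returned; transcript, exon and
    CDS rows are ignored. Coordinates stay 1-based inclusive as in GTF.
    A missing ``gene_id`` attribute or an unparseable row is an error naming
    the line number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: unparseable GTF line (expected 9 tab-separated fields)"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: unparseable GTF line: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            if "gene_id" not in feat.attributes:
                raise ValueError(f"{path}:{lineno}: gene row lacks gene_id attribute")
            gene_id = feat.attributes["gene_id"][0]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            name = feat.attributes.get("gene_name", [gene_id])[0]
            biotype = feat.attributes.get(
                "gene_biotype", feat.attributes.get("gene_type", [""])
            )[0]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    name=name,
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand or ".",
                    biotype=biotype,
                )
            )
    return genes


_warned_unknown: set[str] = set()


def assign_region(gene: GeneRecord, region_map: RegionMap) -> RegionLabel:
    """Assign exactly one region label to a gene.

    Genes on X land in PAR1/XTR/PAR2 when their *start* position falls inside
    the interval (a gene straddling a boundary is classified by its start —
    a deterministic single-label rule), else X_other. Unknown chromosomes are
    treated as autosomal and logged once per name.
    """
    if gene.chrom == region_map.y_chrom_name:
        return RegionLabel.Y
    if gene.chrom == region_map.mito_name:
        return RegionLabel.MITO
    if gene.chrom == region_map.x_chrom_name:
        for iv, label in (
            (region_map.par1, RegionLabel.PAR1),
            (region_map.xtr, RegionLabel.XTR),
            (region_map.par2, RegionLabel.PAR2),
        ):
            if iv is not None and iv.start <= gene.start <= iv.end:
                return label
        return RegionLabel.X_OTHER
    if not _is_standard_autosome(gene.chrom) and gene.chrom not in _warned_unknown:
        _warned_unknown.add(gene.chrom)
        logger.info("chromosome %r not in region map; treating as autosome", gene.chrom)
    return RegionLabel.AUTOSOME


def _is_standard_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr")
    return c.isdigit()


def chrom_class(gene: GeneRecord, region_map: RegionMap) -> ChromClass:
    """Coarse class used to color/partition DE results."""
    if gene.chrom == region_map.x_chrom_name:
        return ChromClass.X_LINKED
    if gene.chrom == region_map.y_chrom_name:
        return ChromClass.Y_LINKED
    if gene.chrom == region_map.mito_name:
        return ChromClass.MITO
    return ChromClass.AUTOSOMAL


def region_table(genes: Iterable[GeneRecord], region_map: RegionMap) -> pd.DataFrame:
    """Tabulate (gene_id, name, chrom, start, end, strand, region, class)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "name": g.name,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "region": assign_region(g, region_map).value,
            "class": chrom_class(g, region_map).value,
        }
        for g in genes
    ]
    return pd.DataFrame(rows)


def write_region_table(genes: Iterable[GeneRecord], region_map: RegionMap,
                       path: str | Path) -> Path:
    path = Path(path)
    region_table(genes, region_map).to_csv(path, sep="\t", index=False)
    return path


def read_region_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def region_lookup(genes: Iterable[GeneRecord],
                  region_map: RegionMap) -> Mapping[str, RegionLabel]:
    return {g.gene_id: assign_region(g, region_map) for g in genes}


def class_lookup(genes: Iterable[GeneRecord],
                 region_map: RegionMap) -> Mapping[str, ChromClass]:
    return {g.gene_id: chrom_class(g, region_map) for g in genes}
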