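"""Sex-chromosome-complement (SCC) informed reference construction.

RNA-seq reads from the pseudoautosomal regions (PAR1/PAR2), which are 100%
identical between the human X and Y chromosomes, cannot be placed uniquely by
an aligner and are split between the two chromosomes. Hard-masking the Y copy
(for XX samples, the whole Y; for XY samples, only the Y PARs) forces those
reads onto the X and removes spurious Y-linked expression. This module builds
such references: FASTA I/O, interval hard-masking, Y-masked / YPAR-masked
genome construction, transcriptome masking, and decoy-aware concatenation for
selective-alignment indexers.

Coordinates are 1-based inclusive throughout (the convention of GTF and of
the published PAR coordinates); BED input is converted at the parser
boundary. Chromosomes are masked, never dropped, so every reference built
from one genome shares a single chromosome set.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("sccref")

# Uppercase IUPAC nucleotide alphabet (incl. U for RNA-derived references).
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

MASK_CHAR = "N"  # hard-mask only; soft-masking is deliberately not offered


class SexChromosomeComplement(str, Enum):
    """Closed complement enumeration used for reference building.

    Inference over expression data may additionally produce ambiguous calls;
    see :mod:`sccref.scc_inference`.
    """

    XX = "XX"
    XY = "XY"


@dataclass(frozen=True)
class MaskInterval:
    """A 1-based inclusive interval on a named record."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class FastaRecord:
    """One FASTA record; ``description`` is the full header line sans '>'."""

    name: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.description:
            self.description = self.name


@dataclass
class GenomeSequence:
    """Ordered named nucleotide sequences with output line-wrap metadata."""

    records: list[FastaRecord] = field(default_factory=list)
    line_width: int = 60

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate record names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.records)

    def __getitem__(self, name: str) -> FastaRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def copy(self) -> "GenomeSequence":
        return GenomeSequence(
            records=[FastaRecord(r.name, r.sequence, r.description) for r in self.records],
            line_width=self.line_width,
        )


def _validate_sequence(name: str, seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in IUPAC_NUCLEOTIDES:
            raise ValueError(
                f"record {name!r}: non-nucleotide character {ch!r} at position {i + 1}"
            )


def read_fasta(path: str | Path, line_width: int = 60) -> GenomeSequence:
    """Read a plain or gzipped FASTA file into a :class:`GenomeSequence`.

    Record names are the header token up to the first whitespace; sequences
    are uppercased. Duplicate names and non-IUPAC characters are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[FastaRecord] = []
    with opener(path, "rt") as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise ValueError(f"{path}: empty FASTA header")
            seq = seq.upper()
            _validate_sequence(name, seq)
            records.append(FastaRecord(name=name, sequence=seq, description=header))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return GenomeSequence(records=records, line_width=line_width)


def write_fasta(genome: GenomeSequence, path: str | Path) -> Path:
    """Write records in order, wrapped at ``genome.line_width`` columns.

    Headers are preserved verbatim; ``read_fasta(write_fasta(g))`` round-trips
    names, order and sequence exactly.
    """
    if not genome.records:
        raise ValueError("refusing to write an empty genome")
    path = Path(path)
    w = genome.line_width
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in genome.records:
            fh.write(f">{rec.description}\n")
            for i in range(0, len(rec.sequence), w):
                fh.write(rec.sequence[i : i + w])
                fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Hard-masking
# ---------------------------------------------------------------------------

def hard_mask(genome: GenomeSequence, intervals: Iterable[MaskInterval]) -> GenomeSequence:
    """Replace every base inside each 1-based inclusive interval with 'N'.

    Lengths and the record set are unchanged; bases outside the intervals are
    byte-identical. Intervals addressing unknown records or running past the
    record end are hard errors — never silently clipped.
    """
    out = genome.copy()
    by_name = {r.name: r for r in out.records}
    for iv in intervals:
        rec = by_name.get(iv.chrom)
        if rec is None:
            raise KeyError(f"interval {iv.label or iv} addresses unknown record {iv.chrom!r}")
        if iv.end > len(rec.sequence):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds record length "
                f"{len(rec.sequence)}"
            )
        s = rec.sequence
        rec.sequence = s[: iv.start - 1] + MASK_CHAR * iv.length + s[iv.end :]
    return out


@dataclass
class ParRegistry:
    """Named sets of PAR mask intervals.

    Two coordinate systems for the GRCh38 pseudoautosomal regions are in
    circulation and are NOT interchangeable: the full-assembly coordinates
    (X and Y PAR1 10,001-2,781,479; X PAR2 155,701,383-156,030,895; Y PAR2
    56,887,903-57,217,415) and the Ensembl Y-sequence coordinates
    (Y PAR1 6,001-2,699,520; Y PAR2 154,931,044-155,260,560). Both ship as
    built-ins; callers must name one explicitly because the correct choice
    depends on which Y sequence build is being masked.
    """

    coordinate_sets: dict[str, list[MaskInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coordinate_sets:
            self.coordinate_sets = _builtin_coordinate_sets()

    def get(self, name: str) -> list[MaskInterval]:
        if name not in self.coordinate_sets:
            raise KeyError(
                f"unknown PAR coordinate set {name!r}; available: "
                f"{sorted(self.coordinate_sets)}"
            )
        return list(self.coordinate_sets[name])

    def add(self, name: str, intervals: Sequence[MaskInterval]) -> None:
        if name in self.coordinate_sets:
            raise ValueError(f"coordinate set {name!r} already registered")
        self.coordinate_sets[name] = list(intervals)

    def add_from_bed(self, name: str, path: str | Path) -> None:
        self.add(name, read_bed(path))

    def y_intervals(self, name: str, y_chrom_name: str) -> list[MaskInterval]:
        """Intervals of a set that target the Y, re-addressed to ``y_chrom_name``.

        Registry intervals use generic 'Y'/'chrY' names; the genome at hand
        may call its Y record something else.
        """
        out = []
        for iv in self.get(name):
            if iv.chrom in {"Y", "chrY", y_chrom_name}:
                out.append(MaskInterval(y_chrom_name, iv.start, iv.end, iv.label))
        return out


def _builtin_coordinate_sets() -> dict[str, list[MaskInterval]]:
    return {
        "GRCh38_full": [
            MaskInterval("X", 10_001, 2_781_479, "PAR1"),
            MaskInterval("X", 155_701_383, 156_030_895, "PAR2"),
            MaskInterval("Y", 10_001, 2_781_479, "PAR1"),
            MaskInterval("Y", 56_887_903, 57_217_415, "PAR2"),
        ],
        "GRCh38_ensembl_Y": [
            MaskInterval("Y", 6_001, 2_699_520, "PAR1"),
            MaskInterval("Y", 154_931_044, 155_260_560, "PAR2"),
        ],
    }


def read_bed(path: str | Path) -> list[MaskInterval]:
    """Read BED intervals (0-based half-open) as 1-based inclusive intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 fields")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            intervals.append(MaskInterval(chrom, start0 + 1, end0, label))
    return intervals


# ---------------------------------------------------------------------------
# SCC-informed genome / transcriptome construction
# ---------------------------------------------------------------------------

def build_informed_genome(
    genome: GenomeSequence,
    scc: SexChromosomeComplement | str,
    registry: ParRegistry | None = None,
    registry_set: str = "GRCh38_full",
    y_chrom_name: str = "Y",
) -> GenomeSequence:
    """Build the SCC-informed genome.

    XX: the entire Y record is hard-masked ("Y-masked"). XY: only the Y PAR
    intervals of the named registry set are hard-masked ("YPAR-masked").
    Every other record is byte-identical; the chromosome set and all lengths
    are unchanged (masked, never removed, so downstream indices built from
    either reference share one chromosome set).
    """
    scc = SexChromosomeComplement(scc)
    if y_chrom_name not in genome:
        raise KeyError(f"genome has no record named {y_chrom_name!r}")
    if scc is SexChromosomeComplement.XX:
        y_len = len(genome[y_chrom_name].sequence)
        return hard_mask(genome, [MaskInterval(y_chrom_name, 1, y_len, "Y-masked")])
    registry = registry or ParRegistry()
    y_pars = registry.y_intervals(registry_set, y_chrom_name)
    if not y_pars:
        raise ValueError(
            f"registry set {registry_set!r} has no Y intervals; cannot build a "
            "YPAR-masked reference"
        )
    return hard_mask(genome, y_pars)


def mask_transcriptome(
    transcripts: GenomeSequence,
    annotation: Mapping[str, tuple[str, int, int]] | None,
    scc: SexChromosomeComplement | str,
    registry: ParRegistry | None = None,
    registry_set: str = "GRCh38_full",
    y_chrom_names: frozenset[str] = frozenset({"Y", "chrY"}),
    par_y_suffix: str = "PAR_Y",
) -> GenomeSequence:
    """Build the SCC-informed transcriptome by fully masking whole transcripts.

    ``annotation`` maps transcript id -> (chromosome, genomic start, genomic
    end). XX: every Y-linked transcript becomes all-N. XY: only Y-PAR
    transcripts (genomic span intersecting a registry Y-PAR interval, or —
    when no annotation is given — an identifier carrying the gencode-style
    ``PAR_Y`` suffix) become all-N. Record count, order, identifiers and
    lengths are unchanged.

    Ensembl-style builds carry no Y-PAR transcripts at all; for those the XY
    output is byte-identical to the input and a warning is logged.
    """
    scc = SexChromosomeComplement(scc)
    registry = registry or ParRegistry()

    def chrom_of(tid: str) -> str | None:
        if annotation is not None:
            if tid not in annotation:
                raise KeyError(
                    f"transcript {tid!r} not resolvable to a chromosome via the "
                    "supplied annotation"
                )
            return annotation[tid][0]
        return None

    out = transcripts.copy()
    if scc is SexChromosomeComplement.XX:
        masked_any = False
        for rec in out.records:
            chrom = chrom_of(rec.name)
            is_y = (chrom in y_chrom_names) if chrom is not None else (
                par_y_suffix in rec.name
            )
            if is_y:
                rec.sequence = MASK_CHAR * len(rec.sequence)
                masked_any = True
        if not masked_any:
            logger.warning("XX transcriptome mask: no Y-linked transcripts found")
        return out

    # XY: mask only Y-PAR transcripts.
    y_pars = [iv for iv in registry.get(registry_set) if iv.chrom in y_chrom_names]
    masked_any = False
    for rec in out.records:
        if annotation is not None:
            chrom, start, end = annotation[rec.name]
            is_ypar = chrom in y_chrom_names and any(
                iv.overlaps(start, end) for iv in y_pars
            )
        else:
            is_ypar = par_y_suffix in rec.name
        if is_ypar:
            rec.sequence = MASK_CHAR * len(rec.sequence)
            masked_any = True
    if not masked_any:
        logger.warning(
            "XY transcriptome mask: no Y-PAR transcripts in this build "
            "(Ensembl-style cDNA); output is identical to input"
        )
    return out


def build_decoy_aware(
    transcripts: GenomeSequence, genome: GenomeSequence
) -> tuple[GenomeSequence, list[str]]:
    """Concatenate the genome after the transcriptome for a decoy-aware index.

    Returns the combined FASTA (transcript records first, genome records
    after, both in input order) and the decoy names — the genome record names,
    one per line when written — as consumed by selective-alignment indexers.
    """
    if not genome.records:
        raise ValueError("decoy set may not be empty for a decoy-aware build")
    collisions = set(transcripts.names) & set(genome.names)
    if collisions:
        raise ValueError(f"transcript/genome record name collision: {sorted(collisions)}")
    combined = GenomeSequence(
        records=[FastaRecord(r.name, r.sequence, r.description) for r in transcripts.records]
        + [FastaRecord(r.name, r.sequence, r.description) for r in genome.records],
        line_width=transcripts.line_width,
    )
    return combined, list(genome.names)


def write_decoy_list(decoy_names: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{n}\n" for n in decoy_names))
    return path


def count_non_n(genome: GenomeSequence, chrom: str) -> int:
    """Number of non-N bases on a record (computed, never assumed)."""
    seq = genome[chrom].sequence
    return len(seq) - seq.count(MASK_CHAR)
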