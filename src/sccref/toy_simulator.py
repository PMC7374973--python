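"""Toy sex-genome simulator and seeded best-hit read assigner.

Builds a miniature genome with the homology structure that makes sex
chromosomes hard to quantify — PAR1 and PAR2 byte-identical between X and Y,
an X-transposed region (XTR) at ~98.78% identity, diverged X-Y gametolog
pairs, X-/Y-specific genes (including an XIST-like and an SRY-like gene) and
an autosome — simulates expression reads with truth labels, and assigns them
with a k-mer seed-and-verify best-hit mapper in which equally good hits are
resolved uniformly at random with a per-read seeded generator. This models
(it does not reimplement) how spliced aligners pick a primary alignment
among multimapping candidates: an error-free PAR read has exactly two
equal-best loci under a default reference and is therefore split 50/50
between X and Y, while the same read maps uniquely to X once the Y copy is
hard-masked. ``run_experiment`` runs the full default-vs-informed
comparison — quantification, SCC inference, fold changes, differential
expression and DE-set overlap — at desk scale.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_regions import (
    ChromClass,
    GeneRecord,
    RegionMap,
    class_lookup,
    region_lookup,
)
from .de_compare import DeComparison, DeResult, de_frame, de_overlap, moderated_de
from .expression_stats import (
    ComparisonResult,
    CountMatrix,
    cpm,
    filter_min_cpm,
    log_cpm,
    paired_t,
    per_gene_fold_change,
    region_summary,
    tmm_factors,
    wilcoxon_signed_rank,
)
from .reference_builder import (
    GenomeSequence,
    FastaRecord,
    MaskInterval,
    ParRegistry,
    SexChromosomeComplement,
    build_informed_genome,
    write_fasta,
)
from .scc_inference import MarkerPanel, SccCall, calls_to_frame, infer_scc

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


# ---------------------------------------------------------------------------
# Toy genome construction
# ---------------------------------------------------------------------------

@dataclass
class ToyGenomeSpec:
    """Gene-class layout and divergence parameters of the toy genome.

    Divergences are per-base substitution probabilities between the X and Y
    copies: the XTR default of 0.0122 corresponds to the 98.78% X-Y homology
    of the human XTR; gametolog pairs are far older and default to 10%
    divergence. PAR divergence is fixed at zero — PAR identity is the
    phenomenon being modeled, not a dial.
    """

    n_par1: int = 4
    n_par2: int = 2
    n_xtr: int = 3
    n_gametolog: int = 4
    n_x_specific: int = 3   # plus one XIST-like gene, always present
    n_y_specific: int = 2   # plus one SRY-like gene, always present
    n_autosomal: int = 20
    gene_length: int = 3000
    intergenic_length: int = 500
    xtr_divergence: float = 0.0122
    gametolog_divergence: float = 0.10
    seed: int = 17

    def __post_init__(self) -> None:
        counts = (self.n_par1, self.n_par2, self.n_xtr, self.n_gametolog,
                  self.n_x_specific, self.n_y_specific, self.n_autosomal)
        if any(c < 0 for c in counts):
            raise ValueError("gene counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("toy genome needs at least one gene")
        for d in (self.xtr_divergence, self.gametolog_divergence):
            if not 0.0 <= d <= 1.0:
                raise ValueError("divergence must lie in [0, 1]")


@dataclass
class ToyGenome:
    """A built toy genome with annotation, region map and PAR registry."""

    genome: GenomeSequence
    genes: list[GeneRecord]
    region_map: RegionMap
    registry: ParRegistry
    gene_class: dict[str, str]  # gene_id -> PAR1|PAR2|XTR_X|XTR_Y|GAM_X|GAM_Y|...
    spec: ToyGenomeSpec

    def genes_by_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits):
        # shift by 1..3 within ACGT so the new base always differs
        cur = np.searchsorted(_BASES, out[hits])
        shift = rng.integers(1, 4, size=len(hits))
        out[hits] = _BASES[(cur + shift) % 4]
    return out


class _ChromBuilder:
    def __init__(self, name: str):
        self.name = name
        self.parts: list[np.ndarray] = []
        self.pos = 0  # length so far

    def add(self, seq: np.ndarray) -> tuple[int, int]:
        start = self.pos + 1
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def sequence(self) -> str:
        return np.concatenate(self.parts).tobytes().decode()


def make_toy_genome(spec: ToyGenomeSpec | None = None) -> ToyGenome:
    """Build the toy X/Y/autosome genome.

    X and Y share byte-identical PAR1 (at the chromosome start) and PAR2 (at
    the chromosome end) blocks, including intergenic spacers. XTR gene
    sequences are copied X -> Y and mutated at ``xtr_divergence`` per base;
    gametolog Y copies are mutated at ``gametolog_divergence``. PAR genes are
    annotated on both chromosomes (the Y copy carries a ``_PAR_Y`` suffix,
    the gencode convention). Fully deterministic given the spec's seed.
    """
    spec = spec or ToyGenomeSpec()
    rng = np.random.default_rng(spec.seed)
    glen, ilen = spec.gene_length, spec.intergenic_length

    genes: list[GeneRecord] = []
    gene_class: dict[str, str] = {}

    def record(builder: _ChromBuilder, gid: str, cls: str,
               seq: np.ndarray) -> None:
        start, end = builder.add(seq)
        genes.append(GeneRecord(gene_id=gid, name=gid, chrom=builder.name,
                                start=start, end=end, strand="+"))
        gene_class[gid] = cls
        builder.add(_random_seq(rng, ilen))

    # --- PAR blocks, built once and shared verbatim ---
    par1_genes = [(_random_seq(rng, glen)) for _ in range(spec.n_par1)]
    par1_spacers = [_random_seq(rng, ilen) for _ in range(spec.n_par1 + 1)]
    par2_genes = [(_random_seq(rng, glen)) for _ in range(spec.n_par2)]
    par2_spacers = [_random_seq(rng, ilen) for _ in range(spec.n_par2)]

    def add_par1(builder: _ChromBuilder, suffix: str) -> int:
        builder.add(par1_spacers[0])
        for i, seq in enumerate(par1_genes, 1):
            gid = f"PAR1_G{i}{suffix}"
            start, end = builder.add(seq)
            genes.append(GeneRecord(gid, gid, builder.name, start, end, "+"))
            gene_class[gid] = "PAR1"
            builder.add(par1_spacers[i])
        return builder.pos

    def add_par2(builder: _ChromBuilder, suffix: str) -> int:
        start_pos = builder.pos + 1
        for i, seq in enumerate(par2_genes, 1):
            gid = f"PAR2_G{i}{suffix}"
            start, end = builder.add(seq)
            genes.append(GeneRecord(gid, gid, builder.name, start, end, "+"))
            gene_class[gid] = "PAR2"
            builder.add(par2_spacers[i - 1])
        return start_pos

    # --- X chromosome ---
    x = _ChromBuilder("X")
    par1_len = add_par1(x, "")
    gam_x_seqs = []
    for i in range(1, spec.n_gametolog + 1):
        seq = _random_seq(rng, glen)
        gam_x_seqs.append(seq)
        record(x, f"GAM{i}_X", "GAM_X", seq)
    xtr_x_start = x.pos + 1
    xtr_x_seqs = []
    for i in range(1, spec.n_xtr + 1):
        seq = _random_seq(rng, glen)
        xtr_x_seqs.append(seq)
        record(x, f"XTR_G{i}_X", "XTR_X", seq)
    xtr_x_end = x.pos - ilen if spec.n_xtr else xtr_x_start
    for i in range(1, spec.n_x_specific + 1):
        record(x, f"XGENE_{i}", "X_SPECIFIC", _random_seq(rng, glen))
    record(x, "XIST_LIKE", "XIST", _random_seq(rng, glen))
    par2_x_start = add_par2(x, "")
    x_len = x.pos

    # --- Y chromosome ---
    y = _ChromBuilder("Y")
    add_par1(y, "_PAR_Y")
    for i, seq in enumerate(gam_x_seqs, 1):
        record(y, f"GAM{i}_Y", "GAM_Y", _mutate(seq, spec.gametolog_divergence, rng))
    for i, seq in enumerate(xtr_x_seqs, 1):
        record(y, f"XTR_G{i}_Y", "XTR_Y", _mutate(seq, spec.xtr_divergence, rng))
    for i in range(1, spec.n_y_specific + 1):
        record(y, f"YGENE_{i}", "Y_SPECIFIC", _random_seq(rng, glen))
    record(y, "SRY_LIKE", "SRY", _random_seq(rng, glen))
    par2_y_start = add_par2(y, "_PAR_Y")
    y_len = y.pos

    # --- autosome ---
    a = _ChromBuilder("chr1")
    a.add(_random_seq(rng, ilen))
    for i in range(1, spec.n_autosomal + 1):
        record(a, f"AUTO_{i}", "AUTO", _random_seq(rng, glen))

    genome = GenomeSequence(records=[
        FastaRecord("X", x.sequence()),
        FastaRecord("Y", y.sequence()),
        FastaRecord("chr1", a.sequence()),
    ])
    region_map = RegionMap(
        x_chrom_name="X", y_chrom_name="Y", mito_name="MT",
        par1=MaskInterval("X", 1, par1_len, "PAR1"),
        xtr=MaskInterval("X", xtr_x_start, xtr_x_end, "XTR") if spec.n_xtr else None,
        par2=MaskInterval("X", par2_x_start, x_len, "PAR2"),
    )
    registry = ParRegistry()
    registry.add("toy", [
        MaskInterval("X", 1, par1_len, "PAR1"),
        MaskInterval("X", par2_x_start, x_len, "PAR2"),
        MaskInterval("Y", 1, par1_len, "PAR1"),
        MaskInterval("Y", par2_y_start, y_len, "PAR2"),
    ])
    return ToyGenome(genome=genome, genes=genes, region_map=region_map,
                     registry=registry, gene_class=gene_class, spec=spec)


def write_gtf(genes: Iterable[GeneRecord], path: str | Path,
              source: str = "sccref_toy") -> Path:
    """Write gene rows (feature type "gene") in GTF dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    return path


def make_toy_transcriptome(toy: ToyGenome) -> tuple[GenomeSequence, dict[str, tuple[str, int, int]]]:
    """One unspliced transcript per gene, plus a transcript->span annotation."""
    records, annotation = [], {}
    for g in toy.genes:
        tid = f"{g.gene_id}_T1"
        seq = toy.genome[g.chrom].sequence[g.start - 1: g.end]
        records.append(FastaRecord(tid, seq))
        annotation[tid] = (g.chrom, g.start, g.end)
    return GenomeSequence(records=records), annotation


# ---------------------------------------------------------------------------
# Expression profiles and read simulation
# ---------------------------------------------------------------------------

# Expected reads per gene by class, before scaling to the per-sample total.
# The Y-copy XTR level is deliberately low: most Y-XTR signal under a default
# reference comes from symmetric X-read misassignment, which is the mechanism
# that makes those genes detectable as sex-biased only under the informed
# reference.
_PROFILE_LEVELS = {
    "AUTO": 1500.0,
    "PAR1": 800.0,
    "PAR2": 800.0,
    "XTR_X": 1000.0,
    "XTR_Y": {"XX": 0.0, "XY": 10.0},
    "GAM_X": 600.0,
    "GAM_Y": {"XX": 0.0, "XY": 300.0},
    "X_SPECIFIC": 800.0,
    "XIST": {"XX": 1500.0, "XY": 0.0},
    "Y_SPECIFIC": {"XX": 0.0, "XY": 400.0},
    "SRY": 0.0,  # unexpressed outside testis
}


def make_expression_profile(
    toy: ToyGenome,
    scc: SexChromosomeComplement | str,
    total_reads: int = 50_000,
) -> dict[str, float]:
    """Expected reads per gene for one sample of the given complement.

    Reads originate only from the annotated X copy of the PAR genes (the Y
    copy is byte-identical, so origin is unobservable anyway); XX samples
    emit no Y-origin reads at all. Levels are scaled so expectations sum to
    ``total_reads``.
    """
    scc = SexChromosomeComplement(scc).value
    profile: dict[str, float] = {}
    for gid, cls in toy.gene_class.items():
        level = _PROFILE_LEVELS[cls]
        if isinstance(level, dict):
            level = level[scc]
        if gid.endswith("_PAR_Y"):
            level = 0.0  # PAR expression simulated from the X copy
        profile[gid] = float(level)
    total = sum(profile.values())
    scale = total_reads / total
    return {g: v * scale for g, v in profile.items()}


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    truth_gene: str
    truth_chrom: str
    truth_pos: int  # 1-based
    sample: str


def simulate_reads(
    genome: GenomeSequence,
    genes: Sequence[GeneRecord],
    scc: SexChromosomeComplement | str,
    profile: Mapping[str, float],
    read_len: int = 75,
    error_rate: float = 0.002,
    seed: int = 0,
    sample: str = "S1",
    double_x_dosage: bool = False,
) -> list[SimulatedRead]:
    """Draw reads uniformly from gene bodies, Poisson counts around profile.

    Per-base substitution errors at ``error_rate``; truth labels attached;
    deterministic given the seed. XX profiles must assign zero reads to
    Y-origin genes. ``double_x_dosage`` doubles X-gene output for XX samples.
    """
    scc = SexChromosomeComplement(scc)
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    unknown = [g for g in profile if g not in by_id]
    if unknown:
        raise KeyError(f"profile references unknown genes: {unknown[:5]}")
    if scc is SexChromosomeComplement.XX:
        bad = [g for g, v in profile.items() if v > 0 and by_id[g].chrom in {"Y", "chrY"}]
        if bad:
            raise ValueError(f"XX profile assigns reads to Y-origin genes: {bad}")

    chrom_arrays = {
        r.name: np.frombuffer(r.sequence.encode(), dtype=np.uint8)
        for r in genome.records
    }
    reads: list[SimulatedRead] = []
    for gid in sorted(profile):
        lam = profile[gid]
        gene = by_id[gid]
        if double_x_dosage and scc is SexChromosomeComplement.XX and \
                gene.chrom in {"X", "chrX"}:
            lam *= 2.0
        if lam <= 0:
            continue
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        if gene.end - gene.start + 1 < read_len:
            raise ValueError(f"gene {gid} shorter than the read length")
        arr = chrom_arrays[gene.chrom]
        starts = rng.integers(gene.start, gene.end - read_len + 2, size=n)  # 1-based
        windows = arr[(starts[:, None] - 1) + np.arange(read_len)[None, :]].copy()
        if error_rate > 0:
            err = rng.random(windows.shape) < error_rate
            if err.any():
                pos = np.where(err)
                cur = np.searchsorted(_BASES, windows[pos])
                shift = rng.integers(1, 4, size=len(pos[0]))
                windows[pos] = _BASES[(cur + shift) % 4]
        for i in range(n):
            reads.append(
                SimulatedRead(
                    read_id=f"{sample}:{gid}:{i}",
                    sequence=windows[i].tobytes().decode(),
                    truth_gene=gid,
                    truth_chrom=gene.chrom,
                    truth_pos=int(starts[i]),
                    sample=sample,
                )
            )
    return reads


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> Path:
    """Write reads as FASTQ with a constant PHRED-40 quality string."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return path


# ---------------------------------------------------------------------------
# k-mer seed-and-verify best-hit assigner
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerIndex:
    """Exact k-mer postings over both strands plus raw byte arrays.

    A posting (chrom, pos, '+') means the k-mer occurs on the forward strand
    at 1-based ``pos``; (chrom, pos, '-') means its reverse complement does.
    k-mers containing N are never indexed, so hard-masked sequence holds no
    postings and attracts no reads.
    """

    k: int
    postings: dict[str, list[tuple[str, int, str]]]
    arrays: dict[str, np.ndarray]


def build_kmer_index(genome: GenomeSequence, k: int = 21) -> KmerIndex:
    if k < 11:
        raise ValueError("k must be >= 11")
    postings: dict[str, list[tuple[str, int, str]]] = {}
    arrays = {}
    for rec in genome.records:
        seq = rec.sequence
        arrays[rec.name] = np.frombuffer(seq.encode(), dtype=np.uint8)
        name = rec.name
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            postings.setdefault(km, []).append((name, i + 1, "+"))
            postings.setdefault(_revcomp(km), []).append((name, i + 1, "-"))
    return KmerIndex(k=k, postings=postings, arrays=arrays)


@dataclass
class ReadAssignment:
    read_id: str
    best_hits: list[tuple[str, int, str, int]]  # (chrom, pos, strand, mismatches)
    n_best: int
    primary: int | None  # index into best_hits; None = unmapped
    read_len: int

    @property
    def primary_hit(self) -> tuple[str, int, str, int] | None:
        return None if self.primary is None else self.best_hits[self.primary]


def assign_read(
    read: SimulatedRead,
    index: KmerIndex,
    max_mismatch: int = 4,
    seed: int = 0,
    rule: str = "random",
) -> ReadAssignment:
    """Assign one read: seed k-mers at stride k, verify ungapped, pick primary.

    Candidate loci come from exact seed hits; each is verified by full-length
    Hamming comparison in which N matches nothing. ``best_hits`` are the
    candidates at the minimal mismatch count (<= ``max_mismatch``). With
    ``rule="random"`` the primary is drawn uniformly among equal-best hits by
    a generator seeded from (run seed, read id); ``rule="first"`` takes the
    lexicographically first locus for fully deterministic audits. An
    unmapped read is a result, not an error.
    """
    k = index.k
    seq = read.sequence
    L = len(seq)
    if k > L:
        raise ValueError("k exceeds the read length")
    offsets = list(range(0, L - k + 1, k))
    if offsets[-1] != L - k:
        offsets.append(L - k)

    postings = index.postings
    candidates: set[tuple[str, int, str]] = set()
    for o in offsets:
        hits = postings.get(seq[o : o + k])
        if not hits:
            continue
        for chrom, pos, strand in hits:
            if strand == "+":
                start = pos - o
            else:
                start = pos - (L - o - k)
            candidates.add((chrom, start, strand))

    read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc_arr = None
    scored: list[tuple[str, int, str, int]] = []
    best_mm = max_mismatch + 1
    for chrom, start, strand in candidates:
        arr = index.arrays[chrom]
        if start < 1 or start + L - 1 > len(arr):
            continue
        window = arr[start - 1 : start - 1 + L]
        if strand == "+":
            mm = int(np.count_nonzero(window != read_arr))
        else:
            if rc_arr is None:
                rc_arr = np.frombuffer(_revcomp(seq).encode(), dtype=np.uint8)
            mm = int(np.count_nonzero(window != rc_arr))
        if mm <= max_mismatch:
            scored.append((chrom, start, strand, mm))
            if mm < best_mm:
                best_mm = mm

    best = sorted(h for h in scored if h[3] == best_mm)
    if not best:
        return ReadAssignment(read.read_id, [], 0, None, L)
    if len(best) == 1 or rule == "first":
        primary = 0
    elif rule == "random":
        rng = np.random.default_rng(
            (seed & 0x7FFFFFFF, zlib.crc32(read.read_id.encode()))
        )
        primary = int(rng.integers(len(best)))
    else:
        raise ValueError(f"unknown primary-selection rule {rule!r}")
    return ReadAssignment(read.read_id, best, len(best), primary, L)


def assign_reads(
    reads: Sequence[SimulatedRead],
    index: KmerIndex,
    max_mismatch: int = 4,
    seed: int = 0,
    rule: str = "random",
) -> list[ReadAssignment]:
    return [assign_read(r, index, max_mismatch, seed, rule) for r in reads]


# ---------------------------------------------------------------------------
# Primary-alignment counting
# ---------------------------------------------------------------------------

@dataclass
class AssignedCounts:
    """Gene counts from primary assignments plus per-read fate tallies."""

    counts: dict[str, int]
    fates: dict[str, int]  # assigned | ambiguous_gene_overlap | intergenic | unmapped
    chrom_totals: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.fates.values())


def count_primary(
    assignments: Sequence[ReadAssignment],
    genes: Sequence[GeneRecord],
) -> AssignedCounts:
    """Count primary alignments into genes.

    A primary overlapping exactly one gene is assigned; overlapping more than
    one is ambiguous (not counted); none is intergenic; unmapped reads pass
    through. Fates always sum to the number of reads. ``chrom_totals`` tallies
    every mapped primary (whatever its gene fate) by chromosome.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree coordinates over the 1-based inclusive gene span
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)

    counts = {g.gene_id: 0 for g in genes}
    fates = {"assigned": 0, "ambiguous_gene_overlap": 0, "intergenic": 0, "unmapped": 0}
    chrom_totals: dict[str, int] = {}
    for a in assignments:
        hit = a.primary_hit
        if hit is None:
            fates["unmapped"] += 1
            continue
        chrom, pos, _, _ = hit
        chrom_totals[chrom] = chrom_totals.get(chrom, 0) + 1
        tree = trees.get(chrom)
        overlapping = tree.overlap(pos, pos + a.read_len) if tree is not None else ()
        if len(overlapping) == 1:
            counts[next(iter(overlapping)).data] += 1
            fates["assigned"] += 1
        elif len(overlapping) > 1:
            fates["ambiguous_gene_overlap"] += 1
        else:
            fates["intergenic"] += 1
    return AssignedCounts(counts=counts, fates=fates, chrom_totals=chrom_totals)


# ---------------------------------------------------------------------------
# End-to-end default-vs-informed experiment
# ---------------------------------------------------------------------------

def toy_marker_panel(toy: ToyGenome) -> MarkerPanel:
    """Marker panel over the toy gametologs, XIST-like and SRY-like genes."""
    n = toy.spec.n_gametolog
    return MarkerPanel(
        y_markers=[f"GAM{i}_Y" for i in range(1, n + 1)],
        x_partners=[f"GAM{i}_X" for i in range(1, n + 1)],
        xist="XIST_LIKE",
        sry="SRY_LIKE",
    )


@dataclass
class ExperimentResult:
    toy: ToyGenome
    counts_default: CountMatrix
    counts_informed: CountMatrix
    read_totals: pd.DataFrame  # per sample x reference x chromosome
    fold_change: ComparisonResult
    region_summaries: dict[str, pd.DataFrame]
    chrom_tests: pd.DataFrame
    scc_calls: list[SccCall]
    de_default: list[DeResult]
    de_informed: list[DeResult]
    de_comparison: DeComparison
    seed: int


def quantify_sample(
    reads: Sequence[SimulatedRead],
    index: KmerIndex,
    genes: Sequence[GeneRecord],
    seed: int,
    max_mismatch: int = 4,
) -> AssignedCounts:
    return count_primary(assign_reads(reads, index, max_mismatch, seed), genes)


def run_experiment(
    spec: ToyGenomeSpec | None = None,
    n_xx: int = 10,
    n_xy: int = 10,
    total_reads: int = 50_000,
    seed: int = 17,
    out_dir: str | Path | None = None,
    de_cutoff: float = 0.01,
) -> ExperimentResult:
    """Run the full default-vs-informed comparison on the toy genome.

    Each sample's reads are assigned twice: against the default toy
    reference and against its SCC-informed reference (Y-masked for XX,
    YPAR-masked for XY). Primary counts feed normalization, SCC inference,
    per-gene/per-region fold changes, paired per-chromosome read-total
    tests and moderated differential expression under both references.
    SCC-inference thresholds are set to floor + 3 log2-CPM from the actual
    library sizes (the spec-level defaults assume multi-million-read
    libraries; the floor log2(prior/L) moves with L).
    """
    if n_xx < 2 or n_xy < 2:
        raise ValueError("need >=2 samples per complement for the DE stages")
    spec = spec or ToyGenomeSpec(seed=seed)
    toy = make_toy_genome(spec)

    default_index = build_kmer_index(toy.genome)
    y_masked = build_informed_genome(toy.genome, "XX", toy.registry, "toy", "Y")
    ypar_masked = build_informed_genome(toy.genome, "XY", toy.registry, "toy", "Y")
    informed_index = {"XX": build_kmer_index(y_masked), "XY": build_kmer_index(ypar_masked)}

    samples = [(f"XX_{i + 1:02d}", "XX") for i in range(n_xx)] + [
        (f"XY_{i + 1:02d}", "XY") for i in range(n_xy)
    ]
    gene_ids = [g.gene_id for g in toy.genes]
    counts_d: dict[str, dict[str, int]] = {}
    counts_i: dict[str, dict[str, int]] = {}
    totals_rows = []
    for s_idx, (sample, scc) in enumerate(samples):
        profile = make_expression_profile(toy, scc, total_reads)
        read_seed = int(np.random.default_rng((seed & 0x7FFFFFFF, s_idx)).integers(2**31))
        reads = simulate_reads(toy.genome, toy.genes, scc, profile,
                               seed=read_seed, sample=sample)
        for ref_label, index in (("default", default_index), ("informed", informed_index[scc])):
            ac = quantify_sample(reads, index, toy.genes, seed=read_seed)
            (counts_d if ref_label == "default" else counts_i)[sample] = ac.counts
            row = {"sample": sample, "sex": "female" if scc == "XX" else "male",
                   "scc": scc, "reference": ref_label, **{
                       f"reads_{c}": ac.chrom_totals.get(c, 0)
                       for c in toy.genome.names}}
            row.update({f"fate_{k}": v for k, v in ac.fates.items()})
            totals_rows.append(row)
    read_totals = pd.DataFrame(totals_rows)

    sex_of = {s: ("female" if scc == "XX" else "male") for s, scc in samples}
    sample_meta = pd.DataFrame(
        {"sex": pd.Series(sex_of), "scc": {s: scc for s, scc in samples}}
    )
    cm_default = CountMatrix(
        counts=pd.DataFrame(counts_d, columns=[s for s, _ in samples]).loc[gene_ids],
        sample_meta=sample_meta.copy(),
    )
    cm_informed = CountMatrix(
        counts=pd.DataFrame(counts_i, columns=[s for s, _ in samples]).loc[gene_ids],
        sample_meta=sample_meta.copy(),
    )

    regions = region_lookup(toy.genes, toy.region_map)
    classes = class_lookup(toy.genes, toy.region_map)

    expr_default = log_cpm(cm_default)
    expr_informed = log_cpm(cm_informed)
    fc = per_gene_fold_change(expr_informed, expr_default, groups=sex_of)

    region_summaries = {
        label: region_summary(expr, regions, groups=sex_of, cpm_values=cpm(cm))
        for label, expr, cm in (
            ("default", expr_default, cm_default),
            ("informed", expr_informed, cm_informed),
        )
    }

    # paired per-chromosome read totals, default vs informed
    test_rows = []
    for chrom in toy.genome.names:
        col = f"reads_{chrom}"
        wide = read_totals.pivot(index="sample", columns="reference", values=col)
        try:
            t, df_, p_t = paired_t(wide["default"], wide["informed"])
        except ValueError:
            t, df_, p_t = np.nan, len(wide) - 1, np.nan
        try:
            w, p_w = wilcoxon_signed_rank(wide["default"], wide["informed"])
        except ValueError:
            w, p_w = np.nan, np.nan
        test_rows.append({"chrom": chrom, "t": t, "df": df_, "p_t": p_t,
                          "W": w, "p_wilcoxon": p_w})
    chrom_tests = pd.DataFrame(test_rows)

    # SCC inference from the default-reference quantification
    floor = float(np.log2(0.25 / expr_default.l_millions.median()))
    calls = infer_scc(expr_default, toy_marker_panel(toy),
                      tau_y=floor + 3.0, tau_x=floor + 3.0)

    # moderated DE per reference
    de_results = {}
    for label, cm in (("default", cm_default), ("informed", cm_informed)):
        filtered = filter_min_cpm(cm, sex_of, min_cpm=1.0)
        factors = tmm_factors(filtered)
        expr = log_cpm(filtered, tmm_factors=factors)
        de_results[label] = moderated_de(expr, sex_of, cutoff=de_cutoff, classes=classes)
    comparison = de_overlap(de_results["default"], de_results["informed"], de_cutoff)

    result = ExperimentResult(
        toy=toy,
        counts_default=cm_default,
        counts_informed=cm_informed,
        read_totals=read_totals,
        fold_change=fc,
        region_summaries=region_summaries,
        chrom_tests=chrom_tests,
        scc_calls=calls,
        de_default=de_results["default"],
        de_informed=de_results["informed"],
        de_comparison=comparison,
        seed=seed,
    )
    if out_dir is not None:
        _write_experiment(result, Path(out_dir))
    return result


def _write_experiment(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.toy.genome, out_dir / "toy_genome.fa")
    write_gtf(result.toy.genes, out_dir / "toy_genes.gtf")
    result.counts_default.to_tsv(out_dir / "counts_default.tsv")
    result.counts_informed.to_tsv(out_dir / "counts_informed.tsv")
    result.read_totals.to_csv(out_dir / "read_totals.tsv", sep="\t", index=False)
    result.fold_change.fold_change.to_csv(out_dir / "fold_change.tsv", sep="\t")
    for label, summ in result.region_summaries.items():
        summ.to_csv(out_dir / f"region_summary_{label}.tsv", sep="\t", index=False)
    result.chrom_tests.to_csv(out_dir / "chrom_tests.tsv", sep="\t", index=False)
    calls_to_frame(result.scc_calls).to_csv(out_dir / "scc_calls.tsv", sep="\t")
    de_frame(result.de_default).to_csv(out_dir / "de_default.tsv", sep="\t")
    de_frame(result.de_informed).to_csv(out_dir / "de_informed.tsv", sep="\t")
    comp = result.de_comparison
    manifest = {
        "seed": result.seed,
        "spec": asdict(result.toy.spec),
        "n_samples": len(result.counts_default.samples),
        "de_overlap": {
            "joint": sorted(comp.joint),
            "unique_to_informed": sorted(comp.unique_to_informed),
            "unique_to_default": sorted(comp.unique_to_default),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
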