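# Methods

## Problem and model

Bulk and single-cell RNA-seq quantification assumes reads can be placed at
their locus of origin. On the human sex chromosomes this assumption fails in
three regions: PAR1 and PAR2 are byte-identical between X and Y (they still
recombine), and the XTR is ~98.78% identical (a post human–chimp X→Y
duplication that no longer recombines). A read from a PAR gene therefore has
two equally good alignments, and aligners resolve the tie arbitrarily —
typically by a pseudo-random primary-alignment choice — sending half of the
PAR signal to the Y annotation copy in every sample, including XX samples
with no Y chromosome at all.

The remedy implemented here is *sex-chromosome-complement (SCC) informed
alignment*: samples without a Y are quantified against a reference whose Y
is entirely hard-masked with Ns; samples with a Y against one whose Y PARs
are hard-masked. Hard-masking (never deletion) is used so all references
share one chromosome set and downstream tools see identical sequence
dictionaries. The XTR is deliberately **not** masked in the YPAR-masked
build: it is diverged between X and Y and genuinely transcribed from the
male Y, so masking it would delete real signal; its divergence is enough for
most 75-bp reads to map uniquely.

Coordinates are 1-based inclusive everywhere (the GTF convention, and the
convention of the published PAR coordinates); BED input is converted at the
parser boundary. Two GRCh38 PAR coordinate systems ship in the registry —
the full-assembly coordinates (X/Y PAR1 10,001–2,781,479; X PAR2
155,701,383–156,030,895; Y PAR2 56,887,903–57,217,415) and the Ensembl
Y-sequence coordinates (Y PAR1 6,001–2,699,520; Y PAR2
154,931,044–155,260,560). They are not interchangeable; the caller must name
one, because the correct choice depends on which Y sequence build is being
masked. Masking rewrites *every* base inside an interval to `N`, including
IUPAC ambiguity codes; bases outside intervals are byte-identical to the
input.

## Expression statistics

- **log-CPM.** Values are `log2(CPM + prior/L) = log2((count + prior)/L)`,
  with `L` the library size in millions and a default prior count of 0.25. A
  zero count maps to the per-sample floor `log2(prior/L)`; at `L = 79.76`
  (the average library of the motivating large-cohort data) the floor is
  −8.32. The prior is a flag (`--prior`) since a prior of 2 is also in
  circulation; every threshold expressed in log-CPM units is therefore
  prior- and library-size-dependent.
- **Expression filter.** A gene is kept when its mean CPM reaches 1 in at
  least one sex group (at `L = 79.76` this is ≈79 counts). The filter is
  applied before normalization, with library sizes computed on the unfiltered
  matrix; genes with all-zero counts in one group (Y genes in XX samples
  under an informed reference) are retained — their absence *is* the signal.
- **TMM.** Scaling factors follow the published trimmed-mean-of-M-values
  definition: upper-quartile-closest-to-mean reference column (ties broken
  by lowest index), 30% two-sided trim on M values and 5% on A values by
  rank, inverse asymptotic binomial variances as weights, factors rescaled to
  geometric mean 1. Cross-checked against edgeR `calcNormFactors` to 1e-6.
- **Paired tests.** Mapped-read totals per chromosome are compared between
  references paired by sample, with the two-sided paired t and the Wilcoxon
  signed rank (exact null for n ≤ 25 after dropping zero differences, normal
  approximation with continuity correction above). All-identical differences
  are an error, not a p-value.
- **Fold changes.** Per-gene informed-minus-default mean log2-CPM differences
  paired by sample; positive = higher under the informed reference.

## Moderated differential expression

DE between the sexes uses a two-group linear model on log2-CPM with
empirical-Bayes variance moderation and no precision weights. Per gene,
`logFC` is the male-minus-female mean difference and s² the pooled residual
variance with `d = n₁+n₂−2` df. The scaled-inverse-chi-square prior
`(d₀, s₀²)` is estimated by moment-matching the marginal scaled-F
distribution of the s²: with `e = log s² − ψ(d/2) + log(d/2)`,
`s₀²` and `d₀` solve `ψ'(d₀/2) = var(e) − ψ'(d/2)` (trigamma inverse by
Newton iteration) and `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`. When the
observed spread of log s² does not exceed chi-square sampling noise, `d₀` is
infinite and `s₀²` is the plain mean of the s² values. The moderated t uses
the posterior variance `s̃² = (d₀s₀² + ds²)/(d₀+d)` with `d₀+d` df, capped
at the pooled residual df across genes (the prior cannot carry more
information than the data as a whole). Genes with zero residual variance are
excluded from prior estimation but still tested. A single-gene matrix falls
back to the ordinary t test and is flagged. The implementation agrees with
limma `lmFit`+`eBayes` to ~1e-4 relative on t and p in the cross-check test,
and its raw p-values reject at 5.0% ± 1% on null simulations.

Significance is Benjamini–Hochberg adjusted p strictly below 0.01 (a
conservative cutoff; exact ties at the cutoff are not significant). DE-set
comparison between references is pure set algebra over the significant
genes, with counts partitioned by chromosome class (X-linked / Y-linked /
autosomal / mito) and direction (up-in-male / up-in-female).

## SCC inference

`y_present` is a strict-majority vote of the available Y gametolog markers
(log2-CPM > τ_Y), never a single gene — individual Y gametologs pick up
misaligned X reads under a default reference. `multi_x` is XIST log2-CPM >
τ_X. XY = Y present and one X; XX = no Y and more than one X; the two
contradictory combinations are explicit ambiguous calls (loss-of-Y,
XXY-like, and reactivated-X states cannot be resolved from expression
alone), and every call carries its marker values for human override. SRY is
reported but excluded from the vote by default (essentially testis-limited);
a flag includes it. The API defaults τ_Y = 1.0 and τ_X = 2.0 log2-CPM suit
multi-million-read libraries, where the zero-count floor sits far below
them. Because the floor `log2(prior/L)` rises as libraries shrink, the toy
experiment derives its thresholds as floor + 3 log2-CPM from the actual
library sizes rather than using the absolute defaults.

## Toy simulator

The simulator generates the *mechanism*, not the species: a toy X and Y
sharing byte-identical PAR1/PAR2 blocks (genes and intergenic spacers
included) at the chromosome tips, an XTR whose Y copy is mutated at 1.22%
per base (the 98.78% homology figure), gametolog pairs at 10% divergence
(old X–Y pairs such as DDX3X/Y are far more diverged than the XTR),
X-specific genes including an XIST-like female-only gene, Y-specific genes
including a silent SRY-like gene, and an autosome. Defaults: 4 PAR1, 2 PAR2,
3 XTR, 4 gametolog pairs, 3+1 X-specific, 2+1 Y-specific, 20 autosomal
genes; gene bodies 3 kb, spacers 500 bp. PAR genes are annotated on both
chromosomes, the Y copy with a `_PAR_Y` suffix (the gencode convention).
Everything is deterministic given the spec seed.

Reads are 75 bp single-end, drawn uniformly from gene bodies with Poisson
counts around a per-gene expected-reads profile and 0.2% per-base
substitution error. The default profile gives each sample ~50,000 reads;
XIST-like expression is profile-level (expressed only in XX samples) rather
than mechanistic. The Y-copy XTR level is set low (10 expected reads vs
1000 for X copies) so that, under the default reference, male and female
Y-XTR counts are both dominated by the same symmetric misassignment of
X-copy reads — which is exactly why those genes become detectable as
sex-biased only under the informed reference, the asymmetry the method
exists to expose. Optional doubled X dosage for XX samples is off by
default so that reference choice, not dosage, drives every comparison.

The assigner is a model of a spliced aligner's primary-alignment behaviour,
not a reimplementation: exact 21-mer seeds at stride k (plus the final
window), candidates verified by full-length ungapped Hamming comparison in
which `N` matches nothing, best hits = minimal mismatches ≤ 4, and the
primary drawn uniformly among equal-best hits by a generator seeded from
(run seed, CRC32 of the read id) — reproducible yet statistically uniform,
so error-free PAR reads split exactly 50/50 in expectation under the default
reference. A `first`-hit rule is available for fully deterministic audits.
Ungapped verification is sufficient because toy genes are unspliced; indels,
quality models and paired ends are out of scope since the phenomenon under
test is locus ambiguity, not fragment modelling. Only primary alignments are
counted: a primary overlapping exactly one gene is assigned, more than one
is ambiguous (not counted), none is intergenic; fates always sum to the read
count.

What passing toy tests shows — and does not. The simulator demonstrates the
masking mechanism end to end (Y reads vanish for XX samples, PAR expression
doubles, XTR gains appear only in XX, the informed DE set strictly contains
the default set) with known truth. It does not model splicing, paired-end
fragments, 3' bias, contigs/alt scaffolds, or real marker-gene expression
variability, so real-data thresholds (notably τ_Y/τ_X) should be reviewed
against the per-marker values the caller reports.

## Problem sizes and numerical choices

The shipped experiment uses 10 XX + 10 XY samples × ~50k reads — large
enough that binomial noise on the PAR split is ~1% and every DE effect is
decisive, while a full run (two references, twenty samples, inference, DE)
completes in well under a minute on one CPU. The acceptance script uses 10 XX
samples × 50k reads for the Y-read-decrease computation. Reference-sample
ties in TMM break to the lowest column index; BH adjustment uses a stable
sort so equal p-values keep input order; the trigamma inverse iterates
Newton to 1e-8 relative. Degenerate inputs are errors, not silent defaults:
empty FASTA, zero library sizes, intervals past a record end, all-zero
paired differences, groups with fewer than two samples.

## Known limitations

- The moderated-t procedure deliberately omits voom precision weights; on
  strongly mean-dependent count noise limma-voom will differ.
- The SCC caller is expression-based and cannot distinguish loss-of-Y or
  XXY-like states from technical artefacts; ambiguous calls require human
  review (DNA-based ploidy estimation is the gold standard and out of
  scope).
- XTR coordinates for real genomes are not bundled (they are not part of the
  standard PAR definitions); region summaries label XTR only when the user
  supplies an interval.
- The k-mer assigner has no splice awareness and must not be used on real
  spliced reads; it exists to make reference-masking consequences measurable
  at desk scale.
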