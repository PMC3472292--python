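# Methods

This note documents the models and procedures implemented in `lmseq`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Coordinates and data model

All in-memory coordinates are 0-based half-open; conversion to the 1-based
closed GFF convention happens only at file boundaries. The data model is
unstranded at the read level: oligo-dT-primed libraries and twice-amplified
aRNA carry no usable strand information, so gene strand is used only to
decide which end of a gene is its 3' end. Genes are single-transcript; when
a GFF gene carries several mRNAs the first (by coordinate, then ID) is used
with a warning. A gene's `exons` span the full mRNA footprint including any
annotated UTRs; the CDS is stored as its genomic span, whose endpoints must
fall inside exons. A read is *unique* when its `NH` tag equals 1, or — with
no `NH` tag — when MAPQ > 3 (splice mappers historically encoded
multi-mapping in MAPQ); only primary, unique alignments are counted
anywhere.

## Read cleaning

Three rules, applied in order per read: (1) any read containing `N` is
discarded (checked on the untrimmed sequence, since undetermined bases
signal a bad cluster regardless of position); (2) bases are trimmed from
the 3' end while the terminal quality is below `min_q` (default phred 10) —
strict suffix trimming that stops at the first base at or above threshold,
even if lower-quality bases remain further 5'; (3) reads longer than 20
bases after trimming are kept (`min_len_keep` = 21, strict). Cleaning is
idempotent and monotone in `min_q`.

## UTR modeling

For each gene and each side, the walk starts just outside the annotated
exon footprint and extends while per-base coverage ≥ `min_cov` (default 2
reads), tolerating at most `max_gap` (10) consecutive sub-threshold bases —
a gap is only included when covered bases follow it, so extensions always
end on a covered base. The walk stops at `max_extent` (2000 bases, about
four times a typical fungal UTR) or at the nearest neighbouring gene
boundary, whichever comes first. A side yields a UTR call when the
extension is at least one base. Defaults favour sensitivity: two
overlapping reads are weak but real evidence, and the 10-base gap tolerance
bridges coverage dropouts at homopolymers without jumping into neighbouring
transcription units.

UTRs are modeled on genomic coordinates: a UTR that itself contains an
intron is recovered as its genomic extent. Coverage evidence is pooled
across all samples in the pipeline — sampling several growth conditions
raises the number of expressed genes and hence of genes with usable
evidence.

Accuracy depends on coverage at the transcript ends: with uniform read
starts the expected coverage decays linearly over the last read-length
bases of the transcript, so the recovered terminus systematically stops
where coverage last reaches `min_cov`. At ~20× mean coverage this bias is
a few bases; at the 5× floor it can reach tens of bases for individual
genes. The terminus-recovery error also grows mildly with transcript
length (longer transcripts spread the same reads thinner), which is why
the length-independence property of 3'-window counting is assessed on
exact mRNA extents (see below).

## Intron refinement

Splice junctions are block gaps of spliced alignments, aggregated per
distinct (contig, donor end, acceptor start) with read-count support.
Per gene: a junction identical to an annotated intron *confirms* it (any
support); a junction with support ≥ `min_support` (2) overlapping an
annotated intron *replaces* it; a junction fully inside an exon *splits*
it. Any change that would create an empty exon, or violate the gene-model
invariants (e.g. swallow a CDS endpoint), is rejected and reported, leaving
the gene unchanged. Junctions outside all gene spans are reported as
candidates only — novel gene annotation remains a manual step. Requiring
two supporting reads suppresses one-off alignment artifacts while retaining
sensitivity at moderate depth.

## Quantification

**Both-ends counting.** A read counts for gene *g* iff it is > 34 bases,
primary, unique, and both terminal aligned bases lie within *g*'s exonic
footprint (CDS + UTRs); internal blocks are unconstrained, so spliced reads
across *g*'s introns count normally. Reads whose ends hit different genes,
or one end outside any gene, are not counted. The rule deliberately
sacrifices boundary-straddling reads to avoid counting spurious mappings —
the direct consequence, reproduced by the tests, is that genes with
unannotated 3' UTRs lose counts under 3'-biased libraries, which is the
motivation for modeling UTRs before counting.

**Region classification.** Each eligible alignment is assigned to
exon/intron/intergenic by the majority of its aligned bases (ties broken
exon > intron > intergenic); a read whose bases are split across two or
more genes with no gene holding a strict majority is ambiguous.

**3'-window counting.** The window is the transcript-coordinate interval
[100, 400) measured from the 3' end (half-open; strand-aware), projected
through the exon chain to genomic blocks; transcripts shorter than 400
bases use [100, length), and transcripts of ≤ 100 bases have an empty
window. A read counts when both terminal bases fall in the projected
window. Because every transcript contributes at most a 300-base target,
counts are insensitive to transcript length and to 5' loss from linear
amplification — provided the mRNA 3' ends are correct. Window counts
inherit the terminus error of modeled UTRs; on exact extents, window
counts of constant-expression genes are uncorrelated with length
(|ρ| < 0.01 in validation), while anchoring on modeled termini leaves a
residual |ρ| ≈ 0.18 driven by the length-dependent terminus bias above.

**Normalization.** CPM: counts divided by the per-sample total of counted
reads × 10⁶, with the total defined as the column sum of the gene-count
matrix. This is a *relative* (compositional) normalization — see the
differential-expression caveat below.

## Differential expression

**Classical analysis.** Replicate i of condition A pairs with replicate i
of B (all pairwise ratios when replicate numbers differ); a ratio is
defined only where the denominator CPM is positive, and genes with no
defined ratio are excluded. The group criteria (4: all ratios ≥ 4 or all
≤ 0.25; 3: mean ≥ 4 or ≤ 0.25 and CV < 0.5; 2: all ≥ 2 or all ≤ 0.5;
1: mean ≥ 2 or ≤ 0.5 and CV < 0.5; else 0) are evaluated highest-first.
The "all replicates" criteria require directional consistency: two ratios
of 2.0 and 0.5 both clear 2-fold but disagree in direction and land in
group 0. The standard deviation uses the n−1 denominator; a single defined
ratio gets sd = 0.

**Bayesian rate ratio.** Counts are pooled per condition; the per-read
rate λ gets a Gamma(Σk + ½, Σtotal) posterior (Jeffreys prior with the
sample totals as exposure). 10,000 seeded Monte-Carlo draws of λ_A/λ_B
yield the posterior mean, the equal-tailed 95% interval and
p_diff = max(P(ratio > 1), P(ratio < 1)) ∈ [0.5, 1]. The model is a
deliberate stand-in for count-ratio methods with Bayesian credible
intervals; it makes no claim of equivalence to any particular program.
Its calibration is validated directly: the 95% interval covers the true
simulated ratio 94.6% of the time over 1000 genes.

**Consensus.** With threshold T (4 for like-vs-like comparisons, 8 for
microdissected-vs-total, where residual annotation bias inflates apparent
changes): call +1 iff the classical mean ratio > T, the Bayesian posterior
mean > T, p_diff ≥ p_min and the classical group is 1–4; −1 mirrors this
below 1/T. "Probability = 1" is implemented as p_diff ≥ 0.999 because a
finite Monte-Carlo estimate never equals 1 exactly; with 10,000 draws the
threshold corresponds to at most ~10 opposing draws. Missing either
component yields 0.

**Compositional caveat.** CPM ratios estimate *relative* changes. If a
large fraction of the transcriptome rises, every normalized ratio is
compressed by the growth of the total: 10% of genes rising 16-fold roughly
doubles a sample's total and halves all observed ratios, parking true
changers at the 8-fold decision boundary. The two-threshold design and the
validation scenarios assume the DE mass is a modest share of the total; the
DE-recovery benchmark therefore simulates its 16-fold changes downward
(also the dominant direction in microdissected-tissue comparisons, where
most calls are losses relative to total mycelium).

**MA tables.** M = log₂(mean A / mean B) with zero denominator → +20 and
zero numerator → −20 exactly (genes zero on both sides have no ratio);
A is the mean normalized count over all replicates of both conditions.

## Reporting

Top-N sets use the average normalized 3'-window count across the
replicates of each condition; ties at the boundary break lexicographically
by gene id for determinism. The overlap table enumerates every non-empty
Venn cell; cells partition the union. Expression levels are mean per-base
mRNA coverage × 10⁹ / total aligned bases (coverage per kilobase per
million counted bases); zero-coverage genes are excluded from the log₂
set, fits are refused below 10 genes. The mixture is 1-D Gaussian with
spherical components, fitted for k = 1..3 by EM (three initialisations,
reg_covar 10⁻⁶) and selected by BIC among fits whose smallest weight is at
least 1/n, so a chosen k never carries an effectively empty component.
k_max = 3 matches the most structure reported for such distributions.

## Synthetic data generator

The generator emulates the study design: random genomes (default 4 × 120 kb
contigs), non-overlapping genes with ≥ 500-base intergenic gaps, 1–4 exons
per gene with 50–120-base introns carrying canonical GT..AG (strand-aware)
motifs, UTR lengths drawn uniformly from 50–260 (5') and 100–420 (3')
bases — bracketing the median UTR lengths reported for filamentous fungi —
and log-normal per-gene expression (σ = 1 by default). Two conditions with
two biological replicates each and 50,000 reads of 50 bases per sample are
the defaults; a `de_fraction` of genes (10%) changes `de_fold_change`-fold
(16×) in conditions after the first, with direction configurable
(both/up/down). Reads per gene are proportional to expression with Poisson
noise (a negative-binomial option with gamma-Poisson mixing covers
between-replicate overdispersion); note reads are *not* proportional to
transcript length, so full-length counts are length-independent by
construction.

Read starts on the spliced transcript are uniform (`uniform`,
mycelium-like) or 3'-biased (`three_prime`, LM-like): the read 3'-end
distance from the transcript 3' end follows an exponential with scale
`bias_decay` (150 bases) truncated to the feasible range. The truncated
exponential is a stand-in for the unknown functional form of
amplification's 5' loss and is exposed as a configuration knob. Alignments
are emitted directly as truth (the mapping stage is bypassed): spliced
reads become multi-block SAM records with N skips, flag 0, MAPQ 50,
`NH:i:1`. Qualities follow a linear 3'-degradation profile (baseline 38,
0.1 phred/base) and bases are replaced by `N` at rate 0.002.

Not emulated: substitution sequencing errors, GC or hexamer-priming bias,
multi-mapping, paired ends, alternative isoforms, real mapper artifacts.
Passing tests therefore certify the *rules* (counting semantics, walk
logic, decision thresholds) and their statistical behaviour under the
stated noise models — not robustness to alignment error or biases the
generator does not produce.

## Validation scenario sizes

The scenarios in `lmseq.validation` (shared by the test suite and
`scripts/acceptance.py`) use: 10,000 fuzzed reads (cleaning), a 50-gene /
10,000-read instance (counting), 10,000 random ratio vectors plus a
720-row enumeration (classification), 100 genes at ~20× uniform coverage
(UTR recovery; comfortably above the 5× floor the walk needs), 40 genes /
20 corrupted boundaries (intron recovery), 200 genes × 2 conditions × 2
replicates at 200,000 reads per sample (DE recovery; ≥ 300 expected counts
per changer), 150 genes at 120,000 reads (3'-bias robustness), n = 5000
(mixture recovery), and a 20-gene full-pipeline fixture run twice
(determinism). The generator-level expression-recovery check runs 200
genes at 300,000 reads (Spearman ρ > 0.95 against truth).

## Known limitations

* UTR calls carry a coverage-dependent terminus bias (short by the bases
  where coverage falls below `min_cov`); they are extents, not polyA sites.
* Spliced UTRs are recovered as genomic extents.
* The consensus caller has no multiple-testing control by design — the
  fold thresholds and the p_diff ≈ 1 requirement are the stringency
  mechanism, and the empirical false-positive rate on nulls is validated
  instead.
* CPM normalization is compositional; interpretability of fold thresholds
  degrades when a large share of the transcriptome changes in one
  direction.
* Overlapping genes share no reads under both-ends counting (ends hitting
  two genes at once are ambiguous); the generator never places overlapping
  genes, so this path is only exercised by hand-built fixtures.
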