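# Methods

This note documents the models, conventions and design choices behind
`snbias`, in the order the pipeline runs them.

## Synthetic experiment

The generator emulates one tumor model profiled under three dissociation
protocols (warm, cold, nuclei) with a shared gene universe.

**Gene universe.** Gene-body length is log-normal,
`L ~ round(LogNormal(9.2, 1.3))` nt floored at 200 (median ≈ 10 kb, heavy
right tail into the Mb range, as in a mammalian annotation). PolyA-run
count is `Poisson(L × 2×10⁻⁴)`, i.e. one qualifying run per ~5 kb on
average; because the Poisson mean is proportional to length, length and
polyA count are strongly correlated (Pearson r ≈ 0.97 at 10,000 genes —
analytically `c·σ_L / √(c·μ_L + c²·σ_L²)` for rate `c`, which the
heavy-tailed length distribution pushes toward 1). Baseline expression
weight is `LogNormal(0, 1)`, *independent of length*, so that any
downstream length bias is attributable to the planted capture tilt rather
than confounded baseline expression. Exactly 13 genes are flagged
mitochondrial (the human mitochondrial protein-coding complement); 50
stress, 300 lncRNA and 50 fusion-target genes are drawn pairwise disjoint
from the mito set.

**Counts.** Per cell, depth is `round(LogNormal(ln 5000, 0.35))` and the
count vector is a single multinomial draw of that depth over normalized
per-gene weights. The multinomial (rather than independent per-gene
Poissons) makes counts sum exactly to depth and models capture
*competition*: tilting capture toward polyA-rich genes necessarily
depresses everything else, which is the actual mechanism of the snRNA-seq
length bias and is why planted folds are compressed in realized counts
(the 6× warm stress fold lands near 6.8× against nuclei but ~5× against an
untilted baseline, and the test band [4, 8] reflects that compression).

**Planted effects** (weight multipliers before normalization):

| parameter | default | role |
|---|---|---|
| `warm_stress_fold` | 6 | stress genes in warm cells |
| `cold_stress_fold` | 2 | stress genes in cold cells |
| `nuclei_polya_capture_coef` | 0.05 | nuclei weight `×(1 + 0.05·polyA)` |
| `nuclei_lncrna_fold` | 3 | lncRNA in nuclei |
| mito weight in nuclei | 0 | purified nuclei carry no mito transcripts |

The nuclear capture tilt is a linear function of *polyA count*, not length:
internal priming acts on polyA stretches, and length enters only through
its correlation with polyA. The lncRNA fold (3) and the depth spread (0.35
log-sd) are free parameters chosen once as realistic magnitudes: reported
nuclear lncRNA enrichment is qualitative but clearly visible per cell, and
a ~±70% two-sigma depth range matches typical 10x libraries. Cells are
split evenly into two samples per protocol so per-sample QC has groups to
work with; the subtype label defaults to a single value.

**Region fractions.** Per-sample exonic/intronic/intergenic fractions are
Dirichlet draws centered on protocol means (nuclei 14/52/34%, warm
42/24/34%, cold 42/26/32%) with concentration 45, giving the few-percent
between-sample scatter seen in paired designs. `concentration=inf`
degenerates to the means.

**Toy genome.** The writer realizes a (≤ 200-gene) universe as FASTA + GTF:
each gene's sense-strand sequence contains exactly `polya_count` maximal
A-runs of length 16–25, separated by ≥ 2 non-A bases, with non-A boundary
bases and background A-runs capped at 11 so maximal-run counting is
unambiguous; minus-strand genes are reverse-complemented into the written
plus strand. Annotation of these files recovers length and polyA count
exactly, which the tests and the demo verify.

**What the generator does not model:** ambient RNA, doublets, batch
chemistry, UMI collision, read-level artifacts, cell-type heterogeneity
within a sample, or gene–gene correlation beyond the multinomial
constraint. Passing tests therefore demonstrate that the *methods* recover
planted effects of realistic size under clean conditions, not that real
data are free of the confounders above.

## Annotation

A polyA region is a maximal run of consecutive A (case-insensitive)
*strictly longer* than `min_run = 15`, i.e. ≥ 16 A; N breaks a run. Runs
are counted on the transcribed strand of the gene-body span
(`end − start + 1`), the intron-inclusive reading of "full-length cDNA";
exon-sum length is deliberately not used, and only the sense strand is
counted (the polyT primer hybridizes the transcript). Length quartile
edges are the empirical 25/50/75 percentiles (linear interpolation) with
right-closed bins, so the top bin is open above its edge. The length-bias
signature takes the top `n_top = 200` genes by polyA count, ties broken by
length (longer first) then gene id — a total order, so the signature is
byte-reproducible.

## QC and normalization

Metrics are per-cell UMI total, detected genes, and %mito (0 for empty
cells). Outlier bounds are median ± `n_mads` × scaled MAD
(consistency constant 1.4826), computed per sample, on log1p(UMI) and
log1p(genes) two-sided and raw %mito upper-sided; the log scale stabilizes
the heavy right tail, and low mito content is never harmful. A zero MAD
(over half the sample tied at the median) keeps only the median value.
Adaptive bounds are backed by hard floors (defaults 200 genes, 500 UMIs),
configurable because "generic cut-offs" vary by study. Note that a 2-MAD
two-sided bound on a roughly normal metric clips ~5% of ordinary cells by
itself — the demo's ~92% pass rate is expected behavior, not data loss.
Normalization is `ln(1 + count × 10⁴ / depth)`; zero-depth cells stay zero
with a warning.

## Module scoring

Genes are ranked by mean normalized expression across cells (ties broken by
gene id for reproducibility) and cut into `n_bins = 24` equal-frequency
bins; each signature gene contributes `n_ctrl = 100` control genes sampled
without replacement from its bin (the whole bin when smaller, which at
moderate universe sizes makes the control mean the exact bin mean). The
score subtracts the mean over the *multiset union* of control draws, and
control pools may include other signature genes sharing a bin (an
`exclude_signature_from_controls` flag disables this). Scores are computed
on normalized, never z-scaled, data. Under the null the score is an
average of per-gene (gene − bin mean) terms, so its standard error is
dominated by gene sampling, not cell noise — the calibration tests use
that spread.

## Differential expression and length-bias analyses

Per gene, a two-sided Mann–Whitney test on normalized values: exhaustive
enumeration of all `C(n_a+n_b, n_a)` assignments when both groups are ≤ 8
cells (midranks handle ties), otherwise the tie-corrected normal
approximation *without* continuity correction — on heavily tied count data
the uncorrected tie-corrected z calibrates well (null false-positive rate
≈ 0.047 in the acceptance suite) where the continuity-corrected version is
conservative. Fold change is `log2((mean(expm1 A)+1)/(mean(expm1 B)+1))`
with a configurable pseudocount; enrichment requires
`|log2FC| ≥ log2(1.5)` and adjusted p < 0.05 (Bonferroni by default, BH
optional). Genes silent in both groups get p = 1, log2FC = 0 and a flag.

Overrepresentation replaces a web-service enrichment call with a one-sided
Fisher exact test (hypergeometric upper tail) per gene set, BH-adjusted
across the collection, with a Haldane 0.5 correction on the odds ratio
when a table cell is zero.

Quartile enrichment fractions are reported under two denominators: the
default `|enriched(P) ∩ bin| / |bin ∩ union of enriched genes|` makes
protocols comparable within a bin (summing to 1 for disjoint sets); the
whole-bin denominator `|bin|` is reported alongside because "% of total
genes" is ambiguous. Region-fraction contrasts use Welch t-tests (small
per-protocol n, unequal variance) Bonferroni-corrected over all
pair × region comparisons.

## Classification

Splits are stratified by label and seeded; scores are recomputed
independently within each split — bin construction and control draws see
only that split's cells, the leakage-safe reading of computing scores
"separately" on train and test. The classifier is an unpenalized logistic
regression of the label on the single score, fit by Newton/IRLS (cap 100
iterations, tolerance 1e-8). Complete separation — expected when a bias
score cleanly splits nuclei from cells — has no finite MLE; the fit stops
at the cap flagged unconverged, which is harmless downstream because
predicted probabilities remain monotone in the score and ROC/AUC only uses
ranks (a ridge option exists for users who want finite coefficients). AUC
is `U/(n₊·n₋)` from midranks (half credit for ties), with the curve
thresholded at every distinct value. The random-signature baseline redraws
the gene set, the split and the control stream each repetition.

## Numerical and reproducibility choices

All randomness flows from one integer seed through named substreams
(CRC-keyed `SeedSequence`), so stages can be re-run in isolation and are
independent of execution order; score columns re-seed identically per
signature, making them order-invariant. Percentile definition is fixed to
linear interpolation. Degenerate inputs fail loudly: < 4 genes or
collapsed edges for quartiles, empty signatures after intersection,
single-sample protocols, samples emptied by QC, overlapping DE groups.

## Problem sizes

The default study-scale analyses use 5,000 genes and 300 cells per
protocol (the classifier and DE twins), 10,000 genes for the
length–polyA correlation, and 2,000 genes × 900 cells for null
calibration; the demo uses 2,000 genes × 450 cells with short genes so the
toy-genome round trip stays small. These sizes give stable statistics
(AUCs and recovery rates are flat across seeds) while keeping any single
run in the seconds-to-a-minute range.

## Known limitations

* Gene length is the genomic span of the GTF `gene` feature; isoform
  structure, UTRs and exon-sum lengths are out of scope.
* The Wilcoxon asymptotic path is a normal approximation; for group sizes
  between 9 and ~20 with extreme ties it is approximate (the exact path
  covers ≤ 8).
* The warm-dissociation and lncRNA gene lists are inputs in real analyses;
  the synthetic twin uses its planted sets, so signature quality on real
  data depends on the supplied lists.
* The classifier is deliberately univariate (one score), matching the
  study design it reproduces; it is not a general protocol classifier.
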