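# snbias

Dissociation-protocol bias analysis for paired single-cell / single-nucleus
RNA-seq.

When the same tumor is profiled after warm enzymatic dissociation, cold
protease dissociation, and nucleus isolation from frozen tissue, the three
libraries differ systematically even though the underlying cells are the
same:

* **dissociation stress** — warm (and, weakly, cold) dissociation induces
  immediate-early stress-response genes (FOS/JUN-class);
* **gene-length bias** — snRNA-seq captures nascent, intron-containing
  transcripts whose internal polyA stretches hybridize the polyT RT primer,
  tilting capture toward long, polyA-rich genes;
* **compartment effects** — nuclei carry no mitochondrial transcripts and
  are enriched for nuclear-retained lncRNA and intronic reads.

`snbias` quantifies these biases and turns them into per-cell scores that
identify each cell's protocol of origin:

1. **Annotation** — for every gene, the intron-inclusive gene-body length
   `L = end − start + 1` and the number of *polyA regions*: maximal runs of
   more than 15 consecutive A on the transcribed strand. The **length-bias
   signature** is the top 200 genes by polyA-run count.
2. **QC and normalization** — per-sample outlier removal at
   median ± 2·MAD (scaled MAD, log1p metrics, upper-sided for %mito) with
   hard floors, then `x = ln(1 + c·10⁴/depth)`.
3. **Module scoring** — for a gene set *S*, the per-cell score is
   `mean_{g∈S} x_g − mean_{g∈ctrl} x_g`, with controls drawn from
   24 equal-frequency bins of mean expression (100 controls per signature
   gene), so the score is centered at zero under the null.
4. **Differential expression** — per-gene two-sided Wilcoxon rank-sum
   between protocols (exact enumeration for groups ≤ 8), fold-change filter
   `|log2FC| ≥ log2(1.5)` on de-logged means, Bonferroni or BH adjustment;
   length-quartile enrichment fractions and read-region summaries.
5. **Classification** — stratified 50/50 train/test split, module scores
   recomputed *within* each split (no leakage), one-feature logistic
   regression, ROC/AUC with Mann–Whitney tie handling, and a size-matched
   random-signature baseline.

A first-class synthetic-data generator plants all of these biases as ground
truth (multinomial counts conditioned on log-normal depth; nuclear capture
weight `1 + 0.05 · polyA_count`; 6×/2× stress folds in warm/cold; zero
mitochondrial weight in nuclei), so the whole pipeline is testable without
any external data, and can also write a toy genome (FASTA + GTF) whose
annotation round-trips exactly.

## Worked example

The quickest tour is the built-in demo (synthesizes data, runs every stage,
writes `report.json` and all intermediates):

```sh
snbias demo --seed 0 --out demo_out
```

The numbered scripts under `analysis/` run the same stages at the study
scale (5,000 genes, 300 cells per protocol, seed 7) and narrate what they
find. For example:

```text
$ python analysis/04_score_signatures.py
mean module score by protocol:
          warm_dissociation  lncRNA  length_bias
cold                 -0.138  -0.226       -0.148
nuclei               -0.636   0.415        0.318
warm                  0.724  -0.237       -0.147
```

The warm-dissociation score ranks warm > cold > nuclei and the length-bias
score singles out nuclei — the planted orderings (all pairwise rank-sum
contrasts Bonferroni p < 1e-90 except cold-vs-warm for the nuclei-specific
scores, as expected).

```text
$ python analysis/07_classify_protocols.py
length_bias -> nuclei: test AUC = 1.000 (random 200-gene baseline: 0.579 +/- 0.096, n=20)
warm_dissociation -> whole cells: test AUC = 1.000 (random 50-gene baseline: 0.584 +/- 0.096, n=20)
```

A single module score cleanly separates nuclei from whole cells on the test
split, while size-matched random signatures hover near chance.

`analysis/06_length_bias.py` shows the mechanism: nuclei-enriched genes are
much longer (median 21,463 nt vs 9,243 nt for warm-enriched, rank-sum
p = 7e-6) and nuclei claim 93% of the enriched genes in the longest length
quartile but only 75% in the shortest.

Library usage mirrors the scripts:

```python
import snbias as sb

cfg = sb.SimulationConfig(seed=7, n_genes=5000, n_cells_per_protocol=300)
universe = sb.simulate_gene_universe(cfg)
adata = sb.simulate_experiment(universe, cfg)
norm = sb.lognormalize(adata)
sig = sb.build_length_bias_signature(universe)
scores = sb.module_score(norm, sig, sb.ScoringParams(seed=7))
```

## Layout

```
src/snbias/        library: simulate, annotation, qc, scoring, diffexp,
                   classify, pipeline, cli, io
analysis/          numbered narrative drivers writing tables to results/
tests/             pytest suite (unit, property, and acceptance checks)
scripts/           acceptance.py
docs/methods.md    model, parameter, and design documentation
```
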