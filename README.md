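# epromoter

Identification of **Epromoters** — gene promoters that also act as distal
enhancers — and of Epromoter-regulated gene clusters from capture
STARR-seq-style promoter activity, differential expression, transcription
factor binding, and TAD annotation.

The package targets regulatory genomicists studying inducible
transcriptional programs (the canonical use case is the type I interferon
response, where clusters of interferon-stimulated genes are coordinated by
a single TF-recruiting hub promoter). It re-implements the analysis chain
as a tested, reusable library with a CLI, plus a synthetic-data generator
with planted ground truth so every step is exercisable offline.

## The method

1. **Enhancer activity.** Reads from reporter (STARR) and input libraries
   are extended to the mean captured-fragment size (314 nt), coverage of
   each captured promoter window (−200/+50 around the TSS) is counted and
   FPKM-normalised, and activity is the fold-change
   FC = FPKM_STARR / FPKM_input per condition and replicate. Promoters with
   input FPKM < 1 are removed.
2. **Epromoter calls.** Promoters are ranked by mean FC; the activity
   threshold τ is the inflection point (knee) of the ranked log₂ FC curve —
   the point of maximum perpendicular distance to the chord joining the
   curve's endpoints. A promoter is an Epromoter in a condition when its
   mean FC ≥ τ. An **induced** Epromoter is an Epromoter whose induction
   ratio (stimulated over non-stimulated mean FC) is strictly > 2, with at
   least one stimulated replicate active; **repressed** mirrors the rule.
3. **Response sets.** Genes with log₂FC > 1 and adjusted p < 0.001 are
   induced; combining with Epromoter calls yields the sets
   *induced gene only*, *induced gene & Epromoter*, and
   *induced Epromoter only* (genes may carry several labels through
   alternative promoters).
4. **TF binding.** Composite ISGF3 peaks (bases covered by STAT1, STAT2 and
   IRF9 peaks simultaneously) are assigned to each induced gene's nearest
   position and categorised as same promoter (≤1 kb of the own TSS),
   another promoter (≤1 kb of any other TSS), or intergenic. Non-redundant
   ISRE motif sites (IRF1–9, STAT1/2, merged at ≥1 bp overlap) are counted
   per promoter in two tiers (all sites; high-confidence p < 1e-4).
5. **Clusters.** TSSs of induced genes and induced Epromoters are linked by
   single linkage at ≤100 kb; clusters are typed by member labels, placed
   in TAD context (same merged TAD / different / outside), and predicted
   **Epromoter-like** when exactly one member promoter binds ≥1 key TF
   while all other members bind none.
6. **Statistics.** KS comparison of nearest-neighbour TSS distances against
   a random gene control; Pearson chi-square for 2×2 contingencies; and a
   shuffle-based overlap enrichment test whose null is a negative binomial
   fitted by moments to 100 within-chromosome shuffles.

## Worked example

Generate a synthetic dataset with planted ground truth and run the whole
chain in memory:

```python
from epromoter import SimConfig, simulate_all, run_pipeline, evaluate_recovery

ds = simulate_all(SimConfig(seed=0))
res = run_pipeline(
    ds.counts, ds.promoters[["promoter_id", "gene_id", "chrom", "tss", "strand"]],
    ds.tss_table, ds.de_table, ds.tf_peaks, ds.isre_sites, ds.tads,
    ds.chrom_sizes, seed=0,
)
print(res.summary["tau"], res.summary["n_induced_epromoters"])
print(evaluate_recovery(res, ds))
```

prints (seed 0):

```
tau: {'ns': 2.285, 'stim': 2.085}
promoters: 2500 removed: 21
induced Epromoters: 80 repressed: 38 constitutive: 169
clusters: 44 with Epromoter: 33 Epromoter-like: 20
proximity KS D=0.622 p=2.47e-36
{'induced_epromoter_precision': 0.9125, 'induced_epromoter_recall': 0.9125,
 'cluster_jaccard': 0.994, 'epromoter_like_accuracy': 1.0}
```

Reading the numbers: the knee threshold τ lands just above the background
fold-change bulk in each condition; 80 promoters are called induced
Epromoters (the generator planted 80, recovered at precision = recall
0.91); the 44 called clusters match the planted cluster memberships at
Jaccard 0.99; and every cluster with a single TF-bound hub is predicted
Epromoter-like. Induced genes sit far closer to each other than a
size-matched random gene control (KS D = 0.62).

The same run is available from the shell:

```bash
epromoter simulate --seed 0 --out fixtures/
epromoter run --counts fixtures/starr_counts.tsv --promoters fixtures/promoters.tsv \
    --tss fixtures/tss.tsv --de fixtures/de_table.tsv --tads fixtures/tads.bed \
    --genome fixtures/chrom.sizes --out results/ --seed 0
```

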