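# chronotrace

Analysis of **time-stamped multiplexed scRNA-seq** experiments, in which every
sample of a developmental time series is marked by a unique pair of barcoded
reporter transgenes before all samples are pooled into a single single-cell
library.  The package is written for developmental biologists profiling
embryonic lineages (the motivating system is the *Ciona* cardiopharyngeal
lineage, sampled hourly from 5 to 14 hours post-fertilization), and covers the
computational chain from raw UMI count matrices to maturation statistics:

1. **Barcode demultiplexing** (`chronotrace.demux`) — assign each cell to its
   sample of origin from sample-barcode (SBC) UMI counts.  A cell is assigned
   to sample *s* when both barcodes of *s*'s designed pair are detected
   (≥ `min_umi` UMIs each), the pair's UMI sum exceeds the best competing pair
   by a margin (default 2×), and the pair's *purity* — pair UMIs over total
   barcode UMIs — clears a floor (default 0.6).  Correlation QC checks that
   cotransfected pairs correlate near-perfectly across cells (Pearson > 0.98
   on log1p counts) while independently electroporated barcodes do not
   (< 0.05).
2. **Developmental-time propagation** (`chronotrace.timeprop`) — impute a time
   for cells lacking a barcode timestamp: each such cell receives the
   *median* timestamp of its *k* = 20 nearest timestamped neighbors in PCA
   space (35 components), accepted only when the neighbors' population
   standard deviation is below 1 h.  Leave-one-out validation re-predicts
   every timestamped cell from its neighbors to estimate transfer accuracy.
3. **Trajectory maturation** (`chronotrace.trajectory`) — graph smoothing
   (one-pass neighbor averaging, *k* = 18), diffusion pseudotime rooted at a
   minimum-time cell, Ward segmentation into regulatory states, Leiden
   clustering of the *transposed* gene matrix into temporal gene programs,
   maturity labels (immature / intermediate / **mature** = programs switching
   on shortly before the lineage bifurcation / terminal = branch-restricted),
   Wilcoxon marker calling (avg log2FC ≥ 0.25, BH-adjusted p < 0.1), and a
   velocity-speed proxy (norm of per-gene expression slopes along
   pseudotime).
4. **Categorical statistics** (`chronotrace.stats`) — Fisher's exact test
   (two-sided p = Σ of point probabilities ≤ the observed one), upper-tail
   hypergeometric enrichment, Haldane–Anscombe log-odds, Bonferroni/BH
   corrections, binomial standard errors of proportion
   SE = √(p̂(1−p̂)/n), and the ordered log-odds "causality chain" over
   per-embryo categorical observations.
5. **Division geometry** (`chronotrace.geometry`) — the min-triplet-cosine
   orientation statistic (minimum |cos θ| over all pairs of axes within cell
   triplets; rigid-motion and scale invariant), sister-volume asymmetry
   ratios, and mediolateral/anteroposterior/oblique classification.
6. **Motif-set enrichment** (`chronotrace.motifs`) — strand-aware assignment
   of motif sites to genes (gene body; promoter −1107/+107 bp around the
   TSS; distal ≤ 10 kb upstream of the TSS or downstream of the TTS, with
   precedence gene body > promoter > distal), differential-accessibility
   motif sets from log2FC rules gated at FDR < 0.1, and hypergeometric
   enrichment against selectable backgrounds.
7. **Synthetic data** (`chronotrace.simulate`) — a generator that emulates the
   experiment end to end (branching trajectory, Gaussian temporal gene
   programs, negative-binomial counts, Poisson barcodes with a shared
   per-cell reporter factor, mosaicism, screen/geometry/motif fixtures) with
   full ground truth, so every stage is testable without external data.

## Worked example

Run the full synthetic pipeline (simulate → demux → propagate → trajectory):

```python
from chronotrace.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1))
stages = report["stages"]
print(stages["demux"]["summary"]["percent_assigned"])        # 80.9
print(stages["propagate"]["loo"])
# {'n_timestamped': 809, 'n_predicted': 809,
#  'frac_exact': 0.7478, 'frac_within_tol': 0.9975, 'frac_unassigned': 0.0}
print(stages["trajectory"]["pseudotime_time_spearman"])      # 0.982
print(stages["trajectory"]["maturity_labels"])
# {0: 'immature', 1: 'intermediate', 2: 'intermediate', 3: 'mature',
#  4: 'terminal', 5: 'terminal', 6: 'terminal', 7: 'terminal'}
```

Reading the numbers: 80.9% of the 1000 simulated cells carry a recoverable
barcode pair (the rest are mosaic or under-captured, as configured);
leave-one-out transfer recovers the exact hour for 74.8% of timestamped
cells and lands within 1 h for 99.8% — the exact-hour rate is limited by the
simulated embryo asynchrony (sd 0.5 h), not by the transfer rule; diffusion
pseudotime orders cells in near-perfect agreement with true time
(Spearman ρ = 0.98); and the eight recovered gene programs are labeled with
the mature program (cluster 3, peaking just before the 10 hpf bifurcation)
separated from founder (immature) and branch-restricted (terminal) programs.

The same stages are exposed as a CLI:

```bash
chronotrace simulate --outdir run/ --seed 1
chronotrace demux --counts run/barcodes --design run/design.tsv --out run/assign.tsv
chronotrace run --seed 1 --outdir run/
chronotrace reporter-stats --table reporters.tsv --out stats.tsv
```

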