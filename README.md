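# dsbpred

Predicting DNA double-strand break (DSB) sites at kilobase scale from
epigenomic occupancy, DNA sequence motifs and DNA shape.

## The problem

Endogenous DSBs are the most dangerous DNA lesions; assays that map them
genome-wide (DSBCapture, BLESS, BLISS, END-seq) are expensive and exist for
only a handful of cell types, while ChIP-seq and DNase-seq peak tracks are
abundant. `dsbpred` implements the machine-learning framework that exploits
this asymmetry: learn a classifier that discriminates DSB sites from
carefully matched non-DSB sites using cheap covariates, then score any
genome in fixed-width bins.

The package is for computational biologists who have peak-level data (BED
intervals, a soft-masked FASTA, JASPAR matrices, a pentamer shape table) and
want a transparent, fully testable re-implementation of each stage:

1. **Sites.** DSB peak calls from two replicates are intersected; control
   sites are drawn at random from the genome matched *per site* to the
   positives on length, GC fraction and repeat (soft-masked) fraction, so
   the classifier cannot win on trivial composition differences.
2. **Features.** Each site is encoded by (a) the occupancy fraction
   x ∈ [0, 1] of every mark's peaks over the site (x = 0.6 when a peak
   covers 60 % of the site), (b) the number of motif hits per JASPAR PWM at
   a relative log-odds score ≥ 0.8 on either strand, and (c) 48 DNA-shape
   statistics — for each of MGW, ProT, Roll and HelT predicted by pentamer
   lookup, the 11 quantiles at 0, 10, …, 100 % plus the variance.
3. **Models.** A random forest (500 trees, mtry = ⌊√p⌋, scores = vote
   fractions, variable importance = mean decrease in out-of-bag accuracy
   under per-feature permutation) and L1-penalized logistic regression with
   cross-validated penalty (coefficients β interpretable as odds ratios
   via OR = e^β); an unpenalized logistic fit supplies Wald p-values.
4. **Evaluation.** ROC and precision–recall curves, AUROC (trapezoid) and
   AUPR (step-wise integral), with a 2 000-replicate bootstrap CI on the
   AUROC; association of individual features is summarised by 2×2
   colocalization tables, Fisher exact tests, and Bonferroni/BH correction.
5. **Genome scan.** The whole genome is tiled into 250-base bins, each bin
   is featurized with exactly the training encoders and scored;
   high/low-score bins become predicted DSBs/controls, and independent
   signals can be profiled across score quantiles.

A first-class synthetic-data module generates toy genomes with planted DSB
sites, conditionally associated mark tracks, planted motifs and a
deterministic stand-in shape table, so every stage is testable end-to-end
without downloads.

## Worked example

Simulate a 2-Mb genome with 1 000 DSB sites and three marks planted at
realistic conditional presence probabilities — DNase-like 0.91 at DSBs vs
0.11 at controls, H3K4me2-like 0.74/0.11, CTCF-like 0.25/0.02 — then train
and evaluate a forest:

```python
from dsbpred import (SimulationConfig, simulate_dataset, occupancy_features,
                     RandomForestDSB)

cfg = SimulationConfig(seed=7, n_chroms=2, chrom_length=1_000_000, n_dsb=1000)
genome, truth = simulate_dataset(cfg)

pos = occupancy_features(truth.dsb_sites, truth.mark_peaks)
neg = occupancy_features(truth.control_sites, truth.mark_peaks)

model = RandomForestDSB.from_features(pos, neg, test_fraction=0.3, seed=7)
results = model.fit(n_trees=500, seed=7)
print(results.summary())
print(results.evaluate(model.data, n_boot=2000, seed=7).summary())
```

which prints:

```
ForestResults [forest] p=3 seed=7
n_trees=500 mtry=1
         importance
DNase        0.2771
H3K4me2      0.0481
CTCF         0.0328
AUROC = 0.942 (95% CI [0.922, 0.960], 2000 bootstrap replicates); AUPR = 0.928
```

Reading the numbers: the held-out AUROC of 0.942 says the forest separates
DSB from matched non-DSB sites almost perfectly given only three occupancy
tracks; the DNase-like mark — planted with the largest presence gap
(0.91 vs 0.11) — dominates the permutation importance, exactly as
accessibility dominates in real data, with the weaker H3K4me2-like and
CTCF-like marks following in order of their planted gaps.

The same objects drive the rest of the toolkit: `score_genome(results,
genome, tracks=...)` scores 250-base bins genome-wide,
`transfer_predict(results, features_b)` applies a fitted model to another
dataset's features, and `enrichment_report` produces the per-mark
colocalization/odds-ratio table.

## Command line

A thin `dsb` CLI wraps the library for shell pipelines:

```bash
dsb simulate --seed 7 --outdir sim/
dsb sample-null --fasta sim/genome.fa --dsb sim/dsb_sites.bed --seed 1 -o neg.bed
dsb run -c config.yaml          # intersect -> sample-null -> featurize -> train -> eval
dsb scan-genome --model run/model.pkl --fasta sim/genome.fa \
    --track DNase=sim/track_DNase.bed ... --width 250 -o scores.bedgraph
```

Every `dsb run` writes a manifest (config, seeds, input checksums, version)
sufficient to reproduce all numeric outputs exactly.

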