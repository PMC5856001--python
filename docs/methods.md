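# Methods

This note documents the statistical procedures implemented in `dsbpred`,
the defaults and numerical conventions chosen where several were
defensible, and what the synthetic benchmark does and does not establish.

## Site definition and interval arithmetic

All coordinates are 0-based half-open (BED convention); any 1-based input
must be converted at the reader boundary, and strand is ignored throughout
(DSBs are unstranded). Interval sets are canonicalized on construction:
sorted by (chrom, start, end) with exact-coordinate duplicates collapsed,
keeping the first occurrence's name/score.

**Replicate intersection** keeps every rep1 peak with ≥ 1-base support in
rep2. By default the *full* rep1 peak is retained rather than the clipped
intersection: downstream size matching presumes whole peaks, and typical
peak-call medians (~391 b) are consistent with that. `clip=True` instead
emits the maximal covered segments (rep1 ∩ union(rep2)); which convention a
published peak set used is rarely stated, so both are supported and the
default documented.

**Occupancy fraction.** A site's feature value for a mark is the fraction
of its bases covered by the union of the mark's peaks. Peaks are merged
before counting (union semantics), making the value invariant to how a
covering region is split into abutting pieces — property-tested against a
per-base boolean-coverage oracle.

**Binning.** Genome tiling emits consecutive fixed-width bins per
chromosome; the trailing partial bin is truncated, never dropped, so bin
lengths sum exactly to the genome size. Callers may filter short bins.

## Matched null sampling

Controls are drawn per site: negative *k* is tied to positive *k* mod
n_pos, inherits its exact length, and is accepted only when its GC fraction
(computed case-insensitively over non-N bases) is within `gc_tolerance`
(default 0.02) and its soft-masked lowercase fraction within
`repeat_tolerance` (default 0.05) of that positive's values. Candidates are
uniform over the genome, rejected when they carry > 10 % ambiguous bases or
overlap the exclusion set (positives plus any blacklist) or a previously
accepted negative; rejection is bounded by `max_attempts_per_site`
(default 10 000) and the sampler aborts if > 5 % of requested sites cannot
be matched. Per-site matching is stricter than distribution-level matching
and implies it; the emitted names record the pairing so QC can recompute
every per-pair deviation. The default negative:positive ratio is 1 for
site-level models; genome-bin analyses use the observed class sizes
instead of sampling.

## Motif features

JASPAR position frequency matrices are parsed with Biopython. The PFM is
converted to probabilities with a pseudocount of 0.8 distributed by the
background frequencies (uniform 0.25 by default — the originating database
does not ship these choices, so they are declared, not inferred) and then
to a log2-odds weight matrix, guaranteed finite. A window is a hit when its
relative score

    rel = (score − min_score) / (max_score − min_score)

is at least the threshold (default 0.8, the conventional "80 % matching
score"); the consensus scores exactly 1 and the anti-consensus exactly 0.
Both strands are scanned (minus-strand scores computed with the
reverse-complement matrix on the forward sequence; coordinates are always
forward-strand), windows containing N are skipped, and overlapping hits all
count — occurrence counts are not de-overlapped. Scanning is verified
against exhaustive window enumeration.

## DNA shape features

Four structural features are assigned by pentamer lookup: MGW (Å) and ProT
(degrees) are base-pair features; Roll and HelT (degrees) are base-pair-
step features, flattened to one value per position by averaging the two
central steps of each pentamer so all four profiles have uniform length
L − 4. Lookup tables must cover all 1 024 pentamers directly or after
reverse-complement completion, and MGW/ProT must satisfy the strand
symmetry value(p) = value(revcomp(p)) to 1e-6.

Each site contributes 12 statistics per feature — quantiles at
0, 10, …, 100 % using linear interpolation between order statistics (the
classic "type 7" default) and the population (divide-by-n) variance — for
48 named predictors. Whether published analyses used sample or population
variance, or another quantile type, is typically unstated; the choices here
are fixed and documented, and the difference is far below the variance
across sites.

The shipped `make_shape_table` generator is **synthetic**: a deterministic
keyed hash of each canonical pentamer mapped into physically plausible
ranges (MGW 2.8–6.2 Å, ProT −16–0°, Roll −8–8°, HelT 30–38°) and
symmetrized exactly. It reproduces the format and invariants of a physical
table — not its chemistry — and exists so shape code paths are fully
testable offline.

## Enrichment statistics

Feature–class association is summarised by 2×2 tables (a = positives with
the feature, etc.): colocalization percentages 100·a/(a+b) and
100·c/(c+d), odds ratio (a·d)/(b·c), and a two-sided Fisher exact test
(the exact test is valid at any count; a chi-square alternative would only
matter for speed at very large n). Zero cells yield explicit 0/∞ odds-ratio
flags unless the Haldane correction (+0.5 per cell) is requested — reports
never silently shift counts. Multiplicity is handled by Bonferroni
(min(1, m·p)) or Benjamini–Hochberg step-up. Logistic coefficients map to
odds ratios as OR = e^β.

## Classifiers

All three families take a labeled feature matrix with a stratified
train/test split (default test fraction 0.3; no canonical split proportion
exists for this design, so it is a documented default).

**Random forest.** Bagged CART trees with Gini splitting, unbounded depth,
mtry = ⌊√p⌋ random features per split, 500 trees — the standard defaults of
the reference random-forest implementations. It is realised as bagging over
randomized trees, which is algorithmically identical to a random forest
while exposing the per-tree bootstrap samples needed for out-of-bag
importance. Scores are vote fractions (the fraction of trees predicting
class 1). Variable importance is the mean decrease in out-of-bag accuracy:
for each tree, accuracy on its out-of-bag rows minus accuracy after
permuting one feature among those rows, averaged over trees.

**Lasso logistic.** Features are standardized, a 30-point penalty path is
scored by cross-validated deviance (stratified folds, default 10), and the
selected model's coefficients are back-transformed to the original feature
scale (constant features are dropped with a warning). Exact zeros are
meaningful: a feature's coefficient survives only if it carries signal at
the selected penalty.

**Unpenalized logistic** (maximum likelihood via statsmodels) supplies Wald
p-values for significance statements. Perfect or quasi-separation is
detected (divergent fitted probabilities or non-finite standard errors) and
raised as an explicit error recommending the penalized model, since ML
coefficients are then unidentified.

## Evaluation

ROC curves are threshold sweeps starting at (0, 0) and ending at (1, 1);
AUROC is the trapezoid area, which equals the Mann–Whitney concordance
probability (ties counted ½) — asserted against a brute-force pairwise
oracle. Precision–recall curves use step-wise precision and AUPR is the
non-interpolated step integral (average-precision form); linear PR
interpolation is known to be optimistic. The AUROC confidence interval is
the 2.5/97.5 percentile over 2 000 plain bootstrap resamples of the test
rows (unstratified; resamples that lose a class are redrawn). AUROC is
insensitive to class imbalance while AUPR is deliberately sensitive to it —
the imbalance experiment below quantifies exactly this contrast.

Three-set overlap summaries (predictions vs two reference assays) classify
each set's intervals by ≥ 1-base overlap with the other two; derived
percentages round half-up to two decimals, matching the conventional
printed style.

## Genome-wide scanning and transfer

Every bin of the tiling (default width 250 b) is featurized with the
*identical* encoders used in training (a round-trip test asserts
bit-for-bit equality) and scored. Bins with score ≥ `high` are predicted
DSBs and ≤ `low` predicted controls; no canonical cutoffs exist for this
design, so the thresholds are mandatory configuration with defaults
(0.25, 0.75), and the middle band is excluded from validation profiles.
Transfer to another dataset requires every training feature to be present —
the feature intersection must be chosen explicitly before training; silent
imputation or zero-filling is refused.

## Synthetic data generator

The generator emulates the *structure* of the real inputs at toy scale:

* **Genome** — i.i.d. bases at a target GC (default 0.41, the human value)
  with lowercase repeat blocks (block sizes log-normal around 300 b)
  covering a target fraction (default 0.45); fully determined by the seed.
* **DSB sites** — non-overlapping, sizes log-normal with median 391 b
  (matching reported peak medians; only the median is reported, so the
  dispersion σ_log = 0.5 is a config default), truncated to [100, 2000] b.
* **Controls** — drawn by the real matched-null sampler, so the generator
  exercises the production path.
* **Marks** — per-site independent Bernoulli presence at P(peak|DSB) and
  P(peak|control); planted peaks are centered on the site with Gaussian
  jitter (sharp accessible/insulator-like marks get small jitter, broad
  histone-like marks larger), so average profiles show centered vs shoulder
  structure. Conditional frequencies are enforced at the sampled control
  sites, not genome-wide. Ground truth whose realized frequency drifts
  beyond 3 binomial sd of specification is redrawn (bounded retries) so the
  emitted truth always meets tolerance, deterministically under the seed.
  The default panel plants DNase-like 0.91/0.11, H3K4me2-like 0.74/0.11 and
  CTCF-like 0.25/0.02 — the observed colocalization contrast between DSB
  and non-DSB sites.
* **Motifs** — consensus copies are written into site sequences (random
  strand, non-overlapping windows per site) with class rates solving a
  target odds ratio against a baseline rate (default 0.05).

What passing the synthetic benchmark shows: the encoders, sampler, models
and metrics interlock correctly, planted effects of realistic magnitude are
recovered, importance ranking follows the planted effect sizes, and the
ROC/PR imbalance behaviour is as theory predicts. What it does not show:
performance on real chromatin, where marks are spatially correlated along
domains, peak calls carry assay-specific noise, GC/repeat structure is not
i.i.d., and causal structure is unknown. Headline accuracies from real
DSB maps (AUROC ≈ 0.97 at site level) are properties of those datasets and
are not desk-scale reproducible; the synthetic benchmark targets the
qualitative and arithmetic claims instead.

## Benchmark problem sizes

The planted-signal experiment uses a 2-Mb genome (2 × 1 Mb), 1 000 DSB plus
1 000 matched control sites (~44 % expected occupancy, near the feasibility
bound for non-overlapping placement) and a 500-tree forest; it is repeated
over 20 seeds for the importance-ranking stability check. The imbalance
experiment trains one forest on 500 sites per class from a 30-Mb
single-chromosome genome and evaluates the same 400 positive test sites
against 400 (1:1) and 24 000 (1:60) matched controls — the 1:60 ratio
mirrors the DSB-bin prevalence of a genome-wide 250-base tiling. These
sizes were fixed from occupancy arithmetic (placement feasibility) and the
binomial/concordance error budgets of the quantities being asserted.

## Known limitations

* Coverage inputs are interval sets (peaks) or per-base counts; bigWig
  signal and read-level simulation are out of scope.
* The sampler matches size/GC/repeat only — not k-mer spectra or chromatin
  covariates.
* Motif scanning uses a 0-order background; no p-value-calibrated
  thresholds or de-novo discovery.
* The forest does not calibrate probabilities; scores are vote fractions.
* Enrichment is unadjusted for covariates, and odds-ratio confidence
  intervals are not reported.
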