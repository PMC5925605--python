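# Methods

`methylforge` re-implements, as a tested pipeline, a genome-wide
methylation analysis of tumor versus adjacent-normal tissue on
450k-style arrays: probe/sample QC and normalization, per-probe
differential methylation against tumor cellularity with empirical-Bayes
variance moderation, bump-hunted differentially methylated regions
(DMRs) with resampling family-wise error control, copy-number inference
from total probe intensity, and a minimal CpG logistic classifier. All
stages are exercised on synthetic cohorts with known ground truth; this
note records the models, the defaults and why they were chosen, and what
the synthetic experiments do and do not demonstrate.

## The synthetic cohort generator

The generator emulates the statistical structure of a two-group
methylation-array experiment, not any particular dataset.

**Manifest.** Probes are laid out in island-like blocks: a configurable
fraction of adjacent probe pairs (default 0.7) are 20–400 bp apart, the
rest 600–10,000 bp, giving geometric block sizes (mean ≈ 3.3 probes) and
a natural substrate for maxgap-500 clustering. Island annotation is
drawn per probe (default 80% in/near islands), SNP flags at 2%,
enhancer flags at 32%.

**Baseline methylation.** Per-probe baseline beta is bimodal — scaled
Beta(2,18) around 0.10 and Beta(17,3) around 0.85 (45% high mode) — the
classic two-hump genome-wide beta density. Baselines, probe brightness
and the identity of spiked loci are drawn from a separate *population*
random stream (`baseline_seed`), so independent cohorts can be generated
from the same population for external validation.

**Tumor signal and cellularity.** A spiked probe with effect Δ observed
in a specimen of tumor-cell fraction c has expected beta
`c·clip(β₀+Δ, 0, 1) + (1−c)·β₀` — a two-population mixture in which
contaminating normal cells dilute the tumor shift linearly.
Hypermethylation events start from the unmethylated mode (β₀ ≤ 0.5),
matching the biology of CpG-island gains; 99% of spiked effects are
positive. Tumor cellularity is Uniform(0.8, 0.9) by default, emulating
macrodissected, tumor-rich specimens. The lower bound comes from a power
analysis of the calling rule: with the default logit noise, the
per-probe group-mean difference of a Δ = 0.3 spike in a 16/31 cohort has
sd ≈ 0.022 and a systematic attenuation ≈ 0.018 (see below), so the
expected diluted effect c̄·Δ − 0.018 must exceed the 0.20 delta-beta
gate by ≥ 1.65 sd for ≥ 95% per-probe detection power — which requires
mean cellularity ≈ 0.85. Together with the ≈ 99.5% probe retention of
the detection filter at the default failure rate, expected recall of
canonical spikes is ≈ 0.95. Cohorts with lower purity are one parameter
away; the recovery guarantees quoted here do not apply to them.

**Noise.** Beta noise is additive Gaussian on the logit scale (sd 0.3)
and back-transformed, which keeps values inside (0,1) without clipping.
Because the logistic transform is nonlinear, this noise is *biased* on
the beta scale: group-mean differences are attenuated by ≈ 0.01–0.015
at the default sd. The law-of-large-numbers check of the mixture is
therefore run with noise disabled, and the attenuation is treated as a
property of the noise model, not an estimator error.

**Intensity.** Total intensity is log-normal: a per-probe brightness
factor (natural-log sd 1.0, shared by all samples) times per-measurement
noise (natural-log sd 0.15) times the median scale (2000). The large
probe-level spread matters: rank-based (quantile) normalization
preserves copy-number dosage only because a doubled probe remains in the
neighborhood of its own rank when probe brightness dominates the
distribution — with i.i.d. probe intensities, quantile normalization
would flatten CNV signal entirely. Copy-number events multiply intensity
by CN/2 and are treated as clonal (purity 1 by default, separately
configurable from methylation cellularity). No intensity distributions
were available to fit, so the log-normal form is an assumption,
documented rather than claimed faithful.

**Detection failures** are independent probe-by-sample events (rate
1·10⁻⁴, the sub-0.1% per-measurement failure rate of a well-run array;
under the any-sample filter this removes ≈ 0.5% of probes in a
47-sample cohort), so the strictest filter rule has work to do. Technical
replicates redraw only the noise terms of an existing tumor sample.

**Spiked truth.** Isolated DMPs (default 500 at Δ = 0.3) avoid
SNP-flagged probes; DMR events occupy whole probe blocks of 10–14
probes, which makes region boundaries well-defined for recovery scoring;
CNV segments are runs of consecutive probes (default 30) assigned to
several tumor carriers each, optionally overlapping a set number of
DMPs to exercise the classifier's exclusion stage.

## Preprocessing

Beta is `M/(M+U+offset)` with offset 100 (a conventional stabilizer;
configurable); M-values are `log2(β/(1−β))` after clipping to
[1e-6, 1−1e-6]. Probe filtering drops SNP-flagged probes and any probe
whose detection p-value exceeds 0.01 in at least one sample (the
strictest reading; a `fraction:x` policy is available). Quantile
normalization maps every column onto the row-rank means of the sorted
columns, ties sharing their rank-range mean. Sample QC flags specimens
whose genome-wide beta density is not bimodal (more than 35% of betas in
[0.3, 0.7] — a stand-in for the visual inspection this check usually is)
and classical-MDS outliers (2-D Torgerson scaling of 1−Pearson
distances, flag at > 5 MADs from the centroid).

## Differential methylation

Each probe's M-values are regressed by OLS on a single continuous
covariate: tumor cellularity, with normals at 0. No separate group
indicator is fitted — the association with tumor involvement *is* the
test. Residual variances are shrunk toward a scaled inverse-chi-square
prior fitted by moment matching on log variances: with
e = log s² − ψ(df/2) + log(df/2), the prior degrees of freedom d₀ solve
ψ′(d₀/2) = var(e) − ψ′(df/2) (Newton inversion of the trigamma), and
s₀² follows from the matched mean; when the observed spread of log s² is
no larger than the chi-square contribution, d₀ = ∞ and the prior is a
point mass. The moderated statistic uses the posterior variance
(d₀s₀² + df·s²)/(d₀+df) on d₀+df degrees of freedom (large-df t when
d₀ = ∞). Zero variances are floored at the 1st percentile of positive
values before log-moment estimation.

Calls are Bonferroni over the tested (post-QC) probe set at α = 0.01,
gated on |Δβ| > 0.20 where Δβ is the tumor-minus-normal group mean of
beta — the effect size is reported on the interpretable beta scale even
though testing happens on M-values. The table is ordered by adjusted p,
then |Δβ|, then probe id, so output is deterministic under ties.

## DMR detection

Probes are chained into clusters with inter-probe gaps ≤ 500 bp. The
per-probe Δβ vector is smoothed within clusters by a truncated running
mean (window 3; window 1 disables smoothing); candidate regions are
maximal same-sign runs of |smoothed Δβ| > 0.20 with ≥ 3 probes. The
family-wise error rate of each candidate is estimated by resampling:
B label permutations (the default null; a label-bootstrap variant is
available) each yield the maximum qualifying region statistic, and
FWER = (1 + #{null max ≥ observed})/(B + 1) — the add-one form keeps
estimates off zero, with floor 1/(B+1). Permutation of two-group labels
is exact under exchangeability, which is why it is the default over
residual bootstrapping. Desk-scale runs use B = 200 (floor 0.005 <
the 0.01 threshold); B = 1000 reproduces the full-scale setting.

## Copy-number inference

Total intensity (M+U) is quantile-normalized, divided by the per-probe
median over normal samples, and log10-transformed, so 0 is diploid and a
clonal one-copy loss sits at log10(1/2) = −0.301. Isolated spikes are
shrunk toward the median of their ±2-probe neighborhood when they exceed
k = 3 sample-sds.

Segmentation is recursive: each interval is scanned for the *arc* (two
change points) maximizing the pooled two-sample t between inside and
outside means, the arc statistic is tested by permutation of the
interval's values (re-maximizing with the identical scan), and accepted
arcs split the interval for recursion. The two-change-point scan is the
default because a single binary split has essentially no power for a
short interior segment on a chromosome-length track: the boundary split
t of a 30-probe event in ~2,500 probes is smaller than the null maximum
over all splits, so a binary-only scheme never finds it. Binary-split
mode remains available (`circular=False`). Arc lengths are scanned
exhaustively for intervals up to 256 probes and on a geometric ladder
(ratio 1.25) above; the identical ladder is applied to observed and
permuted data, so the permutation test is valid for the ladder-max
statistic, and accepted boundaries are then refined by a local exact
scan (radius 8). The permutation loop stops early once the p-value is
guaranteed to exceed α, which leaves null tracks cheap; desk-scale runs
use 200 permutations (full scale: 10,000).

Segments require ≥ 5 markers and mean log ratio > 0.2 (gain) or < −0.3
(loss). Two operating notes discovered during validation: (i)
log10(3/2) = 0.176, so a clonal single-copy gain does *not* pass the
0.2 gain cut — that threshold admits two-copy (and higher) gains; (ii) a
clonal one-copy loss lands exactly on the −0.3 cut, and rank
normalization attenuates extreme-brightness probes by ~0.005–0.01, so
CN = 1 calls flip by chance at this threshold. Segment *recovery* is
therefore assessed on the segmentation output (boundary offsets and
marker-weighted means), and the default end-to-end scenario spikes
two-copy gains. Tumor segments mirrored by a same-direction
normal-sample segment covering ≥ 50% of their length are dropped, as are
segments touching a blacklist interval (≥ 1 bp); the remaining segments
are aggregated per direction by a breakpoint sweep into maximal
intervals supported by ≥ 2 distinct tumors. Recurrent CNVs are joined
against DMRs with a flag for copy-gained, hypermethylated regions.

## The CpG panel classifier

Candidates come from the significant probes in three stages: (1) drop
probes inside recurrent CNV intervals (dosage confounds methylation);
(2) keep probes whose rank AUC is exactly 1.00, orientation-agnostic
(max(U, 1−U)), so perfect hypomethylation separators count; (3) greedy
redundancy pruning in descending |Δβ| order at R² ≤ 0.90. Each stage
raises a named error if it empties the set.

The panel is an L1-penalized logistic regression on beta values (so the
model transfers to any external beta matrix), minimized as
`(1/n)·Σ NLL + λ·‖β‖₁` with an unpenalized intercept on internally
standardized columns, by cyclic coordinate descent inside an IRLS
quadratic approximation. The solver precomputes the weighted Gram matrix
per IRLS step (covariance updates, O(p) per coordinate), cycles the
active set between full KKT-checking passes, clips the linear predictor
at ±30, and — because separable problems have optima on the separation
ray where further coefficient growth changes no classification — stops
once 99.9% of the null deviance is explained. Final fits converge to a
max-coefficient-change of 1e-7.

λ is chosen by repeated stratified k-fold cross-validation (default 25
repetitions of fold assignment, 5 folds; desk scale 10), warm-starting
along a 50-value log grid spanning three decades down from λ_max;
held-out misclassification at threshold 0.5 is averaged and the largest
λ at the minimum wins (parsimony tie-break). The original description of
"1,000 permutations" for the penalty choice is read as repeated
randomization of fold assignments — the standard glmnet-style practice —
rather than a label-permutation null; the ambiguity is noted, not
resolved. CV path fits use a relaxed tolerance (1e-4) and a 95%
deviance-explained stop; held-out misclassification counts are
insensitive at that precision.

Scores are `logistic(intercept + Σ coef·β)`; a sample is called a tumor
only when its score strictly exceeds 0.5 (a score of exactly 0.5 is
normal). Evaluation reports the confusion counts, sensitivity,
specificity, accuracy, and the rank AUC of the scores.

## Orchestration and reproducibility

`run_pipeline` executes simulate → preprocess → dmp → dmr → cnv → train
→ evaluate, writing every artifact as TSV/JSON so any stage can be
resumed from files. A single seed is split into per-stage sub-seeds with
`numpy.random.SeedSequence.spawn` (fixed order: simulate, dmr, cnv,
train), outputs are stamped with the seed and a hash of the canonical
config (output paths excluded from the hash), and a rerun with the same
config is bit-identical. The `desk` scale caps resampling counts
(B = 200, 200 segmentation permutations, 10 CV repetitions) so a full
run of the canonical 20k-probe cohort completes in a few minutes on one
CPU; `full` restores the full-scale resampling counts (B = 1000, 10,000 permutations, 25 repetitions).

## Packaged studies

`methylforge.studies` ships the standard validation experiments: the
analytic copy-number anchor; end-to-end recovery on the canonical spiked
cohort (16/31 training, 30/70 external validation from the same
population); CN 1/3 segmentation recovery; moderation-prior
hyperparameter recovery; type-I and family-wise calibration on null
cohorts; and the confusion-count arithmetic of the canonical
external-validation structure (225/234 tumors, 88/90 non-tumors
correct → sensitivity 0.962, specificity 0.978). `scripts/acceptance.py`
runs them all and writes the numbers to JSON.

## What passing tests show — and what they do not

The synthetic cohorts share the *statistical skeleton* of a real
tumor/normal array study: bimodal betas, cellularity dilution, blocky
probe geography, dosage in total intensity, sporadic detection failures.
They deliberately omit batch and chip-position effects, dye bias,
cross-reactive probes, cell-type heterogeneity beyond the two-population
mixture, genuine biological variance structure (effects here are spiked
at a single Δ), and any dosage→beta coupling (copy number scales both
channels, leaving beta untouched). Recovery and calibration results
therefore validate the pipeline's *mechanics and error control* under
its stated model — they are not evidence about performance on any real
cohort, and the classifier's perfect training separation reflects the
generator's clean effect structure, not expected clinical performance.

## Known limitations

* The bimodality QC rule is a quantitative stand-in for what is usually
  a visual check; its mid-band threshold (0.35) is a convention.
* Vendor background correction and control-probe normalization are out
  of scope; quantile normalization of intensities is optional and off by
  default for methylation (it is always applied inside the CNV log-ratio
  computation, matching that workflow).
* The arc-length ladder makes the segmentation permutation test valid
  for the ladder-max statistic, not the all-arcs max; boundary
  refinement after acceptance recovers exact boundaries in practice.
* One-copy losses are intrinsically marginal at the −0.3 loss cut (see
  above); interpreting loss calls near that threshold requires care.
* The LASSO path can show one-step wiggles in active-set size near ties;
  the path-monotonicity check tolerates single-step violations and logs
  them rather than failing.
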