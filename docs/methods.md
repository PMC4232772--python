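# Methods

## Model and procedure

Expression measures are analyzed on log2 scale under the additive
fixed-effect model *Y = μ + STATE + ε* with Gaussian i.i.d. residuals, fit
separately for each two-state contrast (lethargus versus each flanking
stage; optionally an embryonic cuticle-synthesis contrast from a second
experiment). The fit is the one-way decomposition: group means, between-group
sum of squares on q = 1 degree of freedom, residual sum of squares RSS on
ν = n − 2 degrees of freedom.

### Shrinkage variance and Fs

With few replicates, per-feature variance estimates are unstable; the test
statistic Fs replaces the per-feature residual variance with a James–Stein
shrinkage estimate computed across all G features. Writing
`X_g = ln(max(RSS_g/ν, floor))`:

```
σ̃²_g = exp( X̄ + c (X_g − X̄) ) · B
c     = max(0, 1 − (G − 3) ψ₁(ν/2) / Σ_g (X_g − X̄)²)
B     = exp(−(ψ(ν/2) + ln 2 − ln ν))
```

ψ₁(ν/2) is the exact sampling variance of the log of a scaled χ²_ν, so `c`
is the positive-part James–Stein factor for the log variances, and `B`
removes the mean bias of the log-scale estimate (E[ln(χ²_ν/ν)] =
ψ(ν/2) + ln 2 − ln ν). When all X_g coincide the estimator pools completely;
when their dispersion is large, c → 1 and the per-feature estimates are
recovered up to B. With G ≤ 3 the factor is undefined and the code falls
back to unshrunk (bias-corrected) estimates with a warning. The variance
floor (1e-8) keeps zero-residual features inside the log transform.
A Monte-Carlo check (χ²₄ draws around a common variance, G = 1000, five
seeds) confirms the shrunk estimates have strictly smaller mean squared
error than the raw ones.

### Permutation p-values

P-values come from permuting the residuals of the null (grand-mean) model
across the contrast's samples; since the per-feature grand mean is
permutation-invariant, this equals permuting the observed sample values.
One permutation index vector per round is shared by all features,
preserving between-feature correlation (an independent-per-feature mode
exists behind a flag), and the shrinkage is re-estimated inside every round
(freezable by flag). Sampled permutations are canonicalized to their group
assignment (indices sorted within groups), so rounds that reproduce the
observed partition tie with the observed statistic bitwise.

**Pooling.** By default the permuted Fs values of *all* features form one
null distribution and a feature's p is the smoothed fraction of pooled
values at or above its observed Fs, `p_g = (1 + #{Fs* ≥ Fs_g}) / (1 +
n_perm · G)`. This is a deliberate design choice with a sharp reason: a
two-group design with r replicates per group has only C(2r, r) label
partitions, so with r = 3 a per-feature permutation p can never fall below
2/20 = 0.1 and no BH threshold of 0.05 is reachable — per-feature counting
(available as `pool=False`, the exact per-feature exceedance formula) is
usable only for larger designs. Pooling is statistically licensed here
because the shrunk denominator puts all features' Fs on a common scale; it
is the same device the shrinkage-F microarray literature uses at small n.
In exhaustive mode every group assignment is enumerated (identity included)
and p is the exact exceedance proportion without the smoothing term; this
mode reproduces label-enumeration oracles exactly and is feasible up to
50 000 assignments.

Caveat of pooling under strong signal: features with genuine effects
contribute inflated permuted Fs values to the shared null (most visibly in
rounds that reproduce the observed partition), so p-values are mildly
conservative when a large fraction of features is differentially expressed.
At the study's replicate depth (five per state) and planted fractions
(~8 %), recovery is unaffected (see the plant-and-recover results the
acceptance script computes); at 3 replicates the partition floor above
dominates regardless of effect size.

### Multiple testing and set rules

Raw p-values from the two lethargus-versus-flanking contrasts are doubled
(min(2p, 1)) — both tests must individually meet the criterion — and then
BH-corrected (doubling before BH by default; the order is swappable for
sensitivity analysis; doubling-then-BH at α is provably identical to
raw-BH at α/2, which the tests exploit as an independent rule evaluator).
The lethargus set keeps features with adjusted p < 0.05 in both contrasts
and agreeing direction (direction is defined relative to lethargus:
positive log2FC = higher in lethargus). The cuticle set keeps lethargus-set
members whose embryonic contrast has adjusted p < 0.30 with the same
direction; members missing from the embryo data are excluded and counted in
the log. For overlap testing, probe-level calls are reduced to genes: the
representative probe per gene is the one with the largest Fs (largest
across the supplied contrasts; ties go to the lexicographically smallest
probe id), a gene enters the directional lists only if its representative
probe is a set member showing ≥ 2-fold change in every contrast, and the
universe is the unique gene list after probe filtering. The fold filter
applies only to these reduced lists, not to set membership itself. Probes
mapping to multiple genes are rejected rather than guessed.

### Overlap testing

Overlap between two gene lists within the universe is a 2×2 table (in both
/ A only / B only / neither); the test is Fisher's exact, two-sided by the
minimum-likelihood rule, and the reported odds ratio is the sample
cross-product ad/bc (∞ or undefined when bc = 0) — not the conditional MLE
some packages print. The p-value is verified against an exact
binomial-coefficient enumeration oracle for every table with total ≤ 40.

### Protein composition and families

The APPG classifier computes, per protein: cysteine fraction; the number of
C-x₃-C-x₃-C matches (any residues at the six x positions, overlapping
matches counted); the maximum Q+N count in an 80-residue window (threshold
30 by the usual prion-richness convention — the defaults are configurable,
not asserted facts); and a deliberately simple, pluggable signal-peptide
heuristic (an 8-residue window starting within positions 2–25 with ≥ 6
hydrophobic residues) that stands in for a dedicated predictor. The call is
positive iff cysteine fraction ≥ 0.09 and motif count ≥ 1 (and, when
required by flag, a predicted signal). Families are built by average-linkage
clustering on 100 − percent identity from Needleman–Wunsch global alignment
(match +1, mismatch −1, linear gap −2); records are sorted by id before
clustering, making the tree invariant to input order with ties merging the
lexicographically smallest pair.

### Staging contamination

Pooled RNA is additive in molecules, so mixing is linear on intensity
scale: a fraction f of lethargus animals in an otherwise uniform population
makes a gene with lethargus:non-lethargus ratio R appear
`(1 − f) + f·R`-fold induced; the inverse is `f = (target − 1)/(R − 1)`.
The matrix-level operation (`spike_contamination`) applies the same
relation per feature, converting log2 matrices to linear internally. The
worked value: f = 0.005, R = 200 gives 1.995 — a 0.5 % staging impurity
mimics a two-fold induction.

## Synthetic data

The expression generator emulates a stage-structured bulk microarray
study: per value, log2 intensity = grand mean (8.0) + per-gene baseline
offset (SD 1.5) + per-probe affinity offset (SD 0.3; included so that
multi-probe summarization and representative-probe selection are exercised
on non-degenerate data, and zero recovers the pure additive model) + state
effect + N(0, noise_sd). Planted genes carry their effect in the lethargus
state relative to *both* flanking states, mirroring the two
lethargus-versus-flanking comparisons; |log2 effects| are uniform on
[2, 8] (4- to 256-fold, matching the hundreds-fold induction of molt
genes). Defaults: 1000 genes, 50 up / 30 down, three states, **five**
replicates per state (the replicate depth of the emulated study — and, per
the partition-floor argument above, the smallest design where an FDR of
0.05 is even reachable), noise SD 0.25 (the study reports no per-stage
variance estimates; this is a generator parameter, not a claimed value).
What the generator does *not* model: probe-level optical background and GC
effects, array spatial artifacts, correlated (non-i.i.d.) noise, and
intensity-dependent variance. Passing tests on this generator therefore
demonstrate the correctness of the statistical machinery under its stated
model, not robustness to those real-data pathologies.

The protein generator plants an APPG-like paralog family — mutated copies
(default 20 % per-site divergence) of one ancestral template carrying a
signal-peptide-like N-terminus, non-overlapping C-x₃-C-x₃-C motifs and a
topped-up cysteine fraction ≥ 9 % — against independent Q/N-rich background
sequences whose cysteine content is kept below threshold, so no background
record satisfies both classifier criteria jointly. Family structure (shared
template) is what makes identity-based clustering recoverable; background
records are mutually unrelated.

Contamination spiking, normalization, DE, set construction, overlap and
protein scanning are orchestrated by `run_pipeline`, which records seeds,
thresholds and per-stage filter counts in `report.json`; identical configs
and seeds give byte-identical reports.

## Numerical choices

- Quantile normalization: reference = row-wise mean of sorted columns; ties
  within a column get the mean of their tied-rank reference values. The
  operation is idempotent on tie-free data. It targets raw array
  intensities with comparable distributions; on synthetic matrices (already
  background-free and on a common scale, with an intentional directional
  excess of induced genes) it would only compress the planted signal, so
  synthetic end-to-end runs disable it.
- Median polish: row/column sweeps to a zero-median convention, max 10
  iterations, convergence at total absolute adjustment < 1e-6; summarized
  expression = overall + column effect; single-probe features pass through.
- Permutation comparisons use plain `>=` on canonicalized assignments (see
  above), making p-values exactly reproducible and tie handling principled.
- p smoothing `(1 + b)/(1 + N)` keeps p strictly positive, as BH requires.
- Fisher two-sided tie rule uses the conventional 1 + 1e-7 relative slack
  when comparing table likelihoods (the same convention R's fisher.test
  uses); the test-suite oracle applies the identical rule with exact
  integer arithmetic.
- Control features are dropped by id prefix (default `AFFX`) before
  statistics; unmapped probes are dropped with a logged count.
- Seeds: every stochastic operation takes one explicit integer seed; no
  global RNG state is used anywhere.

## Problem sizes

Simulation-based checks run at 1000 genes × 500 permutations (plant-and-
recover over five seeds, null calibration at 3 replicates per state to
probe the discrete-permutation regime), enumeration-oracle checks at 2v2
and 3v3 on 20 features, and the Fisher sweep over all tables with total
≤ 40 (test suite) or ≤ 30 (acceptance script). These sizes make the whole
suite run in a few minutes on one core while keeping every Monte-Carlo
margin comfortable.

## Known limitations

- The permutation test inherits the granularity of the design; per-feature
  p-values are unusable below ~6 samples per group, and pooled p-values are
  conservative when many features carry signal (see above).
- The signal-peptide heuristic is a coarse stand-in; callers needing real
  predictions should plug in a dedicated predictor via `classify_appg`'s
  `signal_predictor` argument.
- Alignment identity uses a fixed simple scoring scheme adequate for
  separating synthetic families; no substitution matrices.
- RMA background correction and CEL-file handling are out of scope; the
  pipeline starts from expression tables.
- The contamination model is forward-only: it predicts apparent folds from
  (f, R) but does not estimate f from observed mixtures.
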