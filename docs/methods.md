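# Methods

## Model

The unit of analysis is a curated regulator–target edge (miRNA→mRNA or
miRNA→lncRNA). Over the *n* normal samples the edge has a reference Pearson
correlation `PCC_n`; appending one query sample and recomputing over *n*+1
points gives `PCC_{n+1}` and the per-sample perturbation
`ΔPCC = PCC_{n+1} − PCC_n`. Its significance is assessed with

    Z = ΔPCC · (n − 1) / (1 − PCC_n²)

referred to a standard normal, two-sided. The denominator is
`(1 − PCC²)/(n − 1)` with **no square root**; this is deliberate and is the
statistic this package implements. A square-root variant
(`z_variant="sqrt"`), which standardises ΔPCC by the square root of the same
quantity, is available for sensitivity analysis but is not the default.
Under the default statistic the realised per-edge false-positive rate at
α = 0.05 is ≈ 0.07 on Gaussian data at n = 40–100 (slightly
anticonservative); the frequency aggregation below, not the per-edge test,
is the method's noise control.

Aggregation: an edge's frequency score over a cancer cohort is the fraction
of samples in which it is significant. Edges with score ≥ 0.4 form the
basic network; a miRNA's activity is the sum of its basic-network edge
scores times c1/c2 (basic-network degree over universe degree), so activity
lies in [0, c1²/c2]. Dark-matter miRNAs are those in the top-k (default 20)
of either network's activity ranking that fail the differential-expression
rule.

### Assumptions

- The normal cohort is homogeneous enough that a single reference
  correlation per edge is meaningful, and n ≥ 3 (in practice n ≥ ~20 for
  the normal approximation of Z to be useful).
- Expression is approximately Gaussian on the analysis scale
  (log2(x+1) by default), since Pearson correlation drives everything.
- Each query sample is exchangeable with the reference under the null;
  cancer samples are profiled in **add** mode. Reference members cannot be
  re-added (degenerate), so the normal cohort's own profiles use
  **leave-one-out**: the reference correlation is recomputed on the other
  n−1 samples and ΔPCC = (PCC over all n) − (PCC over n−1), with n−1 as the
  effective reference size in Z.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | two-sided per-edge level; no multiple-testing correction by default (BH within a profile behind `bh=True`) |
| `threshold` | 0.4 | frequency-score cut for the basic network |
| `fc_bounds` | (2.0, 0.5) | linear-scale fold-change bounds for "differential" |
| `top_k` | 20 | activity ranks counted as "high activity" |
| `folds` | 10 | stratified CV folds in the biomarker benchmark |
| `min_expressed_fraction` | 0.1 | loader drops features expressed in fewer samples |

Per-edge p-values are left uncorrected by default because each edge is
tested marginally and the cohort-frequency aggregation supplies the error
control; BH within a profile is available but shrinks every profile's edge
set roughly uniformly and so mostly rescales scores.

## The synthetic cohort generator

`simulate()` emulates a shrunken tumor study: 50 miRNAs, each regulating 8
mRNAs and 8 lncRNAs (one regulator per target), 40 normal and 200 cancer
samples. Generation is a Gaussian copula: target = ρ·(regulator latent) +
√(1−ρ²)·noise, mapped affinely to a log2-expression-like scale (miRNA mean
6, target mean 8, sd 1), so ρ is the exact population correlation of the
edge. Background edges draw ρ uniformly from (−0.8, −0.3) — repressive
regulation; positive "singular" couplings can be configured via
`base_pcc_range`.

Planted signal, defaults chosen once as a plausible strong-perturbation
regime:

- **Driver edges** (20 per target class) belong to 5 *dark-matter* miRNAs
  and use ρ = −0.95. In a Bernoulli(f = 0.6) mask of cancer samples the
  target is redrawn with the correlation **sign flipped** (a regulatory
  inversion; `perturb_mode="decorrelate"` instead severs the coupling).
  Means never move. The strong ρ is what makes a single perturbed sample
  detectable: the per-sample power of the Z test is ≈ 0.75 for a flip at
  ρ = −0.95 and n = 40, but only ≈ 0.5 at ρ = −0.8 — single-sample
  perturbation detection is intrinsically low-powered for moderate
  correlations, which is why the frequency aggregation across a cohort is
  essential.
- **Differential miRNAs** (5, disjoint from the dark-matter set) get a
  +2 log2 mean shift in all cancer samples with correlations untouched.

`expected_edge_score()` predicts a driver edge's frequency score by Monte
Carlo as `f·power + (1−f)·false_flag_rate`: the unperturbed fraction of
cancer samples still flags at the null rate, and omitting that term biases
the prediction low by ≈ (1−f)·0.07. The prediction marginalises over
reference draws, while each real edge conditions on its one realised
reference, so observed scores scatter around the prediction with a binomial
component (sd ≈ 0.035 at 200 samples) plus a conditioning component;
deviations up to ≈ 0.1 for the extreme of 20 edges are expected behaviour,
not failure.

A property worth noting: a mean-shifted miRNA also perturbs the measured
correlations of *all* its edges once its sample is appended to an unshifted
reference — its edges legitimately enter the basic network. The pipeline
separates the two signal kinds at the differential-expression step, not at
the network step. "Background" in recovery checks therefore means edges of
miRNAs carrying no planted signal of either kind.

### What the simulator does not model

Count noise (negative-binomial dispersion, library size), batch effects,
indirect/ceRNA correlation structure between targets, shared targets
between miRNAs, and cohort heterogeneity (subtypes). Passing tests show the
statistics behave as designed under clean Gaussian dependence; they do not
certify performance on real RNA-seq, where weaker correlations and
heavy-tailed noise will lower per-sample power.

## Numerical choices

- |PCC| is clamped to 1 − 1e-8 before the Z denominator, so perfectly
  correlated reference edges give large finite Z instead of dividing by 0.
- Zero-variance (constant) vectors make a correlation invalid (NaN);
  invalid reference edges are excluded from profiles and scores entirely
  rather than scored 0, so they cannot dilute frequencies.
- Ranking ties (equal scores or activities) break lexicographically on
  (regulator, target) / miRNA id; every ranking is deterministic.
- Scores are stored at full precision; the 3-decimal form (0.834) is
  display only.
- Fold change is computed on the linear scale (back-transforming
  log2(x+1) when the matrix is logged); the Welch t-test runs on the
  stored log-scale values; BH adjustment is across features.
- Sensitivity/specificity use the 0.5 point on the classifier's
  probability scale; AUC uses the continuous probabilities. Classifier
  presets: 400-tree random forest, an RBF SVM at C = 1.3471, γ = 0.084,
  and an LDA baseline. Folds are stratified with a fixed seed.

## Problem sizes in tests and the acceptance script

The default study design (400 edges per class, 40 + 200 samples) fits one
target class in under a second, so the full suite — including the 10-fold
random-forest benchmark and 2000-rep Monte-Carlo predictions — runs in
about half a minute. The acceptance script uses the same design: the
null-calibration check runs 200 edges at n_ref = 100 with 30 query samples;
the recomputation checks sweep 20 random instances of up to 50 edges and
30 samples.

## Known limitations

- The no-sqrt Z statistic is not a standardised quantity in the usual
  sense; its null is only approximately normal and mildly anticonservative.
  The package treats it as the method's defining statistic rather than
  deriving an exact null.
- Frequency scores compare cohorts of similar size fairly, but a very
  small cancer cohort quantises scores coarsely (n_samples is the
  denominator).
- Leave-one-out profiles for normal samples measure self-consistency, not
  true out-of-cohort perturbation; they are intentionally conservative.
- The activity score inherits the basic-network threshold: a miRNA whose
  edges all score just below the threshold has activity 0.
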