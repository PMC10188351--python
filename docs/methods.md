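# Methods

This note documents the statistical procedures geroscreen implements, the
assumptions behind them, the design choices made where the procedure was
genuinely open, and what the synthetic-cohort generator does and does not
emulate.

## Data model and assumptions

Each cohort is a gene × sample matrix of **already normalized, log2-scale**
expression together with per-sample clinical metadata. The package validates
structure (unique genes and samples, aligned metadata, survival time/event
pairing) but never re-normalizes: normalization is platform- and
dataset-specific and happens upstream. Duplicate gene rows collapse by their
mean (deterministic and order-independent); missing age excludes a sample
from the correlation stage only and missing survival from the survival stage
only — samples are never globally dropped.

## Age–expression correlation screen

Per dataset, Spearman's rank correlation between each gene and age is
computed on **case samples only** (controls carry no disease-age
interaction of interest), using average ranks for ties and the two-sided
large-sample t approximation for p-values (an exact permutation p is
available for n ≤ 9). Genes with zero expression variance are omitted;
datasets with fewer than 3 usable case samples are skipped.

**Sign consistency.** A gene joins the positive (negative) list when
ρ > 0 (ρ < 0) in at least `min_support` of the datasets where it is
*measured*; the default is one fewer than the number of contributing datasets
(11 of 12). Counting over measured datasets avoids penalizing platform gaps
while preserving the threshold's meaning; a gene must therefore be measured
in ≥ `min_support` datasets to qualify. Sign-only counting is used — no
per-dataset p threshold enters the filter; significance is assessed solely on
the combined p-value. With permissive thresholds (2·min_support ≤ datasets
measured) a gene could qualify for both sign lists; the larger count wins and
an exact tie excludes the gene, so the lists are always disjoint.

**Stouffer combination.** Per-dataset signed z-scores
z_i = sign(ρ_i)·Φ⁻¹(1 − p_i/2) are averaged with equal weights,
Z = Σz_i/√k, and the combined p is the two-sided normal tail of |Z|. Equal
weights (no √n weighting) keep each cohort's vote equal regardless of size.
p-values are clipped to [1e−300, 1−1e−16] before the quantile transform so
degenerate inputs cannot produce infinities. Significance is α = 0.05 on the
combined p, uncorrected across genes (a BH option exists but is off by
default, matching how such screens are typically applied); the combination
always uses *all* datasets measuring the gene, including the discordant one
allowed by the support rule.

**UpSet tables.** For reporting, exact-subset intersection counts of the
per-dataset sign lists are computed by direct set algebra (one row per
dataset subset of size ≥ `min_degree`), i.e. the tabular content of an UpSet
plot; plotting itself is out of scope.

## Differential-expression meta-analysis

Per dataset: LFC = mean(case) − mean(control) on the log2 scale; p from
Welch's two-sample t-test; BH correction within the dataset. Welch's t is a
deliberately simple, assumption-light test; the per-dataset test is pluggable
(any callable mapping the two group matrices to (lfc, p)), so a
moderated-variance variant can be substituted without touching the
meta-layer. Genes flat in both groups get p = 1. Across datasets:
combined LFC = arithmetic mean over the datasets measuring the gene;
combined p by direction-aware Stouffer with signs from per-dataset LFCs;
combined q by BH across genes. Because "minmax-normalized LFC" is not a
uniquely defined quantity, the meta table reports **both** the raw-scale
combined LFC (interpretable in log2 units) and a symmetric minmax-scaled
column (divided by the largest |combined LFC|, hence in [−1, 1] with the sign
preserved).

## Survival screen

Patients with age and survival metadata are assigned to age cohorts: young
(age < 45), middle-aged (45 ≤ age ≤ 60 — both boundaries inclusive, the
natural reading of "from 45 to 60"), senior (age > 60); bounds are
configurable. Within a cohort, each gene's median expression splits patients
into high (≥ median, ties included) and low (< median) arms. Arms are
compared with the two-group log-rank test (χ² with 1 df, asymptotic); KM
curves are fit with `lifelines`. A cohort cell is **not evaluable** when it
has < 4 patients, zero events, or constant expression. Direction of harm:
the arm with the smaller KM median survival is "worse"; when neither median
is defined the survival probabilities at the last common follow-up time are
compared; exact ties are indeterminate. A gene "stratifies by survival" when
significant in ≥ 1 cohort at α = 0.05 (no multiplicity correction across
genes/cohorts by default; a BH option across evaluable cells exists).
Per-cohort results are always retained so stricter definitions can be applied
downstream.

## Strategies and ranking

S1 = {significantly positively age-correlated} ∩ {significant, high-worse in
≥ 1 cohort}; S2 = {significantly negatively correlated} ∩ {significant,
low-worse}; S3 = {all significantly age-correlated, both signs} ∩
{user-supplied aging-target list}, matched case-insensitively with the match
type recorded. The sign lists are disjoint, so S1 ∩ S2 = ∅ structurally.
Provenance tables record exactly which predicates fired per gene.

The ranking is a transparent weighted sum over named evidence channels, each
minmax-scaled to [0, 1] over the candidates and oriented so 1 is best;
missing values take the channel's worst value. Defaults: equal weights over
combined correlation p (smaller better), |scaled combined LFC| (larger
better) and best survival χ² (larger better). This is an auditable stub —
it makes no claim of equivalence to proprietary multi-model AI target-scoring
engines, whose omics/text/funding scores are outside this package's scope.

## Synthetic cohort generator

The generator emulates the *statistical* structure the screen assumes: K
cohorts of heterogeneous size over a shared gene universe, uniform ages,
planted age-correlated genes of both signs, planted case-vs-control shifts,
and one large designated clinical cohort carrying survival metadata (the
role a large public tumor cohort plays in real screens; the other cohorts
have none).

* **Age effects.** Expression of a planted gene is linear in age plus
  Gaussian noise, case samples only. The slope is calibrated so the expected
  Spearman ρ matches the target via the bivariate-normal relation
  ρ_S = (6/π)·arcsin(ρ_P/2): given noise SD σ, the age-signal SD is
  s = σ·ρ_P/√(1−ρ_P²). Ages are uniform rather than normal, so the relation
  is approximate; empirically the mean bias is well inside ±0.1 for targets
  0.3–0.7 at n = 60. Each planted gene's sign flips independently per
  dataset with probability 1 − concordance.
* **Survival.** Exponential survival (constant baseline hazard, default
  0.0015/day, median ≈ 460 days — a realistic scale for an aggressive
  tumor) with log-hazard linear in the centred expression of designated
  genes within designated age cohorts, and administrative censoring at the
  horizon τ = −ln(censor_rate)/h₀ so the expected censored fraction under
  the baseline equals `censor_rate` (default 0.2).
* **Sizing.** Defaults: 12 datasets × 80 samples (75% cases, i.e. 60 cases
  for the correlation stage), 500 genes, 30 planted per correlation sign at
  |ρ| = 0.5, 20 planted fold-change genes at |LFC| = 1, noise SD 1.0 on the
  log2 scale. The survival cohort has 1500 samples (1125 patients), giving
  ≥ 350 patients per age cohort. This size is chosen because the hazard is
  log-linear in *continuous* expression: the within-arm heterogeneity acts
  as frailty and attenuates the marginal high-vs-low hazard ratio, so a
  median-split log-rank screen needs a few hundred patients per cohort for
  reliably high power at a per-unit log-HR of 0.8.
* **Known emergent property.** Planted age-correlated genes share age as a
  common latent factor. In a cohort where *any* age-linked gene drives the
  hazard, age itself becomes prognostic, so other age-correlated genes
  acquire indirect survival associations there. This mirrors real data
  (age is a strong prognostic factor in age-linked cancers) and means
  "extra" red heatmap cells beyond the directly planted ones are expected,
  with directions consistent with each gene's correlation sign. Ground-truth
  evaluation therefore scores recall of directly planted effects and
  cross-sign contamination, not raw false-positive counts in hazard-bearing
  cohorts.

What the generator does **not** emulate: platform/batch effects, count-level
(negative-binomial) noise, gene-gene correlation beyond the shared age
factor, missing genes per platform, non-uniform age distributions,
non-exponential hazards, or informative censoring. Passing tests therefore
demonstrate correctness and calibration of the *procedures* under the stated
model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* p-value clipping to [1e−300, 1−1e−16] before normal quantile transforms.
* Spearman/Welch statistics computed vectorized; results match
  scipy.stats.spearmanr / ttest_ind to machine precision (tested).
* Deterministic orderings everywhere: combined tables sort by combined p
  then symbol; ranking ties break lexicographically; merges use stable sorts.
* Zero-variance genes: omitted from correlation; p = 1 in DE when flat in
  both groups; indeterminate (not evaluable) in the median split.
* Zero events in a log-rank comparison: χ² = 0, p = 1 with a warning.
* All simulation randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning, so collections are bit-reproducible
  and the full pipeline is a pure function of (config, input files).

## Limitations

The per-dataset DE test is Welch's t, not a moderated-variance model — with
very few samples per group its power is below limma-style empirical-Bayes
tests. The survival screen dichotomizes at the median (required by the
design it implements); a Cox model on continuous expression would be more
efficient but answers a different question. The combined correlation
significance threshold is per-gene and uncorrected by default, matching the
screening convention it reproduces; callers needing FDR control should enable
the BH options.
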