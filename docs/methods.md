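# Methods

`anchoromics` implements an anchor-gene multi-omics correlation analysis:
all statistics are organized around one reference feature (the *anchor*,
e.g. the synaptic gene NPTX2) whose correlation with every other measured
variable — transcripts, targeted-proteomics proteins, metadata, principal
components — is profiled, compared across diagnosis groups, clustered into
modules, and tested for pathway-level enrichment.

## Data model

Matrices are features × samples, log-scale (e.g. variance-stabilized
RNA-seq values or log2 protein abundances), with explicit missingness
(`NA`/empty on disk, NaN in memory). Identifiers are matched by string
across files, never by position. Diagnosis groups are
Control / MCI / AD / Other.

## Peptide-to-protein rollup (targeted proteomics)

Parallel-reaction-monitoring panels quantify a protein through several
peptides (raw peak areas, strictly positive). The rollup divides each
peptide by its median over non-missing samples, applies log2, and averages
the transformed peptides of a protein per sample over non-missing entries.
Two consequences worth noting:

* multiplying any peptide's row by a positive constant cancels exactly in
  the median ratio, so instrument response differences between peptides do
  not propagate;
* the median is taken over *non-missing* samples and the per-protein
  average skips missing peptide cells rather than propagating them — the
  only defined choices under missingness, and consistent with the
  pairwise-complete philosophy used for correlations.

Peptides with no observed value, and proteins losing all peptides, are
dropped with a logged warning.

## Correlation statistics

All correlations are Pearson over pairwise-complete observations. A result
is *excluded* (not reported, with a reason) when fewer than three complete
pairs remain or either restricted vector has zero variance.

Two p-value routes exist and are used in different places, each exposed
behind a switch:

* **Fisher z** — z = atanh(r)·√(n−3) against the standard normal; used for
  anchor/volcano profiles (requires n ≥ 4);
* **t-test on r** — t = r·√((n−2)/(1−r²)) with n−2 df; used for the
  all-pairs variable table (requires n ≥ 3).

Both are two-sided only. FDR control is step-up Benjamini–Hochberg with
cumulative-minimum enforcement; a log-space variant performs the ranking
and min-accumulation on log p so that heavily underflowing p-values retain
their order (used for the all-pairs table, whose smallest p-values
underflow at large n). The two variants agree to ~1e−10 when no underflow
occurs. The FDR family for an anchor profile is all non-excluded features
of that run; features excluded for low n or zero variance are not part of
the family.

Profile tiers on |r|: moderate ≥ 0.50, weak ≥ 0.30, otherwise ns. In the
all-pairs table, |r| ≥ 0.70 flags a *strong* association after collapsing
symmetric duplicates. These cuts are configurable but default to the
conventional values above.

## Group shifts, Mahalanobis separation, classification

For a (gene, anchor) pair, within-group Pearson r is computed per
diagnosis group under the same validity rules; groups with fewer than
three complete pairs are marked excluded rather than silently dropped.
Group geometry in the 2-D (gene, anchor) plane:

* **centroids** and normal-theory **coverage ellipses** (axes
  √(eigenvalue·q), q the χ²(2) quantile at the requested coverage,
  default 95%);
* **Mahalanobis distance** D = √((μa−μb)ᵀ S⁻¹ (μa−μb)) with S the
  (n−1)-weighted pooled within-group covariance. D is invariant to any
  common affine map of both groups. A singular S raises an error
  suggesting a ridge fallback rather than silently regularizing.

Qualitative classes are deliberately simple threshold rules, calibrated so
that the published qualitative vocabulary for this kind of analysis maps
onto them and kept configurable because no universal numeric convention
exists:

* **decorrelation** (change Δ = r_disease − r_reference): stable when
  |Δ| < 0.02, decorrelated when Δ ≤ −0.02, over-correlated when
  Δ ≥ +0.02;
* **separation** on D: little < 0.60 ≤ moderate < 0.90 ≤ strong.

Group-level abundance contrasts use Wilcoxon rank-sum tests for the three
pairwise Control/MCI/AD comparisons with BH across the three. For combined
n ≤ 20 the two-sided p is computed by exact enumeration of all group
assignments on midranks (ties handled exactly; identical multisets give
p = 1); larger samples use the tie-corrected normal approximation.

## Correlation modules and path labels

A mixed variable set (RNA features, proteins, numeric metadata, component
scores; each prefixed with its modality) is clustered by average linkage
(UPGMA) on the distance d = 1 − r (range [0, 2]); zero-variance variables
are dropped and pairs excluded by the validity rules are imputed with the
maximum observed distance, both logged.

Module labels are path strings ("1/2/1") assigned top-down for `cut_depth`
levels. At each level a cluster is split into the maximal subclusters
below the largest gap in its subtree's sorted merge heights, provided that
gap is at least half the subtree's height span; without a dominant gap the
split falls back to the plain binary root split. Clusters whose root merge
height is below 0.5 (members cohering at average r > 0.5) are treated as
coherent modules and never split further; their labels are padded with 1s
to the full depth. Children are numbered by increasing mean subtree merge
height, ties broken by smallest leaf index. This makes labels
deterministic and invariant to input order (up to renaming), lets a level
hold more than two branches, and recovers planted block structure exactly:
a strict binary reading cannot, because average-linkage trees over
equidistant blocks are balanced for only about half of random seeds.

## PCA phenotypes and outlier exclusion

Principal components are computed by SVD of the gene-centered matrix with
samples as observations. Samples whose PC1 or PC2 score lies beyond a
configurable ±3 SD of that component's mean are flagged, excluded in a
single pass (not iteratively), and the decomposition is recomputed on the
retained samples; reported scores therefore have mean 0 per component.
Each loading vector is oriented so its largest-magnitude entry is
positive, removing eigenvector sign ambiguity so downstream enrichment
ranks are reproducible. PC loadings can be used as anchor phenotypes for
enrichment, treating a data-driven expression axis the same way as a gene.

On clean multivariate-normal data the expected flag rate at 3 SD is the
two-PC normal tail (~0.5%); a single 500-sample draw has ~0.3% binomial
noise around it, so tests assess the rate averaged over replicate
matrices.

## Anchored enrichment (mean-rank ES, permutation NES)

Features are ranked by ascending correlation with the anchor (average
ranks on ties; excluded features leave the universe). For a gene set S,

    ES(S) = mean(rank of members) − (N + 1)/2.

ES is invariant to monotone transforms of the correlations and obeys the
complement identity ES(Sᶜ) = −(|S|/|Sᶜ|)·ES(S). Positive ES means the set
concentrates among positively correlated features.

Significance uses a *phenotype permutation*: the anchor vector is shuffled
across samples — one shared shuffle per permutation for every set and
every anchor in a run, so NES values are comparable — correlations and
ranks are recomputed, and ES is re-evaluated, giving a per-set null mean
and SD and

    NES = (ES − mean_null) / sd_null.

Gene-label permutation is deliberately not offered: shuffling the anchor
preserves the inter-gene correlation structure under the null, which is
what the phenotype-permutation semantics require. Two-sided p-values come
from the standard-normal approximation of NES (the empirical permutation
tail is also reported as a diagnostic), with BH across sets. The default
is 5,000 permutations; the test-suite and the bundled pipeline preset use
500, which changes NES by well under the null resolution. Sets whose
permutation null has zero SD (e.g. a set equal to the whole universe) are
flagged with NES undefined.

Leading edges are the up-to-five members with the largest positive r
(Pos5) and the most negative r (Neg5), each ordered by |r|; members of the
wrong sign are not padded in, so a set can legitimately report a single
negative contributor.

A running-sum curve (equal-weight hits +1/|S|, misses −1/|Sᶜ|) is exported
for plotting; it returns to zero at position N. The mean-rank ES remains
the inferential statistic — the curve is descriptive only.

**Background uniqueness.** To separate anchor-specific enrichment from
generic co-expression, each background gene (grouped into categories such
as synaptic / trafficking / lysosomal / regulatory) is run as its own
anchor through the identical enrichment with the same permutation
schedule. Per set and category the median |NES| over the category's
anchors is computed, and the set is *unique* to the main anchor when
|NES_main| ≥ 1.2 × every category median. Per-category medians (rather
than one pooled median) are used because backgrounds are curated as
categories; each background anchor is normalized against its own
permutation null so the comparison is between calibrated z-scores.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
a default scale of 60/60/60 Control/MCI/AD samples and 2,000 genes with a
20-protein panel (chosen to keep generation under a second while leaving
correlation estimates stable); `study_scale_config()` provides a
575-sample preset with 180/83/218 (+94 Other) groups and a 135-sample
protein subpanel, matching the cohort scale this design emulates.

* One standard-normal latent factor Z per sample. The anchor RNA is
  baseline + group offset + Z, with default offsets 0 / −0.4 / −0.8 log
  units for Control / MCI / AD — a stepwise decline whose pairwise
  Wilcoxon contrasts are significant at the default group sizes.
* A module gene with group-specific target coupling ρ_g and sign s is
  s·ρ_g·Z + √(1−ρ_g²)·ε, which gives exactly the population within-group
  correlation s·ρ_g with the anchor — closed-form calibration, no
  fitting. Defaults plant a positively coupled "plasticity" module
  (ρ = 0.60/0.45/0.30 across Control/MCI/AD: transcript-level
  decorrelation in disease) and a negatively coupled "stress/lysosomal"
  module (ρ = 0.30/0.35/0.45: strengthening inverse coupling).
  Background genes are independent noise.
* The protein layer covers a configurable gene subset (anchor first, then
  module genes round-robin, then background). Protein = ρ_rp·z(RNA) +
  √(1−ρ_rp²)·η with RNA standardized *within group*, so ρ_rp (default
  0.37, a moderate RNA–protein coupling) is the within-group target; the
  anchor protein additionally receives group offsets (default 0 / −0.5 /
  −1.0 within-group SDs), reproducing a disease protein downshift with
  stable within-group correlation. The anchor's overall RNA–protein r
  then exceeds ρ_rp slightly because the aligned declines add shared
  between-group variance — the same reason an overall r and within-group
  r differ in cohort data.
* Peptides are 2^(protein + noise) × an arbitrary per-peptide constant
  (default 3 peptides/protein, noise SD 0.3 log2 units), exercising the
  rollup's median/log2 path on realistic positive peak areas; optional
  uniform missingness thins the peptide layer.
* Metadata (age, sex, source, PMI, CERAD, Braak) is drawn from
  group-plausible distributions; an optional PMI confounder couples PMI to
  a lysosomal-like panel protein and is off by default.

What the generator does **not** emulate: count-level sampling noise
(values are Gaussian on the log scale, which is what the pipeline
consumes), cell-type composition shifts, batch/source effects, realistic
gene–gene correlation beyond the planted single-factor modules, and
informative (non-uniform) missingness. Passing recovery tests therefore
certify the statistical machinery — calibration of the null, correct
propagation of planted couplings and shifts — not robustness to those
real-data complications.

`emit_true_gene_sets` turns the planted truth into a GMT-style collection
(one set per module plus uniform background draws) so enrichment can be
tested against known positives and calibrated negatives.

## Pipeline, determinism, numerics

`run_pipeline` chains simulate/load → rollup → group stats → anchor
profiles (RNA and protein anchors) → group shifts for the top correlates →
PCA → mixed-variable modules → all-pairs table → enrichment, writing only
TSV/JSON artifacts plus a manifest that echoes the config, every numeric
threshold in play, derived stage seeds, and input checksums. One run seed
fans out to per-stage seeds via SHA-256 of the stage name (kept below
2³¹), so stages are independently reproducible and a fixed seed reproduces
every artifact byte-identically.

Numerical choices: correlations are clipped to [−1, 1]; zero-variance
detection uses an exact nan-variance check in the scalar path and a
relative 1e−12 floor in the vectorized path; |r| = 1 yields the p = 0
limit explicitly; BH is capped at 1; matrix TSV round-trips are
bit-identical because parsing uses correctly rounded `float()`. Wilcoxon
switches from exact enumeration to the tie-corrected normal approximation
at combined n = 20 (exactness where enumerable, standard correction
elsewhere). The permutation null uses the sample SD (ddof = 1).

## Known limitations

* The qualitative class thresholds (±0.02 band, 0.60/0.90 cuts) are
  calibration choices, not estimated quantities; sampling noise in r and D
  near a boundary will flip labels.
* The normal approximation for NES p-values is only as good as the
  permutation null's normality; the empirical tail p is reported alongside
  for checking.
* The separation statistic assumes roughly elliptical within-group
  clouds; heavy tails inflate D.
* PCA outlier exclusion is a single pass; a pathological sample masked by
  a more extreme one is only caught on rerun.
* Module labels depend on the documented gap/coherence rules; other
  reasonable conventions produce different (equally valid) labelings of
  the same tree.
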