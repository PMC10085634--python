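# Methods

This note documents the statistical procedures `colonyscreen` implements,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real screens.

## Input model

One Iris-format file per photographed plate: `#`-prefixed comments, a
header row, then one row per colony with 1-based `row`/`column` indices and
numeric measurement columns. The default measurement is `size`; any numeric
column (e.g. `colony integral opacity`, which weights size by optical
density and better reflects three-dimensional growth) can be selected.
Plate identity is parsed from the filename; the default convention is
`<condition>-<library_plate>_<replicate>.iris` (e.g. `RIF2-6_C.iris`),
overridable by any regular expression with named groups `condition`,
`plate`, `replicate`. Non-numeric measurement cells become missing with a
warning rather than an error: one corrupt cell must not abort a
thousand-plate run. A layout TSV (`plate  row  column  gene`) names the
strain at each position; `WT` is reserved for wildtype and `EMPTY` for
unoccupied positions.

**Stray zeros.** A zero measurement beside non-zero replicates almost
always records a pinning or detection failure, not biology, so within each
(strain, condition) replicate set zeros are converted to missing *unless
every* non-missing replicate is zero — a consistent all-zero set is a real
no-growth phenotype and is kept. The small-screen pipeline skips this step
entirely: in a targeted screen zero growth is usually the result of
interest.

## Two-step plate normalization

Colonies on the outer rows/columns of a dense array grow larger because
they face less nutrient competition. Stage 1 targets this per plate:

1. The grid is partitioned into the outermost ring, the second ring, and
   the centre (requires at least a 5×5 grid).
2. A two-sided Wilcoxon rank-sum test compares the pooled outer-two-ring
   values with the centre (α = 0.05 by default; the test is skipped, and no
   correction applied, when either side has fewer than 3 values).
3. If significant, every colony in ring *k* is multiplied by
   median(centre)/median(ring *k*). Median scaling is the minimal monotone
   transform that equalizes the ring and centre medians exactly and is
   robust to outliers; a zero ring median leaves that ring uncorrected with
   a warning. The correction is idempotent.

Stage 2 makes plates comparable across conditions: each plate is multiplied
by `dataset_median / mean(centre cells)`, where the dataset median is taken
over all stage-1-corrected values. "Centre" deliberately excludes the outer
two rings so that plates whose edge effect was too weak to correct do not
leak it into the scale factor. After stage 2 every plate's centre mean
equals the dataset median to floating-point accuracy. Missing values are
ignored by every median/mean and remain missing. No spatial smoothing
beyond the two-ring scheme is attempted (row/column gradients within the
centre are out of scope).

## Quality control

Four statistics, each targeting a concrete laboratory failure mode; the
user chooses which tests gate curation and at what thresholds.

* **Percentage normality (per replicate plate).** Each position's replicate
  values are standardized (Z = (x − mean)/std with the sample, n−1, std);
  a colony is abnormal if missing or |Z| > 1 (strict). Constant replicate
  sets, and lone observations, get Z = 0 — they carry no evidence of being
  outliers. The plate's score is the percentage of normal colonies; it
  drops when pinning pressure varied across a plate. With exactly 2
  replicates |Z| = 1/√2 always, so the test can only count missing values;
  a runtime warning says so.
* **Mann–Whitney concordance (per replicate plate).** Two-sided
  Mann–Whitney tests between every pair of replicate colony-size
  distributions (scipy's implementation: exact for small samples, tie-
  corrected normal approximation otherwise); each replicate's score is the
  mean p over its pairs. Mislabelled plates and gross pinning failures
  surface as one replicate with a much lower score.
* **Condition-level tests.** The variance of the replicates' Mann–Whitney
  mean p-values (large when all replicates disagree — e.g. coloured media
  defeating colony detection), and the mean across positions of the
  across-replicate sample variance.

`threshold_curves` tabulates the data lost at candidate thresholds: for the
plate-level tests (which fail low) the percentage of replicate plates lost
per condition — normality over the conventional 20–80% grid; for the
condition-level tests (which fail high) the number of conditions lost, over
seven quantiles of the observed statistic range. `curate` removes plates
failing *either* enabled plate test and conditions failing either enabled
condition test, logs every removal with its failing statistic, and re-runs
normalization on the survivors.

## S-scores

For strain *i* in condition *c*:

    S = (mu_exp - mu_cont) / sqrt(s_exp^2 / n_exp + s_cont^2 / n_cont)

* `mu_exp`, `n_exp`: mean and count of the cell's non-missing replicates.
* `s_exp`: population (ddof = 0) std of those replicates, bounded below by
  a **relative variance floor**: the median of std/mean across the strains
  of the same condition × library-plate group, times the cell's own
  `mu_exp`. The floor stops accidentally tight replicates from exploding
  the score. It is deliberately relative, not absolute: an absolute floor
  (median of raw stds) shrinks typical strains' scores but never binds for
  a strain that is uniformly larger, systematically inflating that strain's
  |S| (≈30% for a 2× strain in simulation); the relative floor makes the
  statistic equivariant under uniform per-strain rescaling, which the
  self-control tests verify. Cells with a single replicate use the floor
  outright and are annotated low-confidence.
* `mu_cont`, `n_cont`: median and count of the strain's values pooled over
  every condition-replicate — the strain as its own control, so globally
  fast or slow growers are judged against their own baseline.
* `s_cont = mu_cont × r`, with `r` the dataset-wide median of the per-cell
  relative error std/mean. No closed form for the control spread follows
  from the control being a median, so it is placed on the control's own
  scale with the dataset's typical relative noise.

Non-finite scores (zero denominator) are set missing: an infinite score
carries no usable magnitude. Scores are then rescaled group-wise so each
group's IQR equals 1.35 — because most mutants are unaffected in most
conditions, scores concentrate near zero, and at IQR 1.35 the standard
1.5×IQR outlier fence falls near ±2. The default scaling group is each
condition × library-plate (one physical plate's scores); `--scale-by
condition` treats each condition column as one group instead. Hits are
called strictly: S < −3 (defect; the threshold is asymmetric because
loss-of-function phenotypes are far more common) and S > 2 (gain). Groups
with zero IQR are left unscaled and flagged.

For visualization the matrix is hierarchically clustered (rows and columns)
with uncentred Pearson correlation distance — 1 − Σxy/√(Σx²Σy²) over
pairwise-complete positions, i.e. cosine distance — and average linkage,
and written as CDT/GTR/ATR files for Java-TreeView-style viewers.

## Benchmarks

**Operon ROC.** Genes in one operon usually share function, so their
S-score profiles should be more alike than cross-operon pairs. Profile
pairs (cosine similarity over shared conditions, minimum overlap 3) are
labelled positive (same operon) or negative (different operons; subsampled
to 10× the positives with a fixed seed by default, since the negative
universe is quadratic — full enumeration is available). At each of 21
thresholds from −1 to 1 in steps of 0.1 a pair is called positive when its
similarity is strictly greater than the threshold; sensitivity, specificity
and FPR per threshold give an ROC whose AUC is the trapezoid area over the
(FPR, sensitivity) staircase anchored at (0,0) and (1,1). Because operon
co-membership is an imperfect proxy for shared function, AUC is a relative
quality measure between processing variants, not an absolute accuracy.

**Bootstrap robustness.** The smallest exchangeable unit the pipeline
consumes is the replicate measurement within a (strain, condition) cell, so
bootstrap draw *b* resamples each cell's non-missing replicates with
replacement (count preserved, missing stays missing), using
`numpy.random.default_rng([seed, b])` consumed in stored column-then-row
order — the draw is fully defined by the seed. Each draw re-runs scoring
and scaling; MAE = mean |mean_b(S_b) − S_true| over cells observed in both,
also reported as a percentage of the true scores' std. B defaults to 1000;
identical replicates give MAE exactly 0.

## Small screens

Fitness ratios replace S-scores when few conditions are screened and the
assumption of mostly-null, symmetrically distributed effects fails. Per
physical plate the denominator is the mean of that plate's pooled WT
colonies (plates with no usable WT are excluded with a warning): the bar/
heatmap statistic is mean(mutant colonies)/mean(WT), the swarm statistic is
each colony/mean(WT). Across replicate plates the mean ratio carries a
Student-t 95% CI (n = replicate plates). Significance is the CI excluding
1 (bar plots) and a pairwise one-way ANOVA of mutant vs WT per-colony
ratios (swarm plots) — pairwise rather than omnibus because the question is
each mutant's difference from wildtype; with two groups the ANOVA F is
exactly the squared pooled-variance t. Star bands: ns p > 0.05, \*
0.01 < p ≤ 0.05, \*\* 0.001 < p ≤ 0.01, \*\*\* 0.0001 < p ≤ 0.001,
\*\*\*\* p ≤ 0.0001. No multiple-testing correction is applied by default.

## Genetic interactions

Per replicate plate (several WT colonies are pooled by mean), the ratios
F_A, F_B and observed F_AB are each genotype's mean colony size over the
WT mean; expected F_AB = F_A × F_B from the *same* replicate. Replicates
with zero/missing WT are dropped; fewer than two survivors is an error.
The call is a one-way ANOVA between the replicate vectors of observed and
expected double ratios at α = 0.05: none unless significant, else positive
(alleviating) when delta = mean(obs) − mean(exp) > 0, negative
(synergistic) otherwise. Zero variance on both sides is degenerate (p := 1,
no call). Replicate pairing is plate-level, not pinning-quadrant-level. GI
plates are small and carry no meaningful ring structure, so normalization
is off by default (a flag enables it).

## Synthetic screens

The generator builds colony sizes multiplicatively — base × plate scale ×
ring multiplier × injected effect × noise — matching the structure the
pipeline assumes:

* log-normal base sizes (median 1200 units, 25% CV across strains):
  positive and right-skewed like real colony quantifications;
* edge multipliers (1.5, 1.2) on the outer two rings — a pronounced but
  realistic edge effect;
* 15% plate-scale jitter across condition/replicate plates, 10% replicate
  noise per colony;
* 0.5% missing positions and 0.5% mis-pins (literal zeros, exercising the
  stray-zero rule);
* injected (strain, condition) multipliers recorded in a ground-truth
  table; operon groups share correlated log-effect profiles
  (ρ = 0.9, log-sd 0.5 by default);
* GI plates: double = WT × F_A × F_B × (1 + offset), with offset 0 the
  multiplicative null.

`simulate_small` forces a common base size for all strains: in a targeted
screen of isogenic knockouts, baseline growth differences are themselves
the phenotype, so they belong in the injected effect table — this makes the
injected multipliers the ground-truth fitness ratios. Identical config and
seed reproduce all outputs byte-for-byte.

What the generator does *not* emulate: spatial gradients other than the
two-ring edge effect, colony-size saturation and neighbour competition,
batch drift over time, condition-correlated detection failures, and
non-multiplicative noise. Passing recovery tests therefore demonstrate the
pipeline's statistical machinery under its own model assumptions, not
robustness to every artefact of real screens.

## Problem sizes and numerical choices

The test suite runs the power/recovery properties at deliberate desk
scale: 100 seeded repetitions per property, 96-position (8×12) or
25-position (5×5) grids, 10–30 conditions, 3–6 replicates; the
normalization contract uses 100 full-density 32×48 plates, and bootstrap
checks use B = 50 (B = 1000 remains the pipeline default). Quantiles use
numpy's default linear interpolation; IQR scaling tolerance is 10⁻⁶;
normalization post-conditions hold to 10⁻⁹ relative. Ties in the rank
tests use scipy's tie-corrected p-values (identical samples give p = 1).
Degenerate inputs are mapped to conservative answers throughout: Z = 0 for
zero-spread replicate sets, skipped edge tests apply no correction,
zero-IQR groups stay unscaled, zero-variance ANOVA inputs report p = 1.

## Known limitations

* The variance-floor and control-spread constants of the original
  E-MAP-style S-score formulations are not standardized; the definitions
  above are this package's declared choices, kept deliberately simple and
  scale-free.
* Percentage normality is computed per (condition, replicate) across all
  library plates jointly; with many library plates a per-library-plate
  breakdown may localize errors better.
* Cosine similarity over few shared conditions is noisy; the minimum
  overlap of 3 is a floor, not a guarantee.
* The AUC is computed on the fixed 21-point threshold grid, so it is only
  approximately invariant under monotone transforms of the similarity
  scores (exact invariance would require threshold-free ROC construction).
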