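# Methods

`afmaturity` re-implements, as a tested library, a gestational-maturity
analysis of cell-free RNA (cfRNA) from amniotic fluid (AF): differential
expression across three gestational stages, attribution of abundant AF
transcripts to their tissue/cell of origin, a fetal-origin sanity check,
and junction-based alternative-splicing (PSI) comparison. The pipeline is
exercised end to end on a synthetic study generator that plants known
ground truth, so every recovery and error-rate claim in the test suite is
measured against a truth the generator recorded.

## Study design being emulated

Three stage groups of AF cfRNA samples: prenatal (PN, 18–24 weeks,
n = 4), late preterm (PT, 34–36 weeks, n = 6) and full term (FT, 39–40
weeks, n = 6). Within the late-preterm group, morbidity flags mark three
infants needing respiratory support and three needing gavage feeding, with
one infant carrying both flags. Fetal sexes are balanced within each stage
group so that the sex-marker genes carry no stage signal.

## Synthetic data generator

The generator is first-class, deterministic code: one `numpy` PCG64 stream
seeded from `SimulationConfig.seed` produces the whole bundle, so equal
seeds give byte-identical outputs.

**Expression.** RPKM-scale values are `2^(mu_gs + eps)` with
`eps ~ N(0, noise_sd_log2^2)` (default 0.4 log2 units — a typical
biological+technical spread for bulk RNA-seq at this depth). Gene baselines
are `N(3, 1.5^2)` on the log2 scale. Planted components of the mean
`mu_gs`:

- *Stage-monotone genes* (default 200; half induced, half suppressed):
  means move by `stage_effect_log2` (default 1.5) per stage step, upward
  PN→PT→FT for induced genes and downward for suppressed ones.
- *Tissue markers* (66 tissues × 10 markers): each tissue carries a
  stage-activity pattern (fractions of its markers detectable per stage,
  cycling through ramp-up / late / early / constitutive / rare / transient
  shapes). Active markers gain `activity_log2` (default 6) in that stage's
  samples; inactive markers sit at a fixed modest baseline (log2 = 2) so
  they stay clear of the top-decile abundance cut. The realized per-tissue
  fractions are recorded in the ground truth. Mean activity (~0.2) keeps
  the expected number of active markers per stage (~130) below the
  top-decile capacity (~200 genes of 2000), so the abundance threshold
  separates active from inactive markers cleanly.
- *Sex markers*: XIST is high (log2 = 7) in female and low in male
  samples; RPS4Y1/DDX3Y/EIF1AY the reverse. Only XIST has an explicit
  literature anchor; the chrY trio are standard male-specific transcripts.

`activity_profile="constant"` makes every tissue's activity identical
across stages. Together with `stage_effect_log2 = 0` and `psi_shift = 0`
this defines the *fully null* configuration used for type-I-error
calibration: with the default stage-varying activity table the marker
genes are genuinely differential, which would make a "null" false-positive
count meaningless.

**Atlas.** Gene-by-tissue means are log2-normal around per-gene baselines;
each planted marker's value in its home tissue is set to exactly
`marker_expression_fold` (default 8) times the mean of the other tissues.
With 0.4 log2-unit atlas noise, the expected maximum among 65 non-target
tissues is ~2.2× their mean, so planted markers clear both specificity
rules with margin while non-markers almost never do (measured false-call
rate ≲ 0.2%).

**Junctions.** Each of the (default 50) cassette-exon events contributes
three junctions on one chromosome — two inclusion junctions flanking an
internal exon and one exclusion junction sharing both outer splice sites.
Per sample, total event depth is Poisson around `base_junction_depth`
(default 60, floored at 1); `n_incl ~ Binomial(depth, PSI_true)` reads
support inclusion, the remainder exclusion, and the inclusion reads are
split symmetrically between the two inclusion junctions so that the
event-level PSI estimate is exactly binomial around the truth. True PSI is
uniform on [0.15, 0.85 − shift] and moves by `psi_shift` (default 0.3)
between PT and FT, alternating direction across events; PN follows PT.
Decoy junctions on a second chromosome share no boundaries and must never
enter an event. A deep reference panel ("body-map"-like) contains a
configured fraction (default 0.5) of the events.

**What the generator does not emulate.** Maternal contamination, library
composition biases, gene length effects, correlated noise between genes,
annotation-dependent event classes (intron retention, mutually exclusive
exons), and count overdispersion beyond Poisson depth jitter. Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not performance on real AF cfRNA.

## Normalization and differential expression

- **TMM scaling** (`tmm_normalize`): per-sample factor = exp2 of the
  weighted mean of per-gene log2 ratios against a reference sample
  (the one with the most typical upper quartile), after trimming 30% from
  each tail by log-ratio and 5% by average log abundance; weights are
  inverse approximate binomial variances; factors are rescaled to
  geometric mean 1. Note this variant takes ratios of raw values, so pure
  depth differences show up in the factors (an exactly doubled sample
  yields the (1/√2, √2) pair); it is intended for count-scale input.
- **Detectability filter**: keep genes with RPKM > 1 in at least one
  sample (strict inequality).
- **Stage test** (`anova_stage_test`): one-way fixed-effects ANOVA on
  log2(RPKM + 1) across PN/PT/FT, Benjamini–Hochberg adjusted, plus the
  three pairwise contrasts with fold changes as ratios of pseudocounted
  linear group means. A gene is differential when adjusted p ≤ 0.05 and
  some pairwise fold ≥ 1.5. Degenerate zero-between-variance genes report
  p = 1; zero-within with positive between reports p = 0. The pseudocount
  bounds folds for near-zero genes but makes results only approximately
  invariant to a global rescaling of all samples (the pseudocount's
  relative weight changes); column-permutation invariance is exact.
- **BH adjustment** is delegated to `statsmodels.multipletests` behind
  `benjamini_hochberg`; the test suite checks it against an independent
  brute-force step-up implementation.
- **Moderated t** (`moderated_t_test`): per-gene pooled two-group
  variances are shrunk toward a scaled inverse-chi-square prior,
  `s̃² = (d0·s0² + d·s²)/(d0 + d)`, with (d0, s0²) estimated by moment
  matching on log variances (digamma/trigamma closed forms; Newton inverse
  trigamma) and t̃ referred to a t distribution with d + d0 degrees of
  freedom. `prior_df=0` recovers the ordinary t exactly (tested);
  `prior_df=None` estimates it. "Regulated" requires unadjusted p ≤ 0.05
  and fold > 2 — deliberately unadjusted because the morbidity subgroups
  (3 vs 6) have no power to spare; BH-adjusted p-values are reported
  alongside for transparency.
- **Temporal patterns** (`classify_temporal_patterns`): the default
  "sign" rule calls a differential gene induced when its log2 stage means
  are non-decreasing PN→PT→FT with at least one increase (tolerance 0 by
  default), and mirrored for suppressed. The "som" alternative trains a
  seeded 1-D self-organizing map (default 2 nodes, Gaussian
  neighbourhood, learning rate 0.5→0.01 linearly over 500 epochs) on
  z-scored stage-mean triples and labels nodes by codebook slope; on
  noise-free data it reproduces the sign labels for all planted genes.

## Tissue profiling

- **Abundance**: a gene is abundant in a stage when its mean over that
  stage's samples strictly exceeds the 0.90 linear-interpolation quantile
  of all per-gene stage means. The quantile is taken per stage over stage
  means (not per sample) because the downstream comparison is stage-wise.
- **Specificity**: candidate tissue = argmax over the atlas row;
  *enriched* iff expression ≥ 3× the mean of all other tissues; *specific*
  iff additionally ≥ 1.5× every other tissue. Argmax ties make a gene
  non-specific. All-zero rows and genes absent from the atlas are skipped
  and reported.
- **Stage marker profile**: per tissue and stage, the fraction of that
  tissue's specific markers (among those present in the matrix) that are
  abundant at that stage. Tissues with no specific marker are omitted.
- **Marker-set enrichment**: exact hypergeometric upper tail
  P(X ≥ r) via `scipy.stats.hypergeom` plus the standardized overlap
  z-score with finite-population correction; one-sided
  (over-representation), significant at p < 0.05. Marker sets are
  intersected with the universe first; empty intersections are skipped;
  a query outside the universe is an error.
- **Fetal origin**: a sample is predicted male when the mean of the chrY
  markers exceeds XIST, female otherwise; missing markers downgrade the
  prediction to unknown rather than erroring.

## Splicing (PSI)

Junction BED12 files are parsed with the intron recovered from the two
anchor blocks; records with other block counts are skipped and counted.
Event detection is coordinate-exact and strand-blind. For every candidate
exclusion junction, inclusion candidates share exactly one splice site and
end strictly inside the exclusion span; a left and a right candidate with
a nonempty implied exon between them merge into a cassette event, and
unpaired candidates become single-inclusion alt-5'/3' events. PSI =
inclusion/(inclusion + exclusion) with cassette inclusion support averaged
over the two inclusion junctions; samples with fewer than 10 supporting
reads (configurable) are missing. Group contrasts use ΔPSI = mean(B) −
mean(A) over non-missing samples and call an event regulated when
|ΔPSI| ≥ 0.1 and a two-sided Mann–Whitney test gives p ≤ 0.05
(unadjusted, same small-cohort rationale as above); events with fewer than
2 informative samples per group are dropped. Panel filtering calls an
event "found" when its exclusion junction and at least one inclusion
junction match a reference panel exactly; events absent from a deep
adult/placental panel are candidate fetal-specific isoforms.

## Numerical choices and degenerate inputs

- log2(x + 1) everywhere a log scale is needed; fold changes are ratios of
  pseudocounted linear means with direction reported separately so folds
  stay ≥ 1.
- BH inputs outside [0, 1] are rejected, not clipped.
- The trigamma inverse uses the asymptotic branches 1/√x (large x) and 1/x
  (small x) with Newton refinement between, converging to 1e-10.
- Mann–Whitney with both groups constant and equal reports p = 1.
- `tmm_normalize` refuses all-zero samples and single-sample matrices;
  genes with a zero in either sample are excluded from that factor fit.
- Event ids are built from sorted junction coordinates, so detection is
  independent of input order.

## Problem sizes

Defaults (2000 genes, 66 tissues, 16 samples, 50 events) run the full
pipeline in well under a second, which is what lets the suite measure
type-I error and power over 50 replicate simulations and lets
`scripts/acceptance.py` recompute every reported quantity from scratch in
a few seconds.

## Known limitations

- The moderated-t prior assumes variances exchangeable across genes after
  scaling; mean–variance trends (as modelled by voom/limma-trend) are not.
- The TMM variant's raw-ratio M values fold sequencing depth into the
  factors; matrices already on a depth-normalized (RPKM) scale should not
  be re-normalized with it.
- Splicing regulation thresholds (|ΔPSI| ≥ 0.1, rank test) are a
  pragmatic default for 6-vs-6 designs, not a calibrated criterion.
- Marker-set enrichment treats gene sets as unweighted; no background
  expression matching is attempted.
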