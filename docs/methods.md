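# Methods

This note records the statistical model behind each stage, the
assumptions baked into the synthetic cohorts, and the numerical
conventions a user should know before trusting or modifying results.

## Study structure

The pipeline targets a discordant-monozygotic-twin EWAS design with
five sample groups: discovery twin pairs (one affected, one unaffected
co-twin each), unaffected control twin pairs, independent replication
twin pairs, singleton subjects sampled before and after diagnosis, and
autoantibody-positive but disease-free singletons. The sample sheet is
the single source of grouping truth. For control pairs — where neither
co-twin is affected — the `status` column records an arbitrary but
fixed "index co-twin" assignment that determines the sign of intra-pair
differences; the variance profile computed from those differences is
unchanged under a global reassignment, and single-pair reassignments
are neutral in distribution.

## Preprocessing

**Beta values.** `β = max(M,0)/(max(M,0)+max(U,0)+100)`. The +100
offset stabilises low-intensity probes and bounds β strictly below 1;
negative raw intensities are legal and clamped. β is monotone
increasing in M, decreasing in U.

**Sample QC.** Two rules with *strict* inequalities: discard an array
when its missing-beta fraction exceeds 0.05; flag an array whose
non-missing betas include fewer than 10% values ≥ 0.75 (loss of the
expected bimodal marginal). A flagged array would be re-hybridised in
the lab; software has no re-run, so flagged arrays are excluded by
default while the flag is preserved so callers can substitute repeat
data. Both thresholds are exposed as parameters.

**Probe filter.** Keep exactly the autosomal probes with complete data
across the retained arrays. A probe absent from the annotation is an
error (its chromosome cannot be established). Each dropped probe gets
one reason; `sex_chromosome` takes precedence over `incomplete`.

**Quantile normalization.** Each sample's sorted values are replaced by
the across-sample mean of order statistics, preserving within-sample
rank order. Tied values receive the mean of the order-statistic means
they jointly occupy (average-rank convention), which makes the
transform deterministic and idempotent; with ties present, the
marginal-equality guarantee holds up to that averaging.

## Rank tests

Both Wilcoxon tests are implemented with explicit branch control:

- **Exact branch** — the full tie-free null distribution by dynamic
  programming (equivalent to enumerating all 2^n sign assignments, or
  all C(n1+n2, n1) rank arrangements). Used when the data are tie-free
  and n ≤ 25 (signed-rank) or min(n1, n2) ≤ 10 (rank-sum). Two-sided
  p = min(1, 2·min(lower tail, upper tail)).
- **Approximation branch** — midrank statistic, normal approximation
  with tie-corrected variance and a 0.5 continuity correction toward
  the mean. Used for larger samples or tied data (including exact
  zeros' midranks counterpart in the rank-sum case).
- Zero paired differences are dropped before ranking (classical
  Wilcoxon zero handling; Pratt's method is not used). An all-zero
  difference vector is degenerate: p = 1 with a degeneracy flag.

Exact p-values are discrete: at n = 15 pairs the attainable two-sided
rejection rate at the 0.01 threshold is ≈ 0.0084, not 0.01, and under
the null `mean(−ln p)` over exact-branch tests sits slightly below 1.
The calibration of the exponential-scale statistic therefore uses the
approximation branch, whose p-values are effectively continuous.

## Discovery

Per probe, a two-sided signed-rank test of the paired differences; all
probes with p < α (default 0.01) are called MVPs. No multiple-testing
correction is applied — with ~10⁴–10⁵ probes and 15 pairs the exact
test cannot reach Bonferroni-scale thresholds, so the threshold is a
triage device and the call set records `n_probes_tested` for users who
wish to post-correct. Direction is the sign of the *mean* paired
difference (the quantity reported per MVP).

**Excess-count permutation.** The affected/unaffected labels within a
pair are exchangeable under the null, so each permutation independently
negates every pair's difference column with probability 1/2 and
recounts calls. Empirical p-values use the add-one estimator
`(1 + #{count* ≥ observed}) / (n_perm + 1)`, which never returns zero.

**Neighbor analysis.** For each MVP, the closest same-chromosome
assayed probe within 2 kb (if any); neighbors of hyper-MVPs are
compared with neighbors of hypo-MVPs by one-sided Welch's t on their
mean intra-pair differences. This detects regional (DMR-like) signal:
it is powered only when effects span promoter mates.

## Variance control, replication, amplicons

Control-pair variance is the per-probe sample variance (ddof = 1) of
intra-pair differences across control pairs, ranked increasingly with
ties broken by probe order. The enrichment test is one-sided Welch on
raw variances (MVP probes lower); variances are right-skewed, so a
log-scale comparison can be performed by the caller on the profile
table if desired. A single-probe call set falls back to a one-sample
formulation with a warning.

Replication compares hyper- vs hypo-MVP mean intra-pair differences in
unseen pairs (one-sided Welch, hyper > hypo). Bootstrap CIs (50% and
95%, percentile) resample MVP *probes* with replacement — the plotted
unit; with only a handful of replication pairs, pair-resampling would
be far too coarse. The amplicon group test applies the same one-sided
Welch to externally supplied per-amplicon mean differences; a
zero-variance degenerate case returns 0.5/0/1 by the sign of the mean
difference.

## Temporal enrichment

Per MVP, a one-sided rank-sum test of case singletons vs all 2·n_pairs
control-twin individuals, oriented by the discovery direction, and the
summary `X = mean(−ln p)`. Natural logarithms are required: under a
uniform p, −ln p ~ Exp(1), so X is the scale parameter of the fitted
exponential and 1 is the null value.

Two caveats are intrinsic and documented rather than hidden:

1. Control individuals are pair-correlated while the rank-sum null
   assumes exchangeability (a nonparametric Behrens–Fisher situation).
   With strongly correlated pairs this inflates the null X slightly
   (≈ +0.04 at the default generator correlation of 0.8); the
   Brunner–Munzel alternative (`alt_test="behrens-fisher"`) addresses
   unequal variances but is uncomputable under complete separation, so
   the conservative rank-sum remains the default.
2. **Bootstrap form.** Replicates resample the case samples and the
   control *pairs* (both co-twins together, preserving the within-pair
   correlation; pair-level resampling yields wider, honest intervals
   than individual-level resampling on correlated data). X is convex
   in the underlying rank statistics, so with only 7 + 9 resampling
   units the bootstrap replicates X* sit systematically above the
   point estimate; a raw percentile interval inherits that bias and a
   percentile CI-inversion p rejects null data. The implementation
   therefore uses the **basic (reflected) bootstrap**:
   CI = [2X − Q(1−a), 2X − Q(a)], and the one-sided p — the level at
   which the one-sided interval's leftmost limit reaches 1 — is the
   add-one fraction of replicates with X* ≥ 2X − 1. This corrects the
   bias to first order; coverage of the null value remains approximate
   at these sample sizes (the interval tends to sit conservatively
   low), which is a known limitation, not an error.

Bootstrap replicates contain duplicated samples, hence ties, so they
are generally evaluated on the tie-corrected approximation branch even
when the point estimate used the exact branch. Degenerate replicates
(all tests uninformative) are kept and counted in a diagnostics field.

The pre-vs-post comparison applies the same machinery with per-subject
(post − pre) differences, one-sided signed-rank tests, and a
subject-level bootstrap. The directionality fraction is the share of
MVPs with sign(mean(case) − mean(control)) equal to the discovery
direction; exact zero differences count as inconsistent.

## Synthetic cohorts

`simulate_cohort` draws, per probe p and sample s:

    β[p,s] = clip( μ[p] + shared[p,g(s)] + ε[p,s] + effect, 0, 1 )

- μ per *promoter* (both promoter mates share it) from the bimodal
  mixture 0.7·Beta(5, 25) + 0.3·Beta(25, 5) — a low-methylation mode
  near 0.17 and a high mode near 0.83, as promoter arrays show.
- `shared` is a biological deviation common to a twin pair (or to the
  two time points of one subject), s.d. `noise_sd·sqrt(ρ/(1−ρ))`;
  ε is per-array technical noise with s.d. `noise_sd`. MZ-twin biology
  is modelled as fully pair-shared, so the within-pair correlation of
  measured values is exactly ρ (`pair_correlation`) and intra-pair
  differences contain only technical noise plus any effect.
- Effects: `n_true_mvps` autosomal probes receive an additive shift on
  the proportion scale (magnitude uniform in `effect_range`, clipped),
  positive with probability `hyper_fraction`; affected co-twins and
  case singletons carry it, control pairs never do. Additive
  proportion-scale effects match how intra-pair differences are
  reported (percentage points); logit-scale effects were rejected
  because they would distort the stated effect ranges at extreme μ.
- Annotation: probes laid out two per promoter, 500–2,000 bp apart
  (`neighbor_spacing_bp`), promoters 100 kb apart cycling through the
  autosomes, with `frac_sex_probes` of probes placed on chrX/chrY;
  missing values masked uniformly at `missing_rate`.

Key parameter defaults and their provenance:

| parameter | default | units | basis |
|---|---|---|---|
| n_probes | 27,458 | probes | array size of the emulated platform |
| n_discovery / control / replication pairs | 15 / 9 / 4 | pairs | study design |
| n_pre_post_subjects / n_abpos_singletons | 7 / 4 | subjects | study design |
| n_true_mvps | 132 | probes | discovery call count being emulated |
| effect_range | (0.0013, 0.066) | proportion | reported mean intra-pair difference range |
| hyper_fraction | 58/132 | — | reported hyper:hypo split |
| pair_correlation | 0.8 | — | **assumption**: MZ co-twin methylation is highly correlated; no value is reported for the emulated data |
| noise_sd | 0.02 | proportion | **assumption**: ~2 percentage-point technical noise, typical of this array class |
| missing_rate | 0.005 | — | **assumption**; yields ~21–22K complete probes of 27,458 after filtering, matching the reported retention scale |
| frac_sex_probes | 0.04 | — | approximate X/Y share of the platform |

A single seed drives named sub-streams (annotation, baseline, truth,
one per cohort, missingness), so enlarging one cohort never perturbs
another's draws.

**What the generator does not emulate**, hence what passing tests do
not demonstrate about real data: probe-type chemistry differences,
batch/chip effects, cell-composition heterogeneity (the emulated design
used purified monocytes precisely to avoid it), spatial correlation
beyond promoter mates, non-uniform missingness, and reduced biological
metastability at true MVPs — on synthetic data the control-pair
variance enrichment test is therefore null unless the half-noise
scenario is constructed explicitly, and the neighbor analysis is null
unless `effects_span_promoter=True`.

## Problem sizes used in the shipped checks

The calibration of X under the null uses 7 cases vs 9 control pairs
over 20,000–100,000 probes (the statistic's Monte-Carlo error scales as
1/√P; the estimand is unchanged). The type-I calibration of MVP calling
uses 15 pairs × 22,645 probes × 3 replicates. Recovery checks inject
132 effects of 3–6% among 6,000 probes and run discovery, replication
(n_boot = 2,000) and all three singleton enrichments (n_boot = 2,000).
The bundled demo study uses 5,000 probes and n_boot = 5,000. All
complete in seconds to a few minutes on one CPU; production-scale
n_boot = 100,000 enrichment runs take on the order of a minute per
cohort.

## Known limitations

- Exact-test discreteness at n = 15 means the realised discovery type-I
  rate is ≈ 0.84× the nominal threshold; calibration statements account
  for this rather than "correcting" it.
- The rank-sum enrichment inherits a small anti-conservative null shift
  from control pair-correlation (documented above).
- Basic-bootstrap intervals for X are first-order bias-corrected only;
  with 7 + 9 resampling units their coverage is approximate.
- No imputation anywhere: missingness always removes data (samples,
  probes, or zero-difference pairs), never fills it.
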