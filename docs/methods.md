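# Methods

This note documents the models, conventions and design decisions behind
`neurosym`: the symptom-classification pipeline, the hub-graph analysis,
and the synthetic-cohort generator used to validate both.

## Data model

A cohort is a set of subjects, each with a complete real-valued tensor of
baseline-corrected spectral source amplitudes indexed by ROI (1..68, the
Desikan–Killiany parcels), frequency band (θ, α, β) and cognitive task
(1 = Go Green I, 2 = Go Green II, 3 = Lost Star, 4 = Middle Fish,
5 = Face Off), together with four non-negative integer self-report scores.
Values may be negative (baseline correction). Flattening order is fixed:
ROI-major, then band, then task. A subject is labeled positive for a
symptom iff its score ≥ 5 (the threshold is configurable).

**Atlas reconstruction.** The 68 ROI ids follow the rule
`id = 2a − 1` (left) / `2a` (right) with `a` the 1-based alphabetical rank
of the 34 parcel names. This mapping is a *reconstruction* inferred from
published exemplars (it reproduces all fourteen printed id/name/hemisphere
triples) — no authoritative full table was available. A user-supplied
atlas file overrides it.

## Feature augmentation

Stage 1 adds seven statistics (max, min, range, mean, std, q75, q25) taken
across each of the three axes: across ROIs (7·B·T features), across tasks
(7·R·B) and across bands (7·R·T), giving
`m = R·B·T + 7·(B·T + R·B + R·T)` features (4933 at full scale). Stage 2
forms every pairwise product `x_i x_j` (i < j); stage 3 pairs every
feature with a calibrated log transform
`log(1 + (x − min)/(max − min))` ∈ [0, log 2]. The universe of
`2(m + C(m,2))` features (24,339,422 at full scale) is streamed in
fixed-size blocks in a deterministic order — singletons first, then pairs
lexicographically; each base column occupies positions 2p (plain) and
2p + 1 (log) — and only selected columns are ever materialized cohort-wide.

Numerical conventions (each chosen once and fixed so toy examples are
deterministic): population standard deviation (divide by n); quantiles by
linear interpolation between order statistics; a constant feature maps to
all zeros under both calibrations (the limit of the formulas as the spread
vanishes). In fold-safe mode calibration min/max come from the training
partition; on held-out rows the scaled value of a log feature is clipped
to [0, 1] to stay inside the transform's domain (plain features are left
unclipped).

## Chi-squared scoring and selection

The selection score is the chi-squared statistic extended to non-negative
continuous values: with S_c the per-class value sum and
E_c = (S_0 + S_1)·P_c,

    χ²(D, c) = (S_0 − E_0)²/E_0 + (S_1 − E_1)²/E_1 .

It is scale-linear (χ²(ax) = a·χ²(x)), subject-order invariant, zero for
constant or all-zero features, and is used purely as a ranking score.
Because products of baseline-corrected amplitudes can be negative while
the statistic needs non-negative sums, any feature containing a negative
value is min–max rescaled to [0, 1] before scoring ("auto" mode; "always"
and "off" are available). This non-negativity handling is our
reconstruction — documented prominently because no canonical treatment
exists for this statistic on signed data.

Top-k selection (k = 40,000 by default) is exact: a bounded running top-k
over the stream equals full materialization + sort, with ties broken
toward the earlier stream position. Selection happens inside each CV
training fold by default; the `paper_faithful` mode selects once on the
whole cohort before splitting (the two modes bracket the optimistic and
unbiased reading of the original procedure, and both are reported by the
evaluation tools).

A property worth knowing: on signed, heavy-tailed features (products of
zero-mean variables) the statistic is outlier-driven — a column whose
min–max-scaled mass concentrates in a few subjects can score an order of
magnitude higher than a well-separated but symmetric column. At small n
with millions of candidates the selection noise floor is therefore high;
this is intrinsic to the statistic, and is the reason the synthetic
validation (below) uses strongly expressed planted effects.

## Oversampling

Training folds only. SMOTE balances the classes exactly (synthetic points
are convex combinations of a minority sample and one of its k = 5 nearest
minority neighbours; k is reduced with a warning when the minority class is
smaller). The balanced set is then stacked with `factor = 9` replicas
perturbed by Gaussian noise with diagonal covariance equal to `1/100` of
the per-feature variance. SMOTE-then-Gaussian is the default composition;
the reverse order is available (`oversample_order`).

## Classification and evaluation

L2-penalized logistic regression, objective
Σ log(1 + exp(−y_i·wᵀx_i)) + λ‖w‖² with λ = 1, labels coded ±1
internally. The solve is delegated to scikit-learn with C = 1/(2λ) (the
two objectives are proportional); tests verify the solver against a
brute-force objective grid. The intercept is included and unpenalized
(standard practice; the penalized form has none, so it can be disabled).
Features are standardized with training-fold mean/sd before fitting — L2
penalties are scale-sensitive.

Evaluation: 5 repeats of stratified 5-fold CV (25 fold-evaluations);
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total. A zero denominator raises rather than silently returning 0.
The chance-level yardsticks are the normal-approximation proportion CI
(half-width 100·z·√(p(1−p)/n), i.e. ±9.95 percentage points at n = 97)
and a label-permutation null: labels are shuffled across subjects
(preserving class counts), the full pipeline is re-run, and the 95th
percentile of the mean-accuracy distribution is the control threshold.
The null runs one repeat of 5-fold CV per permutation by default
(`null_repeats`).

**Fold-fixed null (fold-safe mode).** For the augmented variant in
fold-safe mode the fold partition is stratified on the original labels and
held fixed across permutations; selection and calibration are then refit
per training partition for every permuted label vector, with all
permutations scored in a single pass per fold. Under the null the permuted
labels are exchangeable with the originals, so the fixed partition remains
approximately stratified; holding it fixed removes a nuisance source of
variation and makes the 100-permutation null computable in a few passes.
In paper-faithful mode selection is redone per permutation (one multi-label
pass) and CV is re-split per permutation. A degenerate training partition
(single-class after permutation) falls back to the majority predictor.

## Hub graph

Every product feature whose two constituents occupy concrete, distinct
ROIs contributes its χ² (plain and log variants both) to the pair strength
strength_{i₁,i₂}; features without such a pair — singletons, across-ROI
statistics, same-ROI products — are skipped and counted. Sub-accumulators
per pair record the χ² mass per band, per task and per log flag of each
constituent; an "aggregated" attribute (e.g. a mean across bands) is
tracked as its own level but never competes in the dominance argmax, which
is taken over concrete levels only with ties broken by fixed order
(θ < α < β; tasks 1..5). The aggregation is a single pass, order-invariant
and additive over record streams.

The aggregation universe is *all* ROI-pair-attributable product features
(with and without log); the analysis reports its own universe size in its
summary. (The original description of which feature subset enters the
strength sums is internally inconsistent — its stated count is not
derivable from any of its feature-count formulas — so the complete-universe
convention is used here.)

Edges: pair strength > threshold (default 100; primary reading). An
alternative `vertex_sum` mode implements the other published reading (edge
when the two endpoint vertex strengths sum above the threshold). Vertex
strength is the incident pair-strength sum. Centralities are current-flow
closeness (information centrality, 1/Σ_u R_eff(v, u)) and current-flow
betweenness (pairwise electrical throughput, endpoints excluded,
normalized by (n−1)(n−2)/2), computed per connected component with edge
weights as conductances; vertices in singleton components are undefined
(NaN) and a 2-vertex component has betweenness 0 by convention. Both are
delegated to networkx and verified against a dense Laplacian-pseudo-inverse
solve in the tests.

## Synthetic cohort generator

The generator emulates the statistical shape of the motivating cohort, not
its physiology. Tensor cells are zero-mean Gaussian with a per-ROI common
factor: cell = √ρ·u_roi + √(1−ρ)·ε, unit marginal variance, scaled by
`noise_sd`. Each symptom has a latent score
Σ β·z (main effects) + Σ β·z₁z₂ (cross-ROI interactions) + logistic noise,
mapped to integer scores 0..ceiling by rank binning calibrated so the
"score ≥ 5" rule hits the target prevalence exactly (up to rounding) —
prevalence control without distributional assumptions. With all β = 0 the
labels are independent of the features by construction.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 97 | the emulated cohort size |
| tensor shape | 68 × 3 × 5 | the emulated feature space |
| noise_sd | 1.0 | arbitrary units; the pipeline is scale-aware |
| roi_corr ρ | 0.8 | amplitudes of one cortical source across bands/tasks are strongly correlated in source-localized data; a high ρ also spreads a planted interaction over the whole cross-ROI product family, which is the regime in which pair-level strength aggregation is informative |
| latent_noise | 0.25 | moderate label noise: a single main effect of β = 3 has Bayes accuracy ≈ 0.95, i.e. planted signals are strong but labels are not deterministic |
| prevalence | 0.4 | keeps the majority-class baseline at 0.6 so accuracy comparisons are not dominated by class imbalance; configurable per symptom |
| score ceilings | 21/27/27/27 | the ranges of the emulated instruments |

What the generator does **not** emulate: EEG time series or spectral
estimation, spatial covariance between neighbouring ROIs, instrument-
specific score distributions, comorbidity structure beyond shared features,
and the (unknown) tail behavior of real source amplitudes. Passing the
synthetic validation therefore shows that the pipeline recovers the kind
of structure it assumes — planted cross-ROI interactions expressed across
correlated cell families — not that real cohorts contain such structure or
that the published real-cohort metrics are reproducible; those require the
private dataset.

## Validation problem sizes

The end-to-end statistical checks run at a reduced scale chosen to keep
the full suite fast while preserving the regime of interest (feature
universe ≫ subjects): 200 subjects, 16 ROIs × 3 bands × 5 tasks
(≈ 1.5 M augmented features), one planted interaction at β = 6, k = 2000
(the same order of universe fraction as 40,000 of 24.3 M), one repeat of
stratified 5-fold CV per seed, ten seeds, and a 100-permutation null.
Under these conditions the augmented pipeline's median accuracy exceeds
the raw-feature variant by ≥ 0.1 and the permutation-null 95th percentile,
and the planted ROI pair ranks first in the strength matrix in ≥ 9/10
seeds.

## Known limitations

- The chi-squared statistic's outlier sensitivity on signed data (above)
  means weakly expressed interactions are not reliably selected at
  n ≈ 100–200; the method's power claims should be read in that light.
- Fold-safe selection at full scale (24.3 M features × 25 folds) is
  computationally heavy; the paper-faithful mode is cheaper (one pass) but
  optimistically biased, and its permutation null is inflated accordingly
  — always compare against the null computed under the same mode.
- Strength aggregation uses whole-cohort labels (it is a descriptive
  statistic, not a cross-validated one); centrality values are therefore
  cohort-dependent and carry no inferential guarantee.
- The atlas id mapping is reconstructed, not authoritative.
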