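# Methods

## The model

Connectome-based predictive modeling treats each of the N(N−1)/2 unique
connectivity edges as a candidate predictor of a continuous phenotype. For a
training set of subjects with edge weights `x_e` (Fisher-z transformed
Pearson correlations between regional time series) and scores `y`:

1. **Screening.** Per edge, the Pearson correlation `r_e = corr(x_e, y)` and
   its two-sided p-value from `t = r√((n−2)/(1−r²))` with n−2 df. Edges with
   strictly `p < θ` are kept (default θ = 0.01) and partitioned by the sign
   of `r_e`. Ties at θ are excluded, which makes selections nested in θ.
   Constant edges are assigned r = 0, p = 1; `|r| = 1` gives p = 0.
2. **Features.** Per subject, the positive-set sum `Σ⁺` and negative-set sum
   `Σ⁻` of edge weights (empty set → 0).
3. **Model.** One bivariate OLS fit `y ~ 1 + Σ⁺ + Σ⁻` (both sums enter a
   single linear model). The classic variant with two univariate models
   (one per sign) is available via `mode="separate"`. A feature constant
   across the training set is dropped; if both are dropped the model falls
   back to the training mean and the fit record says so.
4. **LOOCV.** With n subjects, n folds; the held-out subject is predicted
   from its own sums under the *training* selection and coefficients, so its
   score cannot influence its own prediction. Accuracy is the Pearson
   correlation of the n out-of-fold predictions with the observed scores.
5. **Permutation test.** Scores are permuted across subjects and the entire
   cross-validated procedure re-run; with B permutations the p-value is the
   add-one estimator `(1 + #{r_null ≥ r_obs})/(B + 1)`, which is never 0 and
   is exact under exchangeability. A null replicate whose predictions are
   constant has undefined accuracy and is counted as not exceeding the
   observed value, since it carries no evidence of predictive signal.
6. **Consensus.** An edge enters the final positive (negative) network iff
   it is selected with that sign in *every* fold — aggregation is set
   intersection, the standard reading of "survived each iteration"; a union
   mode exists for sensitivity analysis and keeps the two networks disjoint
   by dropping sign-conflicted edges. Per-edge consensus weight is the mean
   connectome weight over subjects.

All modules share one frozen edge order — the row-major upper triangle
(0,1), (0,2), …, (N−2,N−1) — so fold-wise selections can be intersected by
index and summation order is reproducible.

## Strength metrics

For a fixed edge set and one subject: network strength is the signed sum of
Fisher-z weights (negative weights subtract; the published strengths are all
positive, consistent with predominantly positive weights among selected
edges, and an `absolute=True` variant exists for sensitivity analysis);
pair strength restricts the sum to edges whose endpoints form a given
unordered subnetwork pair; node strength sums the edges incident to a node.
Two exact identities are maintained and tested: node strengths sum to twice
the network strength (handshake), and pair strengths over all unordered
pairs sum to the network strength (partition).

Composition percentages (cross- vs within-subnetwork, per-pair shares) are
rounded half-up to 2 decimal places, matching the convention of the reported
values (e.g. 96.02%, 27.27%); Python's default half-even rounding would
disagree on exact halves.

## Group comparisons

Strength measures are compared among groups by the partial F for the group
factor in `value ~ 1 + group + age + gender + education_years + mean_fd`
(gender coded 0 = female, 1 = male). With a single categorical factor this
partial F equals the Type III F. Zero-variance covariates are aliased with
the intercept and are dropped, so the test then reduces exactly to one-way
ANOVA; genuine collinearity among remaining columns raises an error naming
the aliased columns. A constant response, or a group factor adding nothing,
yields F = 0, p = 1 rather than 0/0.

The Bonferroni family for the network-strength block is m = 7 (two totals
plus five subnetwork-pair measures); the source analysis does not state its
family size, so m is explicit and configurable. Node-level tests across all
nodes use Benjamini–Hochberg FDR at q = 0.05. Post hoc contrasts offer
Fisher's LSD (pooled-error t, N−k df, unadjusted), Bonferroni on the LSD t,
and a Dunnett-T3-style unequal-variance contrast (Welch t with
Welch–Satterthwaite df referred to the studentized-range distribution over
the k groups, as in Games–Howell) intended for use when a
variance-homogeneity check fails. Paired positive-vs-negative strength
comparisons use the two-sided paired t-test; two identical vectors give
t = 0, p = 1 by convention rather than NaN.

## Synthetic cohorts

The generator emulates the study design, not the physics of fMRI: groups of
45 FES / 41 GHR / 48 HC subjects; FES symptom scores ~ N(22.24, 6.86²)
clipped to [7, 49], the valid range of a 7-item 1–7 subscale; age,
education, mean FD and male proportion drawn per group from the published
summaries (FD floored at 0.001 mm since it is non-negative); edges are
independent N(0, noise_sd²) in Fisher-z units with baseline 0 — only
relative structure matters to a per-edge correlation screen.

A planted positive (negative) signal edge for an FES subject with
standardized score z gets `± effect_size · z` added, giving a per-edge
population edge–score correlation `ρ = effect_size/√(effect_size² +
noise_sd²)`. Defaults: 10 + 10 planted edges, noise_sd = 0.3 Fisher-z,
effect_size = 0.15 (ρ ≈ 0.45). The effect size is the one free quantity the
source analysis does not report; it is calibrated so that at the package's
evaluation scale (60 nodes, 45 FES subjects) the mean LOOCV accuracy over
seeds falls inside the 0.3–0.7 band around the reported accuracy of 0.47
while the permutation test remains significant in ≥ 90% of replicates — a
weaker coupling keeps the accuracy lower but lets too many replicates miss
significance, so the calibration is pinned by the significance requirement. FES
subjects additionally receive an additive shift (default −0.12 Fisher-z) on
every edge of one designated subnetwork pair (default CT–SH,
cingulo-opercular to somatomotor-hand), sized so the group strength gap over
a typical pair matches the published order of magnitude.

Randomness uses named substreams of one master `SeedSequence`: edge
placement (key 0), partition (key 1) and per-subject draws (key (2, group,
index)), so enlarging any group never reshuffles existing subjects' draws.

What the generator does **not** emulate: BOLD time series, spatial
autocorrelation between edges, distance or module structure in the
connectome background, head-motion artifacts, or score–covariate
correlations. Passing tests therefore demonstrate that the estimation
machinery is correct and calibrated under the assumed generative model, not
that the effect sizes or networks of any real cohort are recoverable.

## Problem sizes and numerical choices

- Pearson r is clipped to |r| ≤ 1 − 1e−7 before `atanh`, keeping all edge
  weights finite.
- Screening p-values use `scipy.special.stdtr`; OLS uses `numpy.linalg.lstsq`
  (minimum-norm; designs here are full rank after constant-feature drops).
- The simulation-based checks run at reduced scale chosen to keep the full
  statistical structure while remaining quick on one core: planted-effect
  recovery at 60 nodes × 45 subjects × 20 seeds × 200 permutations, and null
  calibration at 20 nodes × 20 subjects × 100 replicates × 200 permutations.
  Fold counts and matrix-scale behavior are checked at the full 264-node
  scale, where one LOOCV takes about a second.
- Text serialization is at 12 significant digits; reports contain no
  timestamps, so a rerun with the same seed is byte-identical.

## Known limitations

- No external-cohort validation mode (the motivating analysis itself had
  none) and no k-fold variant; cross-validation is leave-one-out only.
- No covariate adjustment inside CPM itself; covariates enter only the group
  comparisons, mirroring the source analysis.
- The permutation test re-runs LOOCV in full per permutation; at 264 nodes
  with 10,000 permutations this is hours of compute, which is inherent to
  the procedure rather than to this implementation.
- The Dunnett T3 contrast uses the studentized-range reference rather than
  the studentized maximum modulus; for k = 3 groups the difference is
  slight and conservative in the cases checked.
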