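# Methods

## The analysis model

Nest-mark chemistry is treated as compositional: a sample is characterized
by the relative proportions of its compounds, never by absolute peak
areas. Two normalizations enforce this before any statistics:

* **Quantile normalization** (sort / mean-of-order-statistics / reassign)
  forces every sample onto one common value distribution, removing
  non-linear per-sample intensity bias (body size, extraction volume,
  injection efficiency). Ties within a sample receive the mean of the
  reference values at the tied ranks. The transform is idempotent on
  tie-free data; with exact ties a second application can shift values
  marginally because tie-averaging perturbs the pooled reference.
* **Centered log-ratio (clr)**: `clr(y)_i = ln y_i − mean_k ln y_k` per
  sample. Rows sum to zero and the transform is invariant under per-sample
  positive rescaling, so any residual intensity factor is annihilated. clr
  requires strict positivity; the pipeline guarantees it by substance
  filtering (presence above threshold in every analysis sample), never by
  pseudo-counts.

The fixed stage order is **filter → quantile normalize → clr**: filtering
establishes the positivity clr needs, and normalization must see the raw
(untransformed) areas. The background screen drops a compound when its
mean area over control sleeves/blanks reaches its mean over analysis
samples; this operationalizes the ambient-contamination control, with the
comparison logged per compound. Normalization is applied jointly over all
samples of the comparison at hand (marks only, or marks plus extracts);
joint scope is the default because cross-source comparisons need a common
reference distribution.

Discrimination then proceeds through correlation-matrix PCA (retain all
eigenvalues strictly > 1; standardized component scores, which for a
full-rank correlation PCA coincide with regression-estimator factor
scores; loading signs fixed so the dominant entry is positive), squared
Euclidean distances between score vectors, Q3 + 3·IQR pruning of extreme
isolated values (type-7 quartiles), and a binomial-logit GLM of the pair
label on SED fitted by IRLS. The Wald chi-square `W = (β₁/se₁)²` with a
1-df chi-square p-value is the reported test. Complete separation is
detected before fitting and refused with a diagnostic rather than reported
as a finite W.

Source attribution operates on quantile-normalized samples rescaled to a
common total within the compound universe (compounds present in marks):

* **Kovats band**: OLS of ln(mark mean / gland mean) on the Kovats index
  over compounds with positive gland means; compounds whose externally
  studentized (jackknife) residual exceeds `band_k` (default 2) in
  magnitude are treated as foreign-enriched. External studentization is
  used because internally studentized residuals are bounded by √df and
  saturate on small panels, making the verdict at the default threshold
  degenerate.
* **Exogenous filter**: discard when mark mean / (head mean + gland mean)
  strictly exceeds 2 ("more than two-fold"); compounds with no bee source
  at all are discarded with an explicit reason.
* **Contribution factors**: with r = max(head, gland)/min(head, gland),
  r ≤ 2 assigns (1, 1) — both normalized sources summed; larger r assigns
  the dominant source alone. The proportionality weights behind the (1, 1)
  convention are an open design choice; 1:1 summation of the normalized
  sources is the simplest reading and is what the bouquet estimator uses.
  The full ratio distribution is exported for inspection.

Heatmaps cluster samples and compounds by UPGMA (average linkage) on
Euclidean distances over the normalized clr values; merge heights equal
the average pairwise distance between merged clusters (the hclust/SciPy
convention). Dendrograms are sorted smallest-subtree-first (ties broken by
smallest leaf index), a deterministic convention chosen from the several
the R dendsort package offers.

## The synthetic-data generator

The generator emulates the sampling design — `n_bees = 25` females, two
sequential entrance sleeves each, one head and one Dufour's gland extract,
plus 3 passively exposed control sleeves — over a 59-compound panel whose
class compositions match the measured source chemistry: gland secretion
dominated by alkenes (78.7%, mostly 7-positional) with 19.1% alkanes and
minor alcohols/esters; head/cuticular extract 60.0% alkenes / 37.1%
alkanes; marks 44.7% alkanes, 39.8% alkenes, 9.1% aldehydes, 0.5% esters.
Kovats indices follow the n-alkane convention (100·chain length), alkenes
eluting slightly earlier and aldehydes/alcohols/branched alkanes slightly
later than the same-chain alkane.

All variation is multiplicative (mean-one log-normal), since peak areas
are positive and span about five orders of magnitude:

| parameter | default | meaning |
|---|---|---|
| `sigma_individual` | 0.70 | per-bee, per-compound deviation of the gland and head profiles — the individual signature |
| `sigma_drift` | 0.25 | per-sleeve temporal drift of a mark away from the bee's latent tag |
| `sigma_noise` | 0.10 | per-cell measurement noise |
| `sigma_intensity` | 0.50 | per-sample scalar intensity factor (body size / yield), the bias quantile normalization removes |
| `mix_gland`, `mix_cuticle`, `env_enrichment` | 0.32, 0.244, 0.436 | source weights of a mark |
| `env_control_factor` | 0.5 | environment level on control sleeves relative to marks |

Design choices worth noting:

* **Mixing weights** were solved once from the class compositions so the
  expected mark composition reproduces the measured mark percentages given
  the gland and head compositions; the environment source (67.7% alkanes,
  20.7% aldehydes, the rest branched alkanes/alcohols/esters) is the
  unique non-negative completion of that linear system. Six even-chain
  aldehydes occur only in the environment — nest-entrance-only compounds
  with no bee source.
* **Per-sleeve drift.** Each sleeve carries its own independent drift
  factor, because sleeves are deposited and collected at different times.
  This also makes the same/different pair labels exchangeable when
  `sigma_individual = 0`, the regime the type-I control property assumes.
* **Mean-one perturbations** (`exp(N(0,σ²) − σ²/2)`) keep expected
  compositions at their configured targets; plain log-normal factors would
  inflate the bee-derived share of a mark relative to the constant
  environmental term.
* **Signal calibration.** `sigma_drift` has no measured counterpart and is
  a free parameter. The pair (`sigma_individual`, `sigma_drift`) was
  calibrated once so that the same-nest/different-nest median SED ratio of
  the full pipeline is ≈ 0.5, the regime reported for real marks; the
  resulting Wald statistics on synthetic data (W ≈ 40–80) are larger than
  on real data because the generator omits compound-specific exogenous
  variation between sleeves (flower visits, nest-material differences)
  that blurs real tags. For the same reason nearly all synthetic nests
  have their two sleeves adjacent in the UPGMA leaf order, whereas real
  tags cluster together only rarely. Passing tests therefore show the
  pipeline recovers the structure the generator encodes, not that real
  data are this clean.
* **Control sleeves** carry the environment profile at half the mark-level
  enrichment (`env_control_factor = 0.5`): marks accumulate exogenous
  material through bee traffic, passively exposed controls less so. With
  equal levels the background screen would remove the nest-entrance-only
  aldehydes that the analysis is known to retain.

## Numerical choices and degenerate inputs

* clr errors on any value ≤ 0, naming the cell; quantile normalization
  requires ≥ 2 samples; PCA requires ≥ 3 samples, ≥ 2 compounds and no
  constant column (named in the error). If no eigenvalue exceeds 1 the
  largest component is kept with a warning.
* The Kovats band needs ≥ 3 compounds with positive gland and mark means;
  with an exactly collinear quotient line (residual SD < 1e-12) every
  candidate is retained.
* Strict inequalities at both attribution thresholds: discard iff
  enrichment > 2; proportional iff r ≤ 2.
* GLM: IRLS to tight tolerance (`tol = 1e-12`, ≤ 200 iterations); complete
  separation and single-class inputs raise typed errors.
* All simulation randomness flows from one `numpy` generator seeded by the
  config; identical config ⇒ bit-identical datasets, and the pipeline
  writes every numerical artifact with fixed float formatting so reruns
  are byte-identical.
* A single-bee dataset makes every present compound "private" to that bee
  by definition; the screen documents rather than forbids this.

## Known limitations

* **The pairwise GLM is conservative under the null.** All C(2n, 2) SEDs
  derive from only 2n samples, so pairs are dependent: a sample-level
  fluctuation moves its same-nest pair and all its cross-nest pairs
  together, and the label/SED contrast partially cancels. Over 300 null
  replicates (`sigma_individual = 0`) the empirical sampling SD of the GLM
  slope is ≈ 0.70 of the model-based SE, giving a rejection rate of
  ≈ 0.5–1% at nominal α = 0.05 instead of 5%. Type-I error is therefore
  controlled but not calibrated; this is a property of regressing pair
  labels on pairwise distances, not of the fitting code, whose Wald
  statistic matches an independent Newton–Raphson oracle on independent
  toy data to 1e-6.
* The generator does not simulate raw chromatograms, co-elution,
  retention-time alignment, or compound-specific environmental variation
  between sleeves; peak detection and integration are upstream of this
  package.
* The band screen, enrichment threshold and contribution-factor rule use
  population means across bees; per-bee attribution variation is not
  modelled.
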