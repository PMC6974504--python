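# Methods

`latentlens` implements two projection-based classifiers for two-class
metabolomics peak tables — PLS-DA and a single-hidden-layer feed-forward
neural network — inside one shared workflow of cleaning, stratified
splitting, scaling, imputation, cross-validated hyperparameter selection,
permutation testing, bootstrap resampling with BCa confidence intervals,
and per-metabolite contribution metrics. This note records the models, the
defaults and the numerical decisions.

## Models

**PLS-DA (SIMPLS).** With X the N×M scaled concentration matrix and y the
binary class vector (case = 1), the model finds K weight vectors W such
that the scores T = XW maximise covariance with y, predicts ŷ = TC′ = XB
with B = WC′, and is fitted by the SIMPLS recursion on the successively
deflated cross-covariance X′y. Implementation details:

- y is mean-centred internally; X is expected column-scaled (the
  preprocessing module guarantees this). Predictions are continuous scores;
  thresholding happens only inside confusion-based metrics.
- Scores are normalised to unit length, which makes T orthonormal and
  lets the per-component explained sum of squares of y be read off as c_k².
- Each latent variable is oriented so its y-weight c_k is positive. The
  (w_k, c_k) pair is only defined up to a joint sign; the convention makes
  scores plots reproducible and leaves B unchanged.
- The deflation basis is re-orthogonalised explicitly at every step, so
  score orthogonality holds to ~1e-14 even at K close to the rank of X.
  A vanishing residual covariance raises an error suggesting a smaller K.

**Neural network.** Two layers, K hidden neurons, logistic activations in
both layers (a linear mode exists for the regression-equivalence checks).
Hidden pre-activations t_j = w_0j + x′w_j are the "neuron scores" used for
projection plots — the direct analogue of PLS latent-variable scores.
Training is full-batch gradient descent with classical momentum and
learning-rate decay lr_t = lr/(1 + decay·epoch):

- Hyperparameters: K and the learning rate are the tuned pair; momentum
  0.5, decay 0 and 400 epochs are fixed working values that the grid search
  never varies.
- Loss is binary cross-entropy by default (canonical pairing with a
  logistic output); mean squared error is available for the linear framing.
- Weights initialise uniformly in ±√(6/(fan_in+fan_out)) from a seeded
  generator; fits are bit-reproducible given the seed.
- After training, neurons are sorted by descending |c_j| and flipped so
  c_j ≥ 0, using the exact logistic symmetry σ(−z) = 1 − σ(z) (the output
  offset absorbs the flip), so the canonical form predicts identically.
- The analytic back-propagation gradient is verified against central
  finite differences in the test suite (1e-5 relative).

**Structural equivalence.** With linear activations the network composes to
a multiple linear regression with coefficients W1·c; trained to convergence
it reproduces the least-squares fit to machine precision, which anchors the
interpretation of CWA below.

## Contribution metrics

- **B** — the PLS regression coefficients W C′ (signed).
- **VIP** — √(M · Σ_k w²_ik SSY_k / SSY_cum) with unit-normalised weight
  columns and SSY_k = c_k², the y sum of squares explained by component k.
  This normalisation makes ΣVIP² = M an identity, so an averagely
  contributing variable scores exactly 1 (the conventional cut-off). Which
  SSY definition the metric should use is genuinely open; per-component
  explained variance is the choice that forces the identity.
- **CWA** — Σ_j c_j w_ij (signed), the network analogue of B; exact for a
  linear network by the composition above.
- **Garson** — Σ_j |w_ij c_j| / Σ_i |w_ij c_j|, non-negative, summing
  exactly to K; its mean K/M serves as the importance cut-off (0.038 for
  the canonical 52-metabolite, 2-neuron configuration). A hidden neuron
  with all-zero input weights makes the normalisation undefined and raises.
- Significance: signed metrics when the bootstrap 95% CI excludes zero;
  VIP when the CI lower bound exceeds 1; Garson when it exceeds K/M.

## Preprocessing

Fixed order: QC filter → stratified split → log/centre/scale → impute.
The filter keeps metabolites with QC RSD < 20% and missing fraction < 10%
(strict comparisons); tables without QC metadata skip the filter with a
warning. The split is stratified (default 2:1) with per-class rounded
allocation. Scaling is natural log, mean-centre, unit variance, with means
and SDs estimated on the training rows only and applied unchanged to the
test rows — permuting or replacing test rows cannot change the parameters.
Imputation is k-nearest-neighbour (k = 3 by default, a small-cohort-safe
standard choice; distances are Euclidean over mutually observed features
with missing-dimension rescaling) and runs after scaling so distances are
not dominated by high-abundance metabolites.

## Validation

R² = 1 − SS_res/SS_tot on the training fit and Q² = 1 − PRESS/SS_tot on
out-of-fold predictions, both against the raw {0,1} outcome (the scale of
y for these statistics is a convention; {0,1} is used and recorded). AUC
is the rank statistic (ties half-counted), reported for the full fit and
the pooled CV predictions. Cross-validation is stratified 5-fold repeated
over 10 Monte-Carlo repartitions; all grid combinations and both model
families see identical partitions and per-fold seeds, so comparisons are
paired. Hyperparameters are chosen on the |R²−Q²| vs Q² plane: along the
non-dominated frontier the convex hull's slope (Q² gained per unit of
overfit gap) decreases, and the selected point is the interior hull vertex
with the largest slope drop — a discrete stand-in for what is, in
practice, a visual judgement, so the full hull and coordinates are always
returned for manual override. Degenerate hulls fall back to the maximum-Q²
point with a warning. The permutation test refits the fixed configuration
on label-permuted data (n = 100, 5-fold CV) and reports add-one-corrected
empirical p-values, so the smallest attainable p is 1/101.

## Bootstrap inference

The fixed configuration is refitted on r = 100 resamples drawn with
replacement; each resample's unseen samples (on average (1−1/N)^N ≈ 37%,
the familiar "about one third") provide out-of-bag predictions. Latent
variables / neurons of every resampled model are sign- and
permutation-matched to the full-data reference model by maximal absolute
correlation of weight vectors (for the network the matching flip is
function-preserving). Aggregate per-sample scores average over the
resamples where the sample was in-bag (respectively out-of-bag); a sample
never out-of-bag is flagged and excluded from ellipse fitting. Scores
plots carry two ellipses per class: χ²(2)-scaled covariance (95% of the
population) and the same divided by n (95% region of the mean).

**BCa intervals.** z₀ comes from the replicate fraction below the observed
statistic, acceleration a from jackknife skewness, and the adjusted
percentiles are mapped through the replicate distribution with the Hazen
quantile. Centring choices, which matter in practice:

- In-bag AUC: observed = the full-data model's apparent AUC, acceleration
  from leave-one-sample-out AUC jackknifing (no refits needed).
- Out-of-bag AUC: no full-data out-of-sample statistic exists, and using
  the apparent AUC demonstrably drags the interval above chance on pure
  noise; the interval is therefore centred on the replicate median
  (z₀ ≈ 0, near-percentile).
- Contribution metrics: observed = the reference model's metric, a = 0
  (leave-one-out refits for every metabolite are deliberately avoided);
  `method="percentile"` is available. On null features percentile
  intervals are close to nominal (~98% cross zero) while the
  bias-corrected default trades some null coverage (~83% at r = 100) for
  power — both behaviours are pinned in the test suite.

## Synthetic data

The generator draws log-concentrations as baseline + low-rank factor term
(rank 2 by default, loading SD 0.7) + independent noise (SD 1), shifts a
chosen subset of metabolites by `effect_size` marginal log-SDs in the case
class, and exponentiates, so concentrations are strictly positive and
log-safe. Defaults — 50 samples per class, 52 metabolites, 5 informative
at 2 SD — describe a moderately powered single-cohort study of the size
the workflow targets. Missingness is off by default; MCAR and a
left-censoring mode (abundance-dependent loss) are available, and QC RSD
values are drawn uniformly from (2, 15)%. What the generator does *not*
emulate: batch effects, retention-time drift, heteroscedastic QC error,
non-MCAR missingness beyond simple censoring, and realistic blocky
correlation beyond a low-rank factor structure. Passing tests therefore
demonstrate internal correctness and statistical behaviour under a clean
generative model, not performance on any particular real cohort.

## Problem sizes and numerics

The test suite and the acceptance script run the full machinery at the
generator's native scale (100 samples × 52 metabolites, r = 100
bootstraps, 100 permutations, 5-fold × 10 repartitions), which completes
in well under a minute per replicate; multi-seed properties use 5
independent generator seeds with majority voting to be sampling-error
tolerant. Tolerances: SIMPLS invariants at 1e-8 relative or better,
gradient checks at 1e-5 relative, closed-form identities (ΣVIP² = M,
ΣGA = K) at 1e-8–1e-12. CSV round-trips are bit-exact
(`float_precision="round_trip"`); XLSX round-trips are limited to 15
significant digits by the Excel number format itself.

## Known limitations

- Binary outcomes only; no multi-class Y, sparse/orthogonalised PLS
  variants, deeper networks, regularisation or early stopping.
- BCa undercoverage for contribution metrics at r = 100 (above); raise r
  or use percentile intervals when null calibration matters more than
  power.
- The hull-inflection selector encodes one reasonable reading of a visual
  procedure; always inspect the returned diagnostics.
- Imputation quality degrades when missingness is abundance-dependent;
  the censoring generator mode exists precisely to probe this.
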