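# Methods

## Model

The core model is PLS1 regression of an activity vector y (pIC50,
−log₁₀ of the molar IC50) on an autoscaled descriptor matrix X
(column-wise mean-centred, scaled to unit *sample* variance, n−1
denominator throughout — the convention of mainstream chemometrics
software). The response is mean-centred; unit-variance scaling of y is
available but changes nothing observable (predictions and standardized
coefficients are invariant), so it is off by default.

For a single response the NIPALS algorithm needs no iteration: the weight
vector of component *a* is the normalised X′y of the (a−1)-times deflated
matrix. The fit is therefore exactly deterministic; there is no random
initialisation anywhere in the fitting path. The regression vector in
scaled coordinates is b = W(P′W)⁻¹q, and raw-unit coefficients and the
intercept follow by undoing the scaling. Standardized coefficients are
b_std,j = b_raw,j·sd(x_j)/sd(y); a descriptor is flagged significant when
|b_std| is at least half the largest |b_std| (the half-maximum rule of
thumb). Per-LV explained X-variance is the Frobenius share of the rank-one
reconstruction t_a p_a′ in the autoscaled X.

Requesting more components than the informative rank of X raises an error
rather than returning silently degenerate loadings.

## Preprocessing

Cleaning removes columns with missing values, zero variance, or a modal
value occupying more than a configurable fraction of the compounds
(default 0.95 — no standard definition of "quasi-invariant" exists, so the
threshold is explicit and configurable). The activity-correlation prefilter
keeps descriptors with |Pearson r(x_j, y)| ≥ 0.3 against the full data
set's response; the boundary is inclusive (only strictly lower correlations
are eliminated). Filtering against the full response before splitting
mirrors common QSAR practice but is a mild form of information leakage;
the report object records the threshold and every |r| so the choice is
auditable.

## Ordered predictors selection

Descriptors are ranked by the absolute value of an informative vector —
the correlation vector, the standardized regression vector of a pilot PLS
fit with max(lv_range) components, or their element-wise product — and
nested subsets of increasing size are evaluated by leave-one-out Q² (or
SEV; at fixed n both are monotone in PRESS, so they rank trials
identically) at every candidate LV count. Defaults: window = largest
candidate LV count, increment 1, max_subset = min(m, 30), lv_range
1..min(8, n−2). Ties break towards parsimony: smaller subset, then fewer
LVs, then lexicographic names — which also makes the search fully
deterministic. Cross-validation inside the scan re-autoscales within each
fold by default; a fixed-scaling mode (scale once on the full data)
mimics tools that preprocess before CV.

Because the ranking and the Q²-maximising scan both see all n compounds,
the selected model's Q² is optimistically biased — the classic
selection-outside-CV leak. This is inherent to the procedure being
modelled, not an implementation artifact; the synthetic experiments below
quantify it.

## Validation battery

* R² = 1 − RSS/SSy, SEC = √(RSS/(n−p−1)) with p the number of LVs,
  F = (R²/p)/((1−R²)/(n−p−1)) against the upper-0.05 quantile of
  F(p, n−p−1). A perfect fit reports F = ∞ with an overflow flag.
* Q² = 1 − PRESS/SSy, SEV = √(PRESS/n). Q² may be negative — that means
  the model predicts worse than the training mean.
* Leave-N-out jointly permutes rows of X and y (seeded generator),
  partitions into consecutive blocks of size N (last block smaller), and
  leaves each block out once. The denominator is the SSy of the full,
  unpermuted response, keeping Q²(N=1) exactly equal to the leave-one-out
  Q² regardless of the permutation. Default six replicates per N.
* y-randomization scrambles the response (identity permutations are not
  resampled, keeping the null exact), refits on the *fixed* descriptor
  subset at fixed LV count, and records |r(y_perm, y)|, R² and Q² per
  scramble. Two least-squares lines through the (|r|, R²) and (|r|, Q²)
  points — anchored by the original model at |r| = 1 — must have
  intercepts below 0.3 and 0.05. The anchor is a config flag.

## External validation

R²pred = 1 − PRESS_test/Σ(obs − ȳ_train)² uses the **training-set mean**
in the denominator; on the packaged reference tables this convention
reproduces the published 0.641 while a test-mean variant does not, which
settles a genuine ambiguity in the literature. The through-origin battery
is oriented observed-on-predicted for k and R²₀ and predicted-on-observed
for k′ and R′²₀; this orientation reproduces the published
|R²₀ − R′²₀| = 0.004. Thresholds: R²pred > 0.5, k and k′ in [0.85, 1.15],
|R²₀ − R′²₀| < 0.3. Through-origin slopes are only meaningful for
activities on a positive scale well away from zero (true for pIC50 data).

The HCA split clusters the autoscaled descriptor matrix (Euclidean
distance; complete linkage by default, others available) and draws one
test compound per activity-quantile stratum, preferring unused clusters
and never taking the global activity minimum or maximum (those anchor the
training range). The published split was manual; it ships as a fixed-list
fixture, and the HCA heuristic is a reproducible stand-in.

## Outlier diagnostics

Leverage h_i = 1/n + t_i′(T′T)⁻¹t_i in latent-variable space (Σh = A+1),
internally studentized residuals e_i/(SEC·√(1−h_i)), default cutoffs
h* = 3(A+1)/n and 2.5σ. Flags never remove compounds.

## Synthetic data

The generator emulates what a real descriptor matrix looks like to this
pipeline:

* **Planted block.** k_true = 6 columns load (weight 1) on 3 latent
  factors, two columns per factor, the factors equicorrelated at 0.5, plus
  a per-column unique part (sd 1.0). The response is exactly linear in the
  planted columns plus Gaussian noise. The factor correlation and
  same-sign coefficients keep every planted column's marginal |r| with y
  around 0.5–0.6, safely above the 0.3 prefilter, while the unique parts
  make each column individually necessary.
* **Decoy families.** 45 decoys shadow the latent factors (round-robin) at
  population correlation ≈ 0.55 — correlated relatives that carry the
  shared structure but none of the column-specific signal. Decoys of one
  family share an extra noise factor (descriptor variants of one property
  co-vary beyond their common cause).
* **Irrelevant descriptors.** The remaining 388 columns come in strongly
  correlated blocks (within-block ρ = 0.97, block size 80), mimicking the
  heavy redundancy of descriptor software output. This matters: hundreds
  of *independent* noise columns at n = 31 would flood the prefilter with
  chance correlations and let the selection scan mine them, which real
  (redundant) descriptor sets do far less.
* Every column gets a random location and scale so autoscaling does real
  work; the response is located at 7.2 with spread ≈ 0.56 log units, the
  scale of a typical pIC50 series.

The noise level of the `paperlike` preset is set by bisection on the
analytic expected OLS R² of the planted columns,
E[R²] ≈ 1 − (1−ρ²)(n−1−k)/(n−1) with ρ² the population variance ratio;
the preset targets 0.80, placing the full pipeline's selected-model Q²
distribution inside the 0.5–0.8 band typical of validated QSAR models.

**Experiment design.** The study-regime experiments scan LV counts 1–3
(the planted latent rank) with an initial subset size of 6 (the planted
model size) and subsets up to 30 descriptors. Across seeds, the pipeline
keeps ≥5 of the 6 planted descriptors in ~85% of runs and its Q²(LOO)
falls within [0.5, 0.8] in ~80% of runs; the residual spread is dominated
by genuine sampling variability at n = 31 (the Q² of even the *true* model
has a standard deviation near 0.1) plus the selection-leak inflation noted
above. Scrambled-response refits on the true model give Q² ≤ 0 in ~96% of
cases; the exceptions are mostly permutations that happen to retain
|r(y_perm, y)| ≳ 0.4 — i.e. nulls that did not fully destroy the signal —
plus ordinary LOO noise around a negative mean.

**What passing these tests does not show.** The generator is Gaussian,
linear and homoscedastic; real descriptor/activity relationships are none
of these, real descriptor distributions are skewed and discrete, and real
assay error is not iid. Recovery and calibration results on synthetic data
validate the machinery, not the chemistry.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviations everywhere.
* Zero-variance columns: error naming the column (autoscaling), removal
  (cleaning), r = 0 (correlation filter).
* Zero-variance response, length mismatches, infeasible LV counts, unit
  leverages and zero HOMO–LUMO gaps raise ValueError with the degenerate
  quantity named.
* Display rounding of pIC50 is 3 decimals, half-away-from-zero, matching
  printed tables; internal values are never rounded.
* F critical values come from scipy's F quantile; the test suite
  cross-checks them against an independent quantile routine.
* IC50 units are nanomolar in the packaged data; the conversion helper
  accepts µM, mM and M.

## Known limitations

* The prefilter and OPS ranking see the full data set (fidelity to the
  modelled procedure); a leakage-safe variant that filters inside folds is
  not the default.
* The HCA split is a heuristic; with pathological geometry it may not
  achieve one compound per cluster and falls back to stratum sampling.
* y-randomization refits do not redo variable selection (the scramble is
  applied to the final model); re-running selection under scrambled
  responses would give a more conservative null at far higher cost.
* The published descriptor values for the reference compounds are not
  distributed with the package, so the published model's own R²/Q² cannot
  be recomputed from first principles; the packaged statistic blocks are
  instead checked for internal algebraic consistency, and all conclusions
  about the machinery rest on the synthetic ground truth.
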