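# Methods

This note records the models, algorithmic conventions and design choices
behind `irivsca`, and what the synthetic test bed does and does not
establish about real soil spectra.

## Data model

A `SpectrumSet` holds a strictly increasing wavelength grid (nm), an
(n_samples × n_bands) reflectance matrix in [0, 1], unique sample ids and an
optional per-sample target (concentration, µg/g). Wavelength labels are
decimal nm and matched exactly (field instruments have non-integer centers
such as 619.6 nm); nothing is ever rounded to match bands. CSV is the only
on-disk format. Edge trimming keeps the closed interval [400, 2399] nm by
default, which reduces a 2151-band 1 nm grid to exactly 2000 modelling
variables — the convention the rest of the workflow assumes.

## IRIV

**Design matrices.** Each screening round draws a balanced binary matrix
`A` (`n_rows` × p): every column contains exactly `n_rows/2` ones,
independently permuted per column. The complement `B = 1 − A` is evaluated
too, so each round costs `2·n_rows` PLS cross-validations regardless of p.
`n_rows` defaults to 500 (the literature on this selector family does not
fix a value; 500 keeps sub-model sampling dense at desk-scale runtime).
The matrix is redrawn every round from the run's seeded RNG stream.

**Sub-model scoring.** RMSECV is the pooled root-mean-square error of
5-fold cross-validated PLS predictions with at most
`min(10, n_included, n_train − 1)` latent factors. One fold partition is
drawn per IRIV run (seeded) and reused by every sub-model and by backward
elimination, so all RMSECV values within a run are comparable. A sub-model
that includes no variables cannot predict and scores +inf; such entries are
dropped from the φ pools (otherwise a single empty row of `A` at small p
would poison every mean).

The inner loop uses a minimal univariate SIMPLS implementation (`_pls.py`).
For a single response SIMPLS spans the same Krylov subspace as NIPALS PLS1,
and the test suite verifies agreement with scikit-learn's `PLSRegression`
to ~1e-8; the user-facing PLSR regressor in the benchmark harness remains
scikit-learn's. The custom kernel exists because the screen evaluates ~10⁴
small PLS fits per run and per-fit overhead dominates otherwise.

**Variable typing.** For band i, φ0 pools the RMSECV values of all
sub-models (rows of A and of B) that include i, φi those that exclude it;
`DMEAN_i = mean(φ0) − mean(φi)`, and p_i comes from a two-sided
Mann–Whitney U test (exact for small untied samples, normal approximation
with tie correction otherwise; two identical pools short-circuit to p = 1).
Typing follows the four-quadrant rule (strong / weak / uninformative /
interfering); `DMEAN = 0` carries no evidence of benefit and is typed
uninformative. Strong + weak are retained; the round loop stops when no
uninformative/interfering variables remain, when fewer than two variables
survive (a single band cannot be contrasted against its own exclusion), or
at the `max_rounds = 20` safety cap.

**Backward elimination.** Greedily removes the variable whose exclusion
yields the minimum RMSECV while that minimum does not exceed the current
RMSECV. The comparison carries a 1e-9 relative tolerance so exact
redundancies (duplicated columns, whose removal changes the fit only at
rounding level) are eliminated instead of kept; ties break toward the lowest
variable index for cross-platform determinism.

## GF / FD / GFA cascade

The cascade runs on the IRIV-retained band set. Two conventions matter:

* **FD pairs are consecutive retained bands** — feature
  `FD_λb–λa = (v(λb) − v(λa)) / (λb − λa)` for adjacent retained λa < λb.
  This matches the conventional pair-label format (e.g. `GFA_849–769` from
  a retained set containing 769 and 849 nm) and cancels per-sample additive
  baseline offsets exactly.
* **GF scope.** By default the Gaussian filter smooths over the
  retained-band *sequence* (σ in retained-index units). The pipeline instead
  passes the full trimmed spectrum (`full=` argument), in which case each
  retained band is smoothed over its *grid* neighbours (σ in grid-index
  units). The distinction is substantive: sequence-only smoothing is a
  linear map of the retained bands and can add no information, whereas
  grid-neighbour smoothing averages independent band noise using
  measurements outside the retained set — the only mechanism by which a
  derived feature can be genuinely cleaner than the raw band it comes from.
  With σ matched to the width of real absorption features this is a matched
  filter; σ defaults to 1.0 and is a config knob because grids differ.

Kernels are truncated at radius ⌈3σ⌉ and renormalized over in-range taps, so
edges average only observed values; constants are preserved exactly and the
operator is linear. GFA applies the same kernel over the FD pair sequence.

Standardization subtracts the calibration-set mean and divides by the
calibration-set population standard deviation, applying the same transform
to validation data; a zero-variance training column is an error naming the
feature.

## SCA screening

Every feature of every block is Spearman-correlated with the target
(average ranks for ties — identically Pearson on mean-ranked data; constant
inputs are an error, not r = 0). Features with |r| strictly greater than the
threshold (default 0.6) are retained, ordered GF → FD → GFA then by
wavelength. The selection rule for this workflow is stated in the field both as a
"top k" rule and as a 0.6 threshold; the threshold form is implemented and
k is simply the size of the result. Screening uses the full sample pool by default (matching how band-target
correlation curves are usually inspected, on all samples); callers worried
about selection leakage can screen on calibration indices only. An empty
result is returned as an explicit empty FeatureSet — the pipeline treats it
as an error rather than silently falling back.

## SPXY partitioning

Joint distance `d(i,j) = dx(i,j)/max dx + dy(i,j)/max dy` with Euclidean dx
on the feature matrix and |Δy| on the target. Selection seeds with the
globally most distant pair and repeatedly adds the sample with maximal
minimum distance to the selected set (maximin), ties toward the lowest
original index. Distances are computed on raw (unstandardized) features
because partitioning precedes scaling in the workflow. Degenerate inputs
(all samples identical) are an error. The default calibration fraction is
2/3 (42 of 63).

## Benchmark harness

Seven regressors behind one `fit_predict` surface, with fixed documented
defaults and no hyperparameter search: PLSR (≤ 10 factors, matching the
IRIV cap), BayesianRidge, Ridge (α = 1), KernelRidge (RBF, α = 0.1), SVR
(RBF, C = 100, ε = 0.05), XGBoost (300 trees, depth 3, η = 0.1, seeded) and
RandomForest (300 trees, seeded). Hyperparameters are overridable per
`ModelSpec`; unknown keys are rejected against the estimator signature.
Metrics: R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)², RMSE, MAE. Calibration metrics are
computed on the fitted training data (refit-on-all reading). Grades:
R² > 0.9 excellent; 0.82 ≤ R² ≤ 0.9 good; 0.66 ≤ R² < 0.82 approximate
quantitative; 0.5 ≤ R² < 0.66 feasible but needing improvement; < 0.5 not
quantifiable (the band edges overlap at exactly 0.9, which resolves
to "good"). A failing model is recorded in its report row, never fatal to
the grid; the per-regime best model is max Rp², ties to min RMSEp.

## Synthetic test bed

`simulate_targets` draws concentrations from a skew-normal calibrated by
moment matching to the requested mean/SD/skewness (defaults 9.28 µg/g, 1.11,
0.58 at n = 63 — the sampled-soil statistics the generator emulates);
kurtosis follows from the family and is only approximate. Draws are clipped
to mean ± 5 SD, which perturbs the moments negligibly.

`simulate_spectra` builds a smooth soil-like baseline (visible rise, broad
water dips near 1414/1914/2207 nm), adds per-sample offset and tilt, then
subtracts planted Gaussian absorptions whose depths are affine in the
standardized target — by default deeper absorption at higher concentration,
giving the negative band–target correlations typical of soil heavy metals;
per-band effect sizes may be signed. Multiplicative scatter and independent
per-band Gaussian noise complete the model; reflectance is clipped inside
(0, 1). Defaults (offset SD 0.004, scatter SD 0.005, band noise SD 0.003)
are plausible for averaged laboratory spectra.

**Pinned fixtures.** `lab-small` (63 × 200 bands @ 10 nm, five planted
bands), `field-small`, `lab-full` (2151 bands) and `field-noisy`
(63 × 1000 bands @ 2 nm). The first three use deliberately *small*
structured nuisance (offset 0.0015, scatter 0.002, band noise 0.008): a
large shared offset makes every band useful to PLS as a baseline reference,
which would invalidate reading recall/false positives against the planted
ground truth, while near-zero band noise makes the planted bands mutually
redundant so that backward elimination correctly prunes them. Band noise
0.008 against effects of 0.009–0.014 keeps each planted band individually
strong (|r| ≈ 0.8) yet complementary. Recovery is scored with a ±1-grid-step
window (absorptions have finite width; the adjacent band carries nearly the
same information).

`field-noisy` emulates field acquisition: broad (σ = 36 nm) absorption
features of both signs, heavy independent per-band noise (SD 0.035, about
3× the effect sizes) and baseline drift. Raw selected bands then correlate
weakly with the target while heavily smoothed (σ = 6 grid steps,
`FIELD_NOISY_SIGMA`) and differenced features recover the signal — the
regime in which derived-feature screening demonstrably out-predicts raw
bands. On low-noise laboratory-like fixtures the two regimes carry
essentially the same information and their best-model accuracies tie;
claiming superiority for the derived features there would be wrong, and the
test suite asserts the ordering only under field-noise conditions.

**What passing tests do not show.** The generator's absorptions are clean
Gaussians with affine depth–target links; real soil As signals are indirect
(adsorption on Fe oxides / organic matter), weaker, and confounded with
moisture, particle size and roughness. Planted-band recovery and regime
ordering on these fixtures validate the *machinery*, not field performance.

## Problem sizes and determinism

Tests run the screen at its default 500 sub-models per round on 63 × 200
(recovery, 20 regenerations) and 63 × 1000 (regime ordering, 10
regenerations) fixtures; these sizes exercise the full algorithm while
keeping a complete suite run to minutes. All randomness flows from explicit
seeds (NumPy Generator streams; seeded XGBoost/RandomForest); BLAS thread
pools are pinned to one thread in the test suite and acceptance script so
floating-point reductions are bit-reproducible across hosts.

## Known limitations

* Instrument-native formats (ASD, SVC), splice correction and reflectance
  calibration are out of scope; users export plain CSV.
* The Mann–Whitney normal approximation is used for pool sizes ≥ 8; exact
  enumeration only below that.
* The skew-normal target family cannot exceed |skewness| ≈ 0.995 and does
  not control kurtosis independently.
* The field 990-band grid uses the instrument's nominal regional sampling intervals
  (1.5 / 3.8 / 2.5 nm), padded to exactly 990 centers by deterministic
  midpoint insertion into the widest gaps; true instrument centers are not
  public.
* No hyperparameter search is performed by default; the benchmark compares
  feature regimes under fixed, documented model settings.
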