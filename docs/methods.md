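# Methods

This note documents the models, the defaults and the design decisions
behind `aqualeaf`, and what the synthetic experiments do and do not show
about real data.

## Pipeline structure

Two pretreatment paths are kept strictly separate:

* **Aquagram path**: raw absorbance → MSC → per-WAMAC z-scores. MSC runs
  before the z-score because the z-score is taken across spectra and
  would otherwise be dominated by per-spectrum scatter rather than water
  state.
* **Calibration path**: raw absorbance → Savitzky–Golay 2nd derivative →
  1300–1600 nm window → PLS. The derivative removes additive baseline and
  (to first order) multiplicative scatter, and sharpens the heavily
  overlapped water bands.

## Spectral container and I/O

Spectra live in a `SpectraSet`: an ascending wavelength grid (nm), an
`n_spectra × n_bands` absorbance matrix (log(1/R) convention) and a
per-spectrum metadata table (genotype line, plant, leaf 2–4, replicate
1–3, treatment control/stress/recovery, day, stage tag). The exchange
format is wide CSV (metadata columns, then one column per band named by
wavelength with at least three decimals, written losslessly). Grids
arriving in any order are normalised to ascending on load. Reflectance
calibration and vendor binary formats are out of scope; input is assumed
to be absorbance already.

## Savitzky–Golay derivative

Defaults: window 11 points, polynomial order 2, derivative order 2,
`per_index` scaling (derivative with respect to band index;
`per_nm` divides by step^deriv). On a ~6 nm grid an 11-point quadratic
window is a common chemometrics choice: wide enough to suppress noise,
narrow enough not to flatten the ~12–20 nm water bands. The half-window at
each edge is dropped rather than padded — padded edge derivatives are
artifacts, and all downstream analyses use interior water bands. The
filter is linear and exact for polynomials up to the configured order,
which the tests exploit as closed-form oracles. The window and order the
original desktop software would use on such data are not standardised, so
both are exposed in the configuration and echoed into the run manifest.

## Multiplicative scatter correction

Reference = mean spectrum of the set being corrected (the canonical MSC
choice when no master reference exists). Each spectrum is regressed on the
reference by ordinary least squares, `x ≈ a + b·ref`, and corrected to
`(x − a)/b`. A spectrum whose slope |b| < 1e-12 (e.g. a constant trace) is
reported by id as degenerate rather than silently amplified. A fitted
`MscModel` can be applied to new spectra on an identical grid, for
correcting prediction sets against a training reference.

## Aquagram

The 19 water matrix coordinates span 1347.899–1570.896 nm and are built in
as `default_wamacs()` with their conventional assignments (proton/ion
hydration, trapped water, free water at 1409.843 nm, one to four hydrogen
bonds, protein/cellulose-bound water). Each WAMAC is mapped to the nearest
instrument band (ties to the lower wavelength); if the nearest band is
farther than half a grid step a warning is raised and the nearest band is
used anyway.

Normalization choices, both configurable:

* σ_λ is the **sample** (n−1) standard deviation, matching common
  statistical software.
* The normalization population is **all spectra passed in** — control,
  stress and recovery together — because cross-group comparability
  requires a shared μ_λ, σ_λ. Consequently the size-weighted group means
  sum to zero at every WAMAC, and adding a constant to, or rescaling, all
  spectra leaves Aq unchanged.
* Z-scores are computed per spectrum and then averaged within groups
  (rather than z-scoring group-mean spectra); this keeps per-spectrum
  values available for the significance tests and makes group means
  consistent with them.

Aquagrams are computed separately per genotype × leaf by the pipeline,
since leaves differ systematically in absorbance magnitude.

## Group significance

Per WAMAC, per-spectrum Aq values are compared between treatment groups
with all-pairs post hoc tests, gated by Levene's test (group-mean
centring) at α = 0.05: Tukey's HSD under homogeneous variances, Dunnett's
T3 otherwise. T3 uses the Welch statistic and degrees of freedom with the
independence approximation to the studentized-maximum-modulus
distribution, `p = 1 − (2·F_t(|t|; df) − 1)^m` (m = number of pairs); with
two groups this reduces exactly to Welch's t-test, and under a simulated
global null the procedure rejects at the nominal rate (checked at 1000
replicates). Tukey HSD and the studentized range genuinely diverge from T3
at mid p-values; they agree closely wherever p ≤ 0.01, which is where
decisions are made. P-values are binned into strength bands at 0.001, 0.01
and 0.05, boundary values falling in the more significant band. The output
is an explicit (wavelength × pair) table of p-values rather than
compact-letter displays, whose assignment conventions are ambiguous.

This is a per-WAMAC univariate procedure: the tables of interest are
per-wavelength pairwise comparisons, so no true multivariate statistic is
computed, and replicate spectra of one leaf are treated as observations
(no mixed-effects correction) — both noted as limitations below.

The relative water content utility implements
RWC% = 100·(FW − DW)/(FTW − DW), clamping FW < DW to 0% with a warning
and rejecting FTW ≤ DW.

## PLS calibration and grouped cross-validation

PLS1 with NIPALS deflation, mean-centred X and y, no scaling. The
regression vector is assembled as B = W(PᵀW)⁻¹q so that
`predict(x) = ȳ + (x − x̄)·B`; with as many factors as the rank of centred
X this reproduces ordinary least squares, which serves as a test oracle
(together with an independent PLS implementation).

Cross-validation leaves out one *replicate group* — the three measurement
positions of one leaf at one measurement occasion — per fold, so no
replicate of a held-out leaf ever appears in training. Folds are ordered
by sorted group id, making the SECV curve bit-reproducible. Per factor
count a = 1…10 (default), SECV(a) = √(Σ(ŷ_cv − y)²/n); the chosen model
minimises SECV with ties broken toward fewer factors. SECV and SEC use n
in the denominator (RMSEP-style) — the legacy software's exact formula is
not published, and the choice is constant across all comparisons. R² is
reported as the squared Pearson correlation between predictions and
reference (the 1 − PRESS/SStot variant is also reported as `r2cv_press`,
since software packages differ). The calibration uses stress-treatment
spectra only: days of drought are undefined for controls, and recovery
days are on a different clock.

## Synthetic experiment generator

The generator emulates the statistical structure of a two-genotype maize
drought study; it is the test bed for every stage. Forward model per
spectrum:

```
A(λ) = b · ( baseline(λ) + (1 + δ)·Σ_k amp_k·exp(−(λ − c_k)²/(2w_k²)) ) + a + ε(λ)
```

* **Grid**: 125 bands, 908–1670 nm, snapped to the 19 WAMAC wavelengths at
  the nearest pixels so aquagram bands map exactly.
* **Bands**: water features at 930 and 1155 nm plus the 19 WAMACs, split
  into a free/weakly bound group (≤ 1422 nm, widths 12 nm, base amplitude
  0.45; the 1409.843 nm free-water band 0.55) and a strongly bound group
  (≥ 1441 nm, widths 14 nm, base 0.40). Gaussian profiles are a
  simplification (real NIR bands are asymmetric) chosen for closed-form
  oracles.
* **Drought trajectories**: under stress, free/weakly bound amplitudes
  fall and strongly bound amplitudes rise linearly after the genotype's
  onset day (sensitive: day 3; tolerant: day 7), at 0.010 absorbance/day
  for the free-water band and 0.006/day elsewhere; a sigmoidal trajectory
  is available behind a flag. Controls stay at baseline. Recovery holds
  the day-17 state (drought damage does not rebound in four days) plus a
  +0.04 contribution to bound-water bands above 1500 nm.
* **Nuisance structure**: per-spectrum scatter slope b ~ N(1, 0.03) and
  offset a ~ N(0, 0.02); iid band noise ε ~ N(0, 0.005) (instrument-level
  repeatability); per-leaf amplitude scaling δ ~ N(0, 0.05) (leaves differ
  in water-band magnitude — this survives derivatives and is the main
  nuisance latent direction); per-plant drying rate γ ~ N(1, 0.10)
  multiplying the stress progress.

The drying-rate spread is the irreducible error of the calibration: two
plants at the same calendar day are at different physiological stages.
`irreducible_day_rmse` gives its closed form — rate variance on post-onset
days plus the indistinguishability of pre-onset days — and the test suite
checks that the achieved SECV stays within [0.8, 1.5]× this floor. Its
default (0.10) was set so that the default design is calibrated to the
performance regime such studies report (about two latent factors,
cross-validated R² near 0.9, SECV of one to two days); the band
amplitudes and slopes were fixed from the qualitative drought spectroscopy
picture (largest change at the free-water band, inverse behaviour of the
bound-water region) before any test was run and not revisited.

**What passing tests show — and don't.** The synthetic experiments
demonstrate that the pipeline recovers known signal structure (sign
patterns, onset contrasts, day calibration at the designed noise level)
and never leaks replicate information across CV folds. They do not
validate instrument physics: no band asymmetry or temperature shifts, no
drift, no baseline curvature changes, no correlated (pink) noise, no
leaf-surface heterogeneity beyond an affine transform. Absolute SECV/R²
values on real spectra will differ; the machinery, not the numbers,
transfers.

## Pipeline, determinism and problem sizes

`run()` executes: simulate/load → group-mean second-derivative and
difference spectra → MSC + aquagrams per genotype × leaf → significance
tables (third leaf by default) → PLS per genotype, writing every artifact
with a CSV twin for each figure and a manifest recording the resolved
configuration, seed and package version. All randomness flows from one
seed; two runs with the same configuration produce byte-identical numeric
artifacts (figure files are not byte-compared — image metadata is owned by
the plotting library).

Default problem sizes: full experiments are 2880 spectra × 125 bands
(generated in well under a second); the calibration uses 540 stress
spectra × 49 derivative bands per genotype with 180 CV folds. Unit tests
run on a reduced design (2 plants per arm, 576 spectra); the
pattern-recovery tests use five full-size experiments with seeds 0–4; the
null-calibration check uses 1000 replicates of two groups of 30.

## Known limitations

* Replicates of one leaf are treated as independent observations in the
  significance tests; a mixed model would be more faithful to the design.
* No multiplicity correction is applied across the 19 WAMACs; the table
  reports raw pairwise p-values by design.
* The Dunnett T3 p-value uses the SMM independence approximation; it is
  calibrated at the null and conservative relative to Tukey in between.
* The aquagram normalization is population-relative: values are not
  comparable across datasets normalised separately.
* Degenerate inputs are rejected loudly rather than repaired: zero-variance
  WAMACs, constant y, MSC slopes near zero, groups smaller than two.
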