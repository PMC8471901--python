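# Methods

## Scope and data model

`aquamon` implements a longitudinal short-wave NIR (SWNIR) transmittance
monitoring workflow for plant development, together with a synthetic-data
generator that emulates the acquisition design such studies use. The
canonical design is: 2 sample types (intact germinating seeds and induced
callus) × 28 biological replicates ("seeds") × 4 probe positions × 5
consecutive scans × 12 time points (day 4 to day 26, every other day) on
a 660–960 nm grid with 1 nm step (301 channels), with one blank-air
reference scan and one dark scan per day. That design yields 13,440
sample scans, 20 spectra per seed and time point, and 2,688 rows after
consecutive-scan averaging.

Two containers carry the data: `RawScanArchive` (all raw intensities plus
per-day reference/dark vectors, and — when simulated — the generating
`GroundTruth`) and `SpectraTable` (a rows × wavelengths matrix with
per-row metadata and an append-only provenance tag list recording every
transformation in order).

## Absorbance

Raw intensities are converted per scan as `A = −log10((R − D)/(S − D))`
using the reference and dark of the scan's own day. A `ratio` mode
returning the plain dark-corrected transmittance `(R − D)/(S − D)` is
provided for instruments whose software reports that quantity; every
downstream default uses `neg_log10`, which is what chemometric practice
calls absorbance. Non-positive transmittance channels are returned as
NaN and the affected rows are flagged by the saturation screen. All
wavelength ranges are inclusive at both ends (trimming 660–960 nm to
720–955 nm keeps 236 channels).

## Synthetic generator

The forward model composes Beer–Lambert attenuation with the instrument
effects a transmittance setup exhibits:

    R(λ) = D(λ) + (S(λ) − D(λ)) · 10^(−A(λ))
    A(λ) = offset + slope·(λ − λ₀)
           + path · Σ_b amp_b · exp(−(λ − c_b)² / (2 w_b²))
           + τ · tempshape(λ) + τ/2 + ε(λ)

- `offset ~ N(0.30, 0.05)` and `slope ~ N(0, 5·10⁻⁴ AU/nm)` are drawn per
  (seed, day, position): seed size/geometry tilts and lifts the baseline.
- `path = exp(N(0, 0.10))` is a per-(seed, day) optical path-length
  multiplier scaling all bands: samples grow and sit differently day to
  day.
- `τ ~ N(0, 0.01)` per scan drives a correlated baseline shift shaped as
  Gaussians at 835 nm (width 20) and 794 nm (width 14) plus a flat τ/2
  term — the temperature sensitivity of the water bands under repeated
  light exposure.
- `ε ~ N(0, noise_sd)` with `noise_sd = 0.01 AU` is white absorbance
  noise. Noise is modeled in absorbance units (applied inside the
  exponent) so that inverting the forward model recovers the stored true
  absorbance to within `noise_sd` exactly, and the noiseless composition
  is the identity to machine precision — the property the recovery tests
  assert.
- The reference is a smooth lamp-shaped curve (peak ≈ 48,000 counts near
  800 nm) with 2% day-to-day drift; the dark is a 500-count floor with
  small channel noise. No instrument response measurements exist for
  this setup, so these are plain plausible shapes; nothing downstream
  depends on them because absorbance uses the same S and D that generated
  the data.

Band amplitudes carry the biology. All presets share one band set: the
three weakly hydrogen-bonded water bands (731, 736, 745 nm, width 5), the
five strongly hydrogen-bonded bands (752, 761, 768, 772, 775 nm, width
5), a temperature-sensitive shoulder at 794 nm, an oxidative-metabolism
band at 810 nm, a broad bulk-water band at 835 nm, and a CH third
overtone at 890 nm (growth media are sugar-rich); the 890 nm band sits
inside the 660–960 nm grid but outside the 720–780 nm analysis window,
so range-truncation logic is genuinely exercised.

**seedling_like.** Weak-bond bands dominate on days 4–14 and again on
22–26; strong-bond bands dominate on days 16–20 (off-stage bands keep 40%
of their base amplitude). The planted stage boundaries are therefore
days 16 and 22, stored in the truth. A monotone growth factor
1 + 0.06·g·(day − 4) scales the water bands and the 890 nm band, and the
810 nm band declines linearly — these give the day of development a
learnable, partly monotone signature. Three latent clusters are realized
as growth-rate multipliers g ∈ {0.8, 1.0, 1.2} plus a cluster-specific
weight (±15%) on the 761 nm band, so clusters differ in spectral shape
(surviving SNV) and not only in scale.

**callus_like.** Band amplitudes follow a shared log-scale random walk
(step sd 0.25 per time point) whose steps — and the growth factor and the
810 nm decline — freeze after day 14, emulating arrested proliferation.
The walk uses a fixed internal stream so the preset itself is
deterministic; replicate-level randomness comes from the generator seed.

**water_temperature.** A single-day design whose groups are temperature
labels (10–60 °C, 8 replicates, 3 scans): weak-band amplitudes increase
and strong-band amplitudes decrease linearly with temperature
(±1.2%/°C around 35 °C). This reproduces the classical hot/cold water
aquagram contrast used to anchor the weak/strong interpretation.

Effect sizes are not reported quantities anywhere; they were chosen once
to give absorbances of realistic magnitude (bands 0.1–0.5 AU over a
~0.3 AU baseline) with noise and nuisance effects (path ±10%, offset sd
0.05 AU) large enough that the preprocessing chain is doing real work.

Defect injection corrupts `round(fraction · n)` randomly chosen sample
scans: `saturation` boosts the scan until it clips at the detector
ceiling (65,535 counts); `misalignment` adds a 0.8–1.6 AU absorbance
offset, as a badly coupled fiber would. Labels are returned for recovery
scoring.

## Preprocessing

The default chain is Savitzky–Golay smoothing (window 31, polynomial
order 2) → SNV → linear detrend, executed in that order. SNV uses the
sample (n−1) standard deviation. Detrend subtracts each spectrum's OLS
line in wavelength, leaving every row orthogonal to [1, λ]. Second
derivatives use the same SG window/order (the window for derivatives is
exposed separately in `PreprocessConfig`); the derivative is taken with
respect to wavelength (per nm²), so downward peaks mark absorbance
maxima. SG edges are handled by a least-squares polynomial fit over the
edge window evaluated at the edge points — no reflection or constant
padding, so no data is fabricated beyond the measured range and
polynomials of degree ≤ the fit order pass through unchanged everywhere.
All operations are row-local and therefore commute with row permutation
and subsetting.

## Outlier screening

Outliers are screened per (sample type, day) group on the scores of the
first three principal components. The implemented rule flags
observations outside `median ± 1.5·IQR` — fences measured from the
*median*. The more common Tukey convention (fences from the quartiles,
`[Q1 − k·IQR, Q3 + k·IQR]`) is available via `convention="tukey"`; the
two genuinely differ (a 9-point worked sample pinning both is in the
test suite) and the median variant is the default because it matches the
workflow this package reproduces. Quartiles use linear interpolation.
Groups smaller than 4 are skipped with a warning. Removal fractions are
logged at every pipeline run; the fraction is an outcome, never a target.

PCA itself is a centered full-SVD decomposition (scikit-learn backend)
with a fixed sign convention: each loading's largest-magnitude element is
positive. Equivalence with a plain numpy SVD oracle is asserted in tests.

Pure-offset defects (the `misalignment` mode) are invisible after SNV, so
recovery of injected defects is measured on trimmed absorbance spectra
(pre-SNV): the saturation screen catches clipped scans exactly, and the
PCA boxplot on absorbance catches baseline offsets through PC1. The
orchestrated pipeline screens on preprocessed spectra by default — the
order the original workflow states — with `outlier_on="absorbance"` as a
config switch.

## PLS day regression

PLS1 with mean-centered X and y, fitted by NIPALS (scikit-learn backend;
the module derives weights, loadings and the per-LV regression-vector
path itself). Because NIPALS components nest, one maximal fit per fold
yields the coefficient path `B_k = W_k (P_kᵀ W_k)⁻¹ q_k` for every
candidate LV count — identical to refitting at each k, at a twelfth of
the cost. `n_lv = 0` degenerates to predicting the training mean.

Validation is one-seed-out: folds partition the seeds, all spectra of the
held-out seed (every day and position) leave the training set, and
centering constants are recomputed per fold. R²cv/RMSECV are computed on
the pooled held-out predictions, not as per-fold averages, matching how
single Y-fit plots are reported in chemometrics. The LV count is capped
at 12 — the number of monitored time points, a cap that guards against
overfitting while remaining meaningful for a single global model — and
further by the training-set rank; the chosen count minimizes RMSECV with
ties broken toward fewer LVs. When deflation exhausts the response
early, the last available coefficient vector is reused for larger k.

## Consensus clustering

Seeds are represented per day by their position-averaged preprocessed
spectrum (one row per seed is required for seed-level clustering). Each
day is clustered independently with Ward linkage on Euclidean distances
and the tree cut at exactly k = 3. Dendrogram labels are arbitrary per
day, so "most frequent appearance" is ill-defined without a
correspondence rule; the package aligns each day's labels to a reference
day (default: the first monitored day) by the permutation maximizing seed
overlap, ties broken toward the lexicographically smallest permutation.
This alignment step is a reconstruction — the workflow it reproduces does
not state how daily labels were matched — and is therefore deterministic
and documented here. The consensus label is the per-seed mode of the
aligned labels; ties go to the lowest label and are flagged.

## Aquagrams and stages

For each WAMAC the per-spectrum absorbances (after the full preprocessing
chain) are z-scored over the whole analyzed set (sample sd, n−1) and
averaged per group. Group-size-weighted column means are exactly zero by
construction — asserted at 1e−10. Bands are read at the nearest grid
point (exact on a 1 nm grid) and linearly interpolated on coarser grids.
The default WAMAC set is the 8-band third-overtone set: weak 731/736/745
nm, strong 752/761/768/772/775 nm.

The WAMAC channels are taken from spectra preprocessed on the full
working range (720–955 nm) and then trimmed to 720–780 nm. Running SNV/
detrend on the narrow 720–780 nm window alone distorts the pattern: with
weak bands on the left and strong bands on the right of the window, the
per-spectrum detrend line absorbs part of the weak/strong contrast and
flips the sign of edge bands (775 nm). This choice is exercised by the
temperature-reference test.

A day's hydrogen-bonding state is `weak` if mean(weak-band values) −
mean(strong-band values) > τ, `strong` if < −τ, else `mixed`; τ defaults
to 0, making `mixed` a measure-zero boundary case on continuous data.
Consecutive days with equal states merge into stages; stage boundaries
are the start days of the second and later stages. Swapping the
weak/strong labels provably flips every state. Aquagram values are not
invariant to adding a constant at a single WAMAC (z-scoring is
column-wise); they are invariant to any per-spectrum affine
transformation already absorbed by SNV upstream.

## Pipeline

`run_full` executes: simulate/ingest → absorbance → saturation screen →
scan averaging → trim (720–955 nm) → preprocess → PCA boxplot outlier
removal → per sample type: PLS on the full and the truncated (730–870
nm) range, per-day Ward clustering with consensus, and aquagram/stage
detection on 720–780 nm. Sample types are processed independently and
written to disjoint subdirectories. The manifest records the config
hash, seed, and row counts before and after every stage; identical
config + seed reproduce outputs byte-for-byte. Daily averages are
computed after outlier removal (a config switch exists because the
original workflow leaves the order unstated).

## Problem sizes and determinism in tests

Unit tests run on reduced designs (6–9 seeds, 2 positions, 2 scans);
end-to-end acceptance tests and `scripts/acceptance.py` use the full
28-seed, 4-position, 5-scan, 12-day design, with 5 generator seeds for
the stochastic regression/stage checks and 10 for label-noise consensus
recovery — sizes at which every check completes in seconds while
exercising the full design arithmetic. All randomness flows through
explicit `numpy` generator seeds; hypothesis-based property tests are
bounded and seeded by example generation only.

## Limitations

- The generator is phenomenological: Gaussian bands on a smooth baseline,
  no radiative-transfer or scattering physics, no Petri-dish/agar optics
  beyond constant terms, no detector nonlinearity short of hard clipping.
  Passing recovery tests shows the analysis chain detects the planted
  effects under realistic nuisance structure; it does not certify
  performance on real instrument data.
- Cross-validation metrics on synthetic presets are analogues, not
  reproductions, of any published values: the generating dynamics are
  stylized and their effect sizes are package choices.
- The stage classifier is a sign rule on band-mean contrasts; with τ = 0
  it will split noise-dominated trajectories into spurious short stages
  rather than report "mixed".
- Only PLS1, Ward/Euclidean/k=3, and the second derivative are provided;
  MSC/EMSC, other linkages and automatic k selection are out of scope.
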