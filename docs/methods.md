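# Methods

This note records the models implemented in `ramantissue`, the parameters
that matter, the numerical choices behind them, and what the synthetic data
does and does not establish.

## Spectra and maps

A spectrum is a strictly increasing wavenumber grid (cm⁻¹) with one
intensity per point (arbitrary units).  Raster maps hold `n_rows × n_cols`
spectra on one shared grid; the default acquisition geometry is 51 × 51
spots over 100 µm × 100 µm (2601 spectra).  All file formats are plain text
(two-column ASCII/CSV for spectra, long-format CSV for maps) written with 12
significant digits so read∘write round-trips beyond the 9-digit contract.
Grid equality uses a 1e-6 cm⁻¹ tolerance; resampling is linear interpolation
and refuses to extrapolate — callers intersect grids first (`common_grid`).

When a map is tiled into k ∈ {2, 4, 9, 16, 25} regions, perfect squares use
a √k × √k tile layout and k = 2 splits along rows only; axes that do not
divide evenly give tiles differing by at most one row/column, larger tiles
first.  This is a deterministic convention: for a 51×51 map it yields
region sizes 1326/1275 (2 divisions), 625–676 (4), and so on, close to but
not exactly the round numbers sometimes quoted for this geometry, whose
counting rule is not documented anywhere we could follow.

## Baseline removal (both chains)

Fluorescence background is removed by iterative modified polynomial
fitting, order 4 by default: fit a polynomial (Vandermonde least squares on
the grid rescaled to [−1, 1]), clip the working signal at
`fit + std(residual)`, refit, and stop when the fit moves by less than
`tol = 1e-6` of the spectrum's intensity range (`max_iter = 100`).

The noise-tolerant clip matters.  Clipping at the bare point-wise minimum —
the textbook modpoly step — makes the fit chase the *lower envelope* of the
noise and leaves a pedestal of roughly +2σ in the corrected spectrum.  At
the default noise level that pedestal sits right at the 0.1 boundary of the
threshold tables and floods the level sets with noise-floor wavenumbers
(~1100 of 1401 grid points in our measurements), destroying the match
counting.  Clipping at one residual standard deviation keeps the fit at the
noise *mean*; flat regions then correct to ≈0 and fall below the 0.1 floor
as intended.  Non-convergence raises a warning, never an exception.

On a noiseless input that is exactly a quartic the iteration is a fixed
point (the baseline equals the input), which is also why a pure-baseline
spectrum is rejected as degenerate by the normalisation step: after
subtraction there is nothing left (max ≤ 1e-8 of the raw scale).

## Smoothing (ML chain)

Smoothing is a Whittaker smoother with asymmetric weight updates: minimise
`Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²`, with `w_i = p` where the signal sits
above the current curve and `1 − p` below, re-estimated for `n_iter`
rounds.  Defaults: `λ = 100`, `p = 0.5`, `n_iter = 10`.

With `p = 0.5` the weights never change and the smoother is the plain
symmetric Whittaker filter, equivalent bandwidth ≈ λ^1/4 ≈ 3 grid steps —
comfortably below the 8 cm⁻¹ peak width, so apex positions move by at most
one grid step while pixel noise is attenuated.  Strongly asymmetric
settings (`p ≪ 0.5` with large λ) turn the same algorithm into a baseline
estimator that hugs the lower envelope and would erase the peaks this chain
must keep; they remain available through the config for callers who want
that behaviour, but they are not a sensible smoothing default.

The ML chain order is: baseline → normalise → smooth → *re-normalise* →
threshold.  The re-normalisation exists because smoothing shrinks the
global maximum slightly and the 0.3 valley cutoff is defined on a
unit-maximum spectrum.

## Threshold tables and match counting (QM)

Levels are 0.1 to 0.9 in steps of 0.1.  Each grid wavenumber is assigned to
`floor(10·I)/10` (an intensity exactly on a boundary belongs to the lower
level, so the maximum 1.0 lands in the 0.9 set); intensities below 0.1 are
noise floor and never match.  A 1e-9 slack is added before flooring so that
binary representations of e.g. 0.3 land in their intended band.  Matching
is exact grid-point identity within a level — the method defines no cm⁻¹
tolerance, so both spectra must be resampled to one grid first.

Classification takes the reference with the highest total match count.
Ties across classes are flagged and broken deterministically: larger
per-class summed count first, then the fixed order tumor, muscle, dermis,
fat.  In the blind test, spectra are split 80/20 per map with a seeded
shuffle; references are built per (patient, tissue) pair from the training
portions, each map's held-out portion is averaged into one unknown, and the
confusion matrix is rows-as-actual.  A config switch pools held-out
portions per (patient, tissue) instead of per map.

## Neural classifiers

Both networks consume 650-slot peak features.  Slots beyond the detected
peaks are zero padding; if more than 650 peaks are found the 650 strongest
are kept (ties toward lower wavenumber) and re-sorted by wavenumber.

* 1D: 650 intensities (slot = peak rank) → three hidden layers of 8
  rectified units → 4-way softmax.
* 2D: 650×2 (wavenumber, intensity) → two banks of 32 1×1-convolution
  filters applied per slot (linear maps 2→32 and 32→32 with shared weights,
  ReLU, no stride/padding/pooling) → flatten (650·32) → 512 rectified units
  → 4-way softmax.  The wavenumber channel is standardised to zero mean and
  unit variance over the training set's non-pad slots (raw cm⁻¹ values
  would dwarf unit-scale intensities); pad slots stay at zero.

Training is mini-batch Adam on softmax cross-entropy: learning rate 5e-3,
50 epochs, batch 32 by default, all configurable, weights in float32,
seeded initialisation (He) and shuffling, so identical data + seed give
bit-identical weights.  The 5e-3 rate was chosen because the very narrow
8-unit layers of the 1D network can sit on a plateau that conflates two
similar classes for well over 50 epochs at smaller rates; at 5e-3 the
plateau resolves within the default epoch budget across seeds.  Evaluation
uses a seeded split stratified by class (and optionally by map) so no class
is absent from either side at desk scale.

A note on the motivation for the 2D design: with per-patient grid offsets
of a few cm⁻¹, a model keyed to *vector position* (each recorded index one
input variable) degrades badly, which is the documented failure that
motivated adding the wavenumber channel.  Our 1D features are peak-rank
ordered rather than position-indexed, so a pure grid offset barely changes
them; the property we can and do test is therefore that the 2D model's
accuracy under session offsets stays within 10 percentage points of the
aligned case, not that the 1D model collapses.

## Metrics and fusion

Confusion matrices are rows-as-actual; published tables printed in other
orientations are imported with an explicit flag (one published network
table is only numerically consistent with its quoted sensitivity and
specificity when its rows are read as actual, whatever its caption says).
Accuracy accepts an explicit denominator for tables whose stated test-set
size differs from the printed cell sum.  Rates are proportions in [0, 1];
percent formatting (one decimal, round-half-even) happens only at the
presentation layer.

Fusion: `P = 1 − (2W_q/(W_q+W_m))(1−P_q) · (2W_m/(W_q+W_m))(1−P_m)` with
`W_q + W_m = 1 ± 1e-9` enforced.  At equal weights this is
`1 − (1−P_q)(1−P_m)`, hence monotone in each accuracy and at least
`max(P_q, P_m)`.

The feasibility curve tiles every labelled map, averages each tile's
*preprocessed* spectra (re-normalising the average), classifies the average
with both routes, and records per-division accuracy plus tumor-vs-rest
false-positive and false-negative rates.  Both methods get their own rate
columns because the probe-feasibility question is asked of each route
separately.  Division count 1 means the whole map.

## Synthetic data

Each class is a sum of Gaussian peaks (default FWHM 8 cm⁻¹) on the 400–1800
cm⁻¹ grid at 1 cm⁻¹ steps, plus a gently rising quartic baseline of
magnitude comparable to the peaks (exercising baseline removal
non-trivially), plus i.i.d. Gaussian noise (σ = 0.05 by default, the scale
being ~1 at the strongest peak).  Per-spot variation: amplitudes jittered
by 8% (fractional, clipped at zero) and centres by 1 cm⁻¹; per-patient
wavenumber grids offset by {0, +3, −2} cm⁻¹ to emulate session range drift.
All randomness flows through explicit seeds; datasets derive per-map seeds
from one root seed, so manifests and maps are byte-reproducible.

The amplitude catalogue is a documented fixture.  Real tissues are
described only qualitatively (which peaks exist, which are bigger), so the
catalogue encodes exactly those inequalities — tumor lacking 662/744/752
and 1364/1396 cm⁻¹, muscle's 1343 cm⁻¹ dominating its 1364/1396 pair, fat
weakest at 1002 cm⁻¹, tumor and muscle small at 1741 cm⁻¹, dermis extra
structure at 1650–1700 cm⁻¹ and fat at 1520–1640 cm⁻¹ — with two deliberate
construction rules: every planted amplitude is ≥ 0.45 so the 0.3 valley
filter retains all intended peaks under smoothing and jitter, and
amplitudes sit mid-way inside 0.1-wide intensity bands so the threshold
tables are robust to small amplitude wobble.  Shared-peak intensities
differ between classes, as they do in real tissue; without that the
count-based matcher would have no margin between classes whose peak sets
nest.

What passing tests on this generator shows: the pipeline's bookkeeping,
determinism and formulas are right, and the classifiers recover classes
that are separable by construction at realistic noise.  What it does not
show: performance on real tissue, where within-class heterogeneity,
overlapping bands, autofluorescence structure, cosmic-ray spikes and
instrument drift are all richer than this forward model.  Published
patient-data accuracies are therefore treated as imported worked examples,
not as numbers this package claims to reproduce from raw data.

## Problem sizes used in the shipped tests

Desk-scale versions of the study conditions keep the suite fast: raster
maps of 10–12 spots per side (100–144 spectra) instead of 51 (2601), one to
three maps per class across three synthetic patients, neural training on
400–1200 spectra with ≤ 50 epochs (6 for the 2D network, whose larger dense
layer converges in a handful of passes).  The full-size 51×51 geometry is
exercised where it is the point (raster bookkeeping, tiling arithmetic) on
short wavenumber grids.

## Known limitations

* Match counting weights every grid point equally; broad low-level wings
  contribute as much as diagnostic apexes.  The 0.1 floor mitigates but
  does not remove this.
* The 1D network's rank-ordered slots shift wholesale when a peak drops
  below threshold; classification then depends on the training set
  containing those dropout variants.
* 1×1 convolutions admit several readings on a 650×2 array; the per-slot
  channel-mixing interpretation implemented here is documented above.
* No cosmic-ray removal, no vendor file formats, no instrument control.
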