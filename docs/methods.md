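# Methods

`seedhsi` implements a complete chemometric pipeline for screening wheat
seeds by viability from two-side VIS/NIR hyperspectral line scans, together
with a synthetic-data generator that reproduces the statistical structure
of such a study so every stage can be tested without instrument data. This
note records the models, the defaults and why, the numerical choices, and
the limits of what the synthetic experiments demonstrate.

## The measurement model

A line-scan imager produces a raw count cube `I0` (rows x cols x 766 bands,
400–1000 nm). Reflectance is recovered against a white-tile scan `W` and a
dark-current frame `B`:

    I = (I0 − B) / (W − B)

clipped to [0, 1] (the instrument convention leaves out-of-range pixels
unspecified; clipping is the least surprising choice and is exact on
synthetic data). Any element with `W ≤ B` is a singular reference and is
rejected rather than silently propagated.

The first and last bands of the sensor range are noise-dominated, so
analysis uses the 688 bands in the closed interval [430, 970] nm. On the
evenly spaced 766-band grid with inclusive endpoints (spacing 600/765 nm)
that crop retains exactly 688 bands; this inclusive-endpoint convention is
the only grid reading consistent with both printed counts, and it is fixed
throughout the package.

The seed is segmented on the band nearest 830 nm (ties toward the lower
wavelength), where seed tissue (reflectance > 0.4) separates cleanly from a
dark background (< 0.1). The threshold value itself is not standardised;
the default is Otsu's method on that band image — parameter-free and robust
to the synthetic contrast — with a numeric override. The largest
4-connected component above threshold is the ROI; its per-band arithmetic
mean is the seed-side spectrum.

## Synthetic populations

The generator emulates the study design: 160 seeds — 106 calibration (75
viable + 31 non-viable) and 54 prediction (38 + 16) — each with a ventral
groove and a reverse (embryo-bearing) side spectrum.

Class-mean curves are monotone-cubic (PCHIP) interpolations through ~10
control points per side, shaped like real wheat reflectance (blue trough,
chlorophyll structure near 670 nm, red edge, NIR plateau, mild 970 nm water
dip), kept inside (0.05, 0.9). The viable/non-viable difference is

    d(λ) = separation · tanh((crossover − λ)/15 nm) · (1 + 1.5 · Σ_b exp(−(λ−b)²/50))

so viable seeds are brighter below the crossover and darker above it with
exactly one sign change — 691.5 nm on the ventral side, 799.5 nm on the
reverse side, matching the crossovers reported for real seeds. Gaussian
bumps (σ = 5 nm) at the informative bands (defaults 500, 680, 850 nm)
concentrate extra separation at known wavelengths so selector-recovery
experiments have a ground truth; the 15 nm transition width keeps the bump
nearest the crossover locally dominant rather than suppressed by the sign
change. Default `separation` is 0.05 reflectance units, the scale of the
visually obvious mean-curve gaps in published two-side wheat scans.

Per-seed-side noise:

| parameter      | default | role                                         |
|----------------|---------|----------------------------------------------|
| `gain_sd`      | 0.08    | multiplicative scatter, `gain ~ lognormal(0, σ)` |
| `offset_sd`    | 0.01    | additive offset, `~ N(0, σ)` (reflectance units) |
| `baseline_amp` | 0.01    | degree-2 Chebyshev drift coefficient scale   |
| `white_sd`     | 0.005   | per-band white noise (reflectance units)     |

Gain/offset/baseline are exactly the distortions SNV and MSC are built to
remove; white noise is what the Savitzky-Golay smoother trades against.
`baseline_amp` is set to the same order as the offset noise so that the
drift is visible but does not dominate. Spectra are clipped into (0, 1];
with all scales at zero the generator returns the class mean exactly, which
the calibration/extraction chain must then reproduce to machine precision —
the pipeline's strongest structural test.

Raw cubes are produced by inverting the calibration formula (flat white
frame at 4000 counts, dark at 100) over an elliptical seed mask on a dark
background, so `calibrate ∘ simulate` is the identity up to sensor noise.

All randomness flows from one root seed through `numpy` `SeedSequence`
spawning, one stream per seed-side, so populations are bit-reproducible and
insensitive to generation order.

## Pre-processing

* **SNV**: per-spectrum `(x − mean) / sd` with the sample (n−1) standard
  deviation — the denominator convention is fixed so results are
  bit-reproducible.
* **MSC**: OLS fit `x ≈ a + b·r` against a reference `r`, returning
  `(x − a)/b`. The reference is always the **calibration-set mean**, frozen
  and reused for prediction rows — refitting on prediction data would leak
  information across the split. `|b| < 1e−10` is rejected as uncorrelated.
* **SG derivative**: Savitzky-Golay with a 7-point window. The window is the
  stated convention; polynomial order 2 and first derivative are the
  standard chemometric defaults for that window and are exposed as
  parameters (`sg_polyorder`, `sg_deriv`) for sensitivity checks. The
  derivative is per band-index step; on the uniform grid this differs from
  d/dnm only by the constant 600/765. Edges are handled by the polynomial
  fits on the terminal windows, so the transform is exact on polynomials up
  to the fitting order.

## SPA wavelength selection

The successive projections algorithm grows a chain from every starting
band: at each step every unselected column of the mean-centred calibration
matrix is projected onto the orthogonal complement of the selected span and
the column of maximum projected norm is appended (numerically zero
projections — duplicates, collinear bands — are never selected, so chains
are always linearly independent). Each candidate subset (start, size) is
scored by the RMSE of a multiple linear regression of the numeric class
code (1/2) on the subset columns, under 5-fold cross-validation on the
calibration set with seeded folds; the global minimiser wins, with ties
toward smaller subsets. A final elimination pass ranks the winning subset
by absolute standardised regression coefficient and keeps the shortest
prefix whose CV RMSE is within one standard error of the best prefix — the
one-standard-error reading of "irrelevant variables are deleted".

Choices worth noting: the validation protocol for the RMSE criterion is not
standardised in the source methodology; 5-fold CV matches the protocol used
for the SVM and avoids sacrificing a further hold-out from 106 seeds (a
single split is available as `validation="split"`). `k_max` defaults to
min(30, n/4): published selected-subset sizes for this problem range from 5
to 22, so 30 is a safe ceiling. Subset sizes on synthetic defaults land in
6–16, consistent with that range.

## Classifiers

**PLS-DA** is PLS1 (NIPALS, which converges in one pass for a single
response) on mean-centred spectra and centred class codes 1/2. A continuous
prediction below 1.5 maps to class 1; the boundary value itself goes to
class 2 (documented tie-break). The latent-variable count is chosen by
leave-one-out classification accuracy over 1..min(20, n−2, p): the
smallest count achieving the maximum wins. The LOO loop computes
predictions for all component counts in one NIPALS pass per left-out
sample, so the selection is exact, not approximated. At full rank the PLS1
regression vector equals the OLS solution — a tested identity, and the
implementation is cross-checked against an independent PLS implementation.

**SVM** is a soft-margin C-SVC with RBF kernel (the kernel solver is
scikit-learn's; the tuning protocol around it is part of this package's
contract). Inputs are standardised by calibration mean/sd (on by default,
switchable — spectra after SG derivative live on very different scales per
band). (C, γ) are tuned on the standard coarse log₂ grid, C ∈ 2^{−5..15},
γ ∈ 2^{−15..3} in steps of 2², by stratified seeded 5-fold CV accuracy;
ties resolve toward smaller C, then smaller γ (prefer the smoother model).

## Datasets and evaluation

Four dataset kinds: **ventral** and **reverse** (one row per seed from that
side), **mean** (elementwise average of a seed's two sides), and
**mixture** (both sides of every calibration seed — 212 training rows —
with prediction rows drawn from configurable ventral/reverse proportions:
(27, 27), (0, 27), (13, 27), (27, 13), (27, 0) seeds contributing one side
each). Proportion subsets are disjoint per seed — a prediction seed
contributes at most one side — read from the published design's ambiguity
in the way that keeps prediction rows independent per seed; subsets are
stratified by class (largest-remainder apportionment) so recall and
precision remain comparable across configurations. No calibration seed's
spectra ever appear in any prediction set; this is asserted at construction.

With class 1 = germinating, the confusion cells are G, NG (correct per
class) and Gr, NGr (the two error types), and the four reported metrics are
overall accuracy (G+NG)/total, viability accuracy (recall) G/(G+Gr), final
germination percentage (precision) G/(G+NGr), and the F-measure (harmonic
mean of the last two). All percentages are reported rounded half-up to one
decimal, full precision retained internally; zero-denominator metrics are
flagged undefined, never reported as 0. Calibration-set accuracy in
reports is resubstitution accuracy.

`reconstruct_confusion` inverts printed (recall, precision) percentages to
the integer confusion matrices consistent with them on a given lot — an
audit tool for published tables. Note that the published
mixture-proportion rows are computed on reduced lots: the 27-row set is a
19 viable + 8 non-viable lot, and the printed percentages of the two 40-row
sets are integer-consistent only with a 29 + 11 composition (the package's
own stratified assignment would give 28 + 12 — proportional rather than
random apportionment).

## What the synthetic experiments do and do not show

Passing tests show the pipeline's internal correctness: exact calibration
inversion, exact crop geometry, the pre-processing algebra, SPA versus
brute-force oracles, selection determinism, leakage-free dataset assembly,
and metric identities on the published tables. On default synthetic
populations both classifiers exceed 85% prediction accuracy and
SNV/SG-preprocessed models match or beat raw-spectra models — the
qualitative ordering found on real seeds.

They do not show real-data difficulty. The synthetic noise model is
scatter-plus-white; it has no per-seed biological shape variability
(moisture, chemistry, morphology), no wavelength-correlated instrument
drift, and one seed per cube. Under the default noise levels the synthetic
two-class problem is close to cleanly separable, so absolute synthetic
accuracies (often 100%) exceed the 85–89% reported for real scans and the
raw-versus-preprocessed gap mostly appears as a variance gap rather than
large accuracy differences. The published real-data accuracies are not
reproduction targets here — the raw scans are not publicly deposited —
only their internal metric consistency is.

## Problem sizes used in the shipped runs

Analysis drivers and the acceptance script run at the study's own scale:
160-seed populations, 688-band spectra, full SPA (every starting band,
5-fold CV), LOO latent-variable selection over 20 candidates, and the full
110-point SVM grid. The replicate comparison of pre-processing methods
uses 20 populations in the test suite and 10 in the acceptance script;
20 replicates bound the Monte-Carlo error on a mean accuracy difference
well below the ~2-percentage-point granularity of a 54-seed prediction set.
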