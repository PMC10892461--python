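# Methods

## The measurement problem

Leaf nitrogen exists in several chemical modes; the two quantified here
are proteinic nitrogen (modelled by casein, ~15 % N by mass, dissolved
in 0.1 N NaOH) and nitrate nitrogen (nitric acid). The calibration
samples are *leaf models*: filter paper impregnated with the mixed
solution, measured by diffuse-reflectance FT-NIR either wet or after
oven drying. Drying concentrates the analytes per volume and removes
most water; the wet state adds a dominant, variable water signature.
The corresponding aqueous solutions are measured by ATR FT-MIR, where
the analytes' fundamental vibrations are directly observable.

The workflow rests on one physical idea: an NIR overtone/combination
band belonging to an analyte must co-vary, across a concentration
series, with that analyte's MIR fundamentals. Hetero-spectral 2D
correlation makes that co-variation measurable even though the two
spectrometers share no wavenumber axis — the nine-level concentration
ladder is the common perturbation variable.

## Pipeline and assumptions

**Absorbance transform.** Diffuse reflectance ratioed against a white
reference is converted as A = log10(1/R). This is the standard
approximation for scattering samples (no Kubelka–Munk correction); the
pipeline can also run directly on reflectance-derived derivatives
(`PreprocessConfig.use_absorbance = False`), since every downstream
statistic (Pearson r, 2D correlation, PLS) is invariant to the overall
scale and nearly so to the monotone transform at these absorbances.

**Savitzky–Golay second derivative.** Local least-squares quadratic
over an 11-point window for NIR (~60 cm⁻¹ at the 6 cm⁻¹ step) and a
17-point window for MIR (64 cm⁻¹ at 4 cm⁻¹), differentiated twice and
scaled by the grid step so units are intensity/(cm⁻¹)². The filter
assumes uniform spacing; a grid whose step deviates from the median by
more than 1 % is rejected rather than silently filtered. The
(window−1)/2 edge points have no complete window and are **dropped,
not padded** — no fabricated data, and the working region
(7500–4000 cm⁻¹) is interior to the measured 9000–4000 cm⁻¹ span on
the high side. Consequence: the processed grid starts ~30 cm⁻¹ above
4000 cm⁻¹, so the five-region splitter snaps outer boundaries to the
nearest grid point within a 5-step tolerance.

**Region restriction.** Replicate variability of the second derivative
(sd/mean across repeated scans) is large above 7500 cm⁻¹ where the
second-overtone signal is weak; analysis is confined to
7500–4000 cm⁻¹. `replicate_variability` reproduces that diagnostic.

**2D correlation.** Synchronous and asynchronous maps use the standard
generalized (Noda) definitions with the m−1 covariance denominator and
the discrete Hilbert–Noda transform. Hetero-spectral pairing aligns NIR
level i with MIR level i of the same ladder; series are built from
per-level replicate means, ordered by the target analyte's
concentration. The asynchronous map is computed and exported but band
selection keys on the synchronous map only — the selection narrative is
about in-phase co-variation. Since no numeric rule for reading NIR
bands off a 2D map is standard, the explicit rule here is: per NIR
region (7500–6890, 6890–5553, 5553–5142, 5142–4439, 4439–4000 cm⁻¹,
each interior boundary belonging to the higher-wavenumber region), keep
the indices whose max |Φ| over the analyte's MIR fundamental windows
reaches the top quantile q (default 0.25). Both q and the MIR windows
(casein: amide I/II 1500–1700 cm⁻¹; nitrate: 1300–1400 and
1020–1070 cm⁻¹) are configuration, not claims.

**Band selection.** Pearson r between second-derivative intensity and
concentration is computed per wavenumber across all spectra (replicates
individually by default; per-level means are a config switch).
Maximal contiguous runs with |r| ≥ τ (default 0.8) become candidate
bands; a single isolated point is a legal band. Selection order is
threshold → 2D intersection → wet/dry common bands → ±k-point extension
(default k = 1, merging any bands that touch); the first three are
pointwise AND and hence order-independent. Wavenumbers whose intensity
standard deviation is below 1e−8 of the largest column sd are treated
as undefined and never selected: variation that far below the strongest
signal is numerically meaningless (in exact synthetic data it would
inherit a perfect correlation from far Gaussian tails) and cannot
support a calibration.

**PLS1 / LOO.** NIPALS PLS1 with column mean-centering only (no
variance scaling — second-derivative intensities share units; scaling
would inflate noise-only wavenumbers). For a single response the weight
step is closed-form, so there is no convergence iteration; a zero-norm
weight (deflation exhausted) raises an error naming the component
instead of silently truncating. Leave-one-out validation holds out one
*group* at a time — by default all six replicates of a physical sample
together (`per_sample`), preventing replicate leakage; literal
per-spectrum LOO is available. The factor count minimises the LOO MAE,
ties resolved toward fewer factors (parsimony); the final model is
refit on all data with that count. Reported metrics: validation
R² = 1 − SSE/SST of the pooled LOO predictions, RMSE, MAE. The factor
cap defaults to min(10, groups − 2, features).

## The synthetic generator

The generator emulates the study design so the whole pipeline is
testable without the (undeposited) measured spectra. It is a seeded
Beer–Lambert mixture: each component contributes Gaussian absorbance
bands scaled by its effective concentration; reflectance sets are
R = 10^(−A).

Components and NIR band centers (cm⁻¹):

| component | NIR bands | MIR bands | role |
|---|---|---|---|
| casein | 6510, 5780, 4865, 4590 | 1650, 1545, 1450 | proteinic-N analyte |
| nitrate | 5900, 4330 | 1350, 1045 | nitrate-N analyte |
| water | 6900, 5200 (broad); 7150, 6300, 5800, 5600, 5250 (narrower) | 3350, 1640, 2120 | solvent / moisture |
| cellulose | 6700, 5200, 4750, 4400, 4250 | — | paper matrix |

Water and cellulose positions follow the features reported for filter
paper and wet leaf models; the analyte positions are *plausible
stand-ins* for protein N–H/C–H combination bands and nitrate stretches
— they are declared generator ground truth, not literature values, and
the recovery tests measure the pipeline against exactly these.

Design defaults (one campaign): 9 levels × 6 replicates; casein ladder
0.2–1.0 %N ascending; nitrate ladder 0.05–0.45 %N in a fixed
decorrelating order (|r| ≈ 0.17 against the casein ladder) because the
study varied the nitrate:protein *ratio* — collinear ladders would make
the two analytes statistically indistinguishable and the printed level
values are not public. Drying multiplies effective analyte
concentrations by 3 and reduces the water scale to 0.05; wet models
draw a per-sample water content ~N(0.80, 0.02 mass fraction). Noise
model per sample: quadratic baseline drift (annihilated by the second
derivative — itself a test), multiplicative gain 1 + N(0, 0.01),
additive absorbance noise N(0, 5e−5 AU) — a realistic noise floor for
128-scan co-added FT-NIR.

`high_interference_wet_design` defines the regime in which
whole-spectrum calibration degrades: moisture sd 0.10, gain scatter
0.05, noise 6e−3 AU (putting single-wavenumber |r| at analyte centers
near the 0.8 selection threshold), and per-sample rigid shifts of the
water and cellulose bands (sd 6 cm⁻¹) representing hydration/swelling
state. Band shifts enter the second derivative nonlinearly, so
wavenumbers near matrix bands carry sample-to-sample variance that a
linear latent-factor model cannot remove — the classic reason water
regions are excluded from NIR calibrations. Under this design the
band-selected calibration beats the whole-spectrum control across
seeds (~0.94 vs ~0.91 LOO R²), mirroring the dry-vs-wet,
selected-vs-whole contrast the method exists for.

**What the generator does not emulate:** Kubelka–Munk / radiative
transfer scattering, instrument line-shape, wavelength-dependent
pathlength, band asymmetry (Voigt/Lorentzian wings), chemical
interactions (e.g. casein–nitrate association, pH-dependent band
positions), drift between replicate sessions. Passing recovery tests
therefore demonstrate the *pipeline logic* — preprocessing, 2D
correlation, selection algebra, calibration — not field performance on
real leaves.

## Numerical choices

- Grid uniformity tolerance: 1 % of the median step; otherwise an
  explicit resampling step is required of the caller.
- Region boundaries snap to the nearest grid point, with a 5-grid-step
  coverage tolerance at the outer edges (derivative trimming).
- Correlation definedness floor: column sd > 1e−8 × max column sd.
- Hotspot quantile threshold uses `np.quantile` linear interpolation;
  q = 1 degenerates to "all indices", and q below the per-region
  quantile resolution isolates a single dominant peak.
- Factor-choice ties go to the smallest count; `np.argmin` semantics.
- CSV exports use `%.17g` floats and round-trip parsing, making the
  read/write cycle lossless and runs byte-reproducible under a fixed
  seed.
- Degenerate NIPALS deflation (weight norm at machine epsilon relative
  to the deflated matrix) is a hard error naming the component.

## Problem sizes

All tests and the acceptance script run the study's own scale: 54 NIR
spectra (9 × 6) on an 834-point grid and 9 MIR spectra on an 801-point
grid per campaign; the hetero-spectral map is ≈ 579 × 785 after
preprocessing. The full suite and the acceptance script each complete
in well under a minute per campaign on one CPU.

## Known limitations

- The MIR windows per analyte and the hotspot quantile are tunable
  stand-ins for a judgment call the original workflow made by visual
  inspection of the 2D maps.
- Whether calibration should consume per-replicate spectra or per-level
  means, and absorbance- vs reflectance-derived derivatives, are left
  as configuration; defaults are per-replicate and absorbance.
- PLS2, OSC/EMSC preprocessing, Voigt band shapes and alternative
  band-selection criteria (VIP, iPLS, genetic algorithms) are out of
  scope.
- Real-leaf validation is impossible at desk scale; see the generator
  caveats above.
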