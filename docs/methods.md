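# Methods

## Model and assumptions

All spectra are treated as Beer–Lambert-linear: the absorbance of a mixture
at every wavelength is the concentration-weighted sum of per-unit
pure-component spectra, with no stray light, baseline drift or
instrument-response nonlinearity. Every resolution route in
`specres.methods` is exact under this assumption; deviations from it (real
instruments drift, excipients absorb) surface as non-flat plateaus, biased
factorized reconstructions or recovery error, which is why the plateau
flatness diagnostic and the factorization leakage check exist.

The geometric premise is an *extended region*: a wavelength window where
the extended component (TCB) absorbs and the other (LVM) does not. On the
zero-order spectrum this is 290–306 nm; on the first derivative the usable
window widens to 280–315 nm. Dividing the mixture by a pure TCB divisor
makes the ratio constant over that window, equal to `c_TCB / c_divisor`,
and every constant-based route (RS, CM, their D¹ analogues, CV, CNV)
starts from that plateau constant. The factorized routes instead rely on a
single interference-free wavelength (304 nm on D⁰, 310 nm on D¹) and need
no divisor at all. DD¹ relies on the complementary fact that a component
divided by its own pure spectrum is a constant whose derivative vanishes.

## Synthetic data

`specres.synthetic` generates Gaussian-band spectra on a 200–400 nm grid at
0.5 nm. The shipped models are:

* TCB-like: bands (220 nm, σ 9 nm, 0.1322 AU/(µg/mL)) and
  (304 nm, σ 10 nm, 0.0533 AU/(µg/mL));
* LVM-like: one band (214 nm, σ 8 nm, 0.0834 AU/(µg/mL)).

Band heights are the published calibration slopes at the corresponding
maxima, so synthetic responses sit on the real instrument's scale. Band
widths are not published; they were chosen once so that the 214/220 nm
bands overlap severely while LVM's tail beyond 285 nm stays below
1 × 10⁻⁶ AU/(µg/mL) — far under the division guard — making the
extended-region assumption hold by construction. Photometric noise is
additive i.i.d. Gaussian with default σ = 0.002 AU, a typical double-beam
photometric noise figure; all noise is seeded.

What the generator deliberately does *not* emulate: the true (non-Gaussian)
band shapes of the real drugs, baseline drift, wavelength-registration
error, correlated noise, and excipient absorption. Passing tests therefore
demonstrate the correctness of the algebra and its noise behaviour under
idealised conditions, not the accuracy attainable on real formulations.

## Numerical choices

* **Grid.** 200–400 nm at 0.5 nm; all binary operations require a common
  grid and resampling is linear interpolation, with extrapolation refused.
  Wavelength reads use the grid value when the requested wavelength sits on
  the grid (every configured read does) and linear interpolation otherwise.
* **Derivative.** The first derivative is the least-squares (Savitzky–Golay
  order-1/2) slope over the nine grid points inside a ±2 nm window (window
  width Δλ = 4 nm), multiplied by the reporting scale factor 10. This
  estimator is exact on straight lines, antisymmetric about Gaussian band
  centres, and uses the whole window rather than only its endpoints, which
  keeps the noise amplification of single-point derivative reads down. The
  half-window is trimmed at each end of the grid.
* **Division guard.** Ratio spectra mask grid points where the divisor is
  below ε = 1 × 10⁻⁴ AU; masks propagate through all downstream algebra,
  and amplitude reads on masked points raise rather than return garbage.
  This matters on D¹ routes, where the divisor's derivative crosses zero at
  304 nm inside the plateau window: the masked crossing point is simply
  excluded from the plateau mean.
* **Plateau flatness.** The plateau constant is the mean of the unmasked
  ratio over the stated window (≥ 3 points required); its percent RSD is a
  flatness diagnostic with default tolerance 2%. Exceeding the tolerance
  attaches a warning but still returns the constant, because real spectra
  drift and near-zero constants (pure-interferent mixtures) are legitimately
  noisy in relative terms.
* **Spectrum subtraction.** The RS-resolved less-extended spectrum is
  computed as `M − k·Y'`, which equals the textbook `(M/Y' − k)·Y'`
  wherever the ratio is defined and extends it smoothly across
  divisor-masked points, so resolved spectra carry no mask holes.
* **Conservation.** For every SS-coupled route the two resolved spectra sum
  to the (order-matched) mixture identically; the residual is asserted
  below 1 × 10⁻¹⁰ as a regression guard.

## Calibration and statistics

Calibration is ordinary least squares of response on concentration, fitted
over the published linear ranges (TCB 2–20 µg/mL at 304 nm, 1–10 µg/mL at
220 nm; LVM 2–14 µg/mL). LOD and LOQ use the ICH/VICH residual convention
3.3·s/|slope| and 10·s/|slope| with the residual SD (or a supplied blank
SD); on noiseless synthetic fits both are zero. Predictions below the LOD
are flagged, never clipped. The CV route carries its own curve — plateau
constant against a normalized (per-1 µg/mL) divisor versus concentration —
which is the identity on ideal data; CNV reads the same constant directly.

Method comparison uses the pooled-variance two-sample *t* (two-sided) and
the larger-over-smaller variance-ratio *F*, each against critical values
computed from the reference distributions at p = 0.05 (never hard-coded
tables). Single-factor ANOVA reports the full SS/df/MS/F partition.
Intra-day precision pools within-day sample variances; inter-day precision
is the RSD of the pooled replicate set across days.

## Design choices where the design was open

* **CV regression.** The CV "regression equation at 304 nm" is interpreted
  as the constant-vs-concentration regression built from divisions by the
  normalized divisor; 304 nm labels the analyte band rather than a second
  amplitude read. The near-unit slope of that curve on real data supports
  this reading.
* **CNV divisor.** The normalized divisor is the pure extended-component
  spectrum per 1 µg/mL; only then does the plateau constant equal the
  concentration outright.
* **Both analytes from CV/CNV.** CV and CNV natively quantify only the
  extended component. The implementation complements them with a
  spectrum-subtraction step — rebuild the TCB spectrum from the found
  concentration, subtract it from the mixture, read LVM at 214 nm — so all
  nine routes report both analytes. This mirrors the package-wide principle
  that spectrum subtraction complements any route that resolves one
  component.
* **TCB read for RS-SS.** Both the 304 nm and the more sensitive 220 nm
  reads are computed; 304 nm is the primary, 220 nm is reported as an
  extra.
* **Derivative kernel.** Only the window width (4 nm) and scale (10) are
  fixed by convention; the least-squares kernel was chosen over the
  two-endpoint difference for its noise behaviour (see above). Any kernel
  exact on lines and odd around band centres yields the same noiseless
  results.

## Study sizes and noise behaviour

The bundled study (`specres run`, `pipeline.run_study`) runs all nine
routes over the five-ratio specificity grid plus the dosage-form level
(24:15 µg/mL from the 120/75 mg/mL label through 1→100 and 1→50 dilutions)
with three replicates per cell by default. The noise-robustness check uses
100 seeded replicates of the 1:1 mixture at σ = 0.002 AU; mean recoveries
stay within ±0.3% of 100% for every route. Replicate RSDs range from
~0.3% (plateau-based D⁰ routes, which average ~30 grid points) to ~1.9%
for the D¹ factorized route, whose scaling amplitude is a single
derivative read at 310 nm — the point of largest noise leverage in the
whole family and the binding case for the 2% repeatability requirement.

## Known limitations

* Binary mixtures only; three-component extensions (extended ratio
  subtraction, constant-centre variants) are out of scope.
* Second and higher derivatives, smoothing filters and vendor file formats
  are not implemented.
* Greenness scoring covers Eco-Scale, AGREE and NEMI; pictograms, signal
  words and principle scores are user-supplied inputs, not looked up from
  hazard databases. GAPI and whiteness (RGB) scoring are not implemented
  because their rubrics are not fully specified by their sources' public
  summaries.
* The AGREE profile shipped with the package is an illustrative scoring of
  a direct spectrophotometric assay, not a reconstruction of any published
  per-principle assignment.
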