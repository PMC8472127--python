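# Methods

This note records the models behind `effiq`, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Measurement chain

### Detector response and linearization

The response is a least-squares polynomial fit of mean pixel value against
detector air kerma over an exposure series (ten dose levels by default):
degree 1 (`linear`) for flat panels, degree 5 (`polynomial5`) for slot
scanners with a non-linear response. Monotonicity over the fitted kerma
range is enforced by rejection — a non-monotone fit raises, naming the
turning point — rather than by constrained fitting, because a response that
bends back signals a measurement problem and should fail loudly.

Linearization inverts the forward model numerically: 1000 forward samples
over the fitted range, inverted by monotone piecewise-cubic (PCHIP)
interpolation. This treats the linear and quintic kinds identically and
reproduces the forward model to better than 1e-6 relative (tested). Pixels
outside the invertible output range are clamped and counted; more than 1%
clamped raises.

### Slanted-edge eMTF

Per edge image: the edge angle is estimated from the data (least-squares
line through per-row centroids of squared gradient, windowed ±15 px around
the row maximum), never assumed — the edge is deliberately shifted between
exposures. Pixels are projected onto the edge normal and binned at 0.1 ×
pitch; empty interior bins (≤10%) are filled by linear interpolation. The
LSF is the central-difference derivative; a Hann taper centred on the LSF
peak is ON by default (noise control; oracle tests run with `window="none"`
because the taper slightly biases noise-free analytic checks). The MTF is
the normalised rFFT modulus, resampled onto a uniform 0.01 mm⁻¹ grid up to
the detector Nyquist 1/(2·pitch). Curves from the five images are averaged
pointwise, then frequencies are multiplied by m = SID/(SID − object
offset); a geometry with `magnification_axis="none"` (slot scan direction)
keeps m = 1.

### eNNPS

Defaults follow the reference acquisition: four linearized flat fields, a
central 1024² ROI each, 256² sub-ROIs with 128 px overlap (49 per image,
196 periodograms). Each sub-ROI is detrended by a least-squares 2-D
quadratic surface (`detrend="mean"` falls back to mean subtraction);
quadratic detrending is standard flat-field practice to keep heel-effect
shading out of the low-frequency bins. NPS(u,v) = Δx·Δy/(NxNy) ·
mean|DFT2(residual)|², divided by the squared mean signal. The 1-D vertical
curve averages the ±7 columns flanking the vertical frequency axis with the
on-axis column excluded (trend residue concentrates there), folds ±v, and
is rescaled to the object plane like the eMTF. No smoothing is applied.

Estimator variance: with 196 overlapping periodograms the 2-D bins carry
~10% relative sd (overlap correlation inflates the naive 1/√196); the
±7-line band average leaves ~3% per 1-D bin. The ±v fold does **not** halve
the variance: the power spectrum of a real image is centro-symmetric, so
the folded values are duplicates. This 3% floor is why the composition
oracle below is stated in RMS terms.

### Scatter fraction

Measurement disks of 60% of the cylinder diameter at the central 5×5
cylinder centres (avoids penumbra); background from equal-area disks at the
40 midpoints between 4-neighbouring central cylinders, on the same image.
SF = mean(lead)/mean(background). The grid can be passed explicitly or
auto-detected by thresholding at half the median level and centroiding the
121 shadows; a count mismatch raises. Background disks that would overlap a
shadow raise a geometry error.

### Dose geometry and q

TF = AK⁺/AK⁻. Dosimeter-plane readings are projected to the detector plane
linearly in SDD/SID for slot beams (fan-beam fluence falls off along one
axis only) and by (SDD/SID)² for cone beams. The AK in the eDQE denominator
is the *phantom-free* air kerma corrected to the detector plane — that is
the quantity's definition — not the behind-phantom DAK; callers may pass
DAK for sensitivity runs. Published component tables are internally
consistent with AK·TF = DAK to the printed precision on most rows; one row
differs in the last digit and we implement the formula, not the digit.

q = Φ_tot/K with K = Σ Φ(E)·E·(μen/ρ)air(E)·u; u = 1.602177e-5 converts
keV·cm²/g·mm⁻² to µGy. The air μen/ρ and the Al/Cu μ/ρ filter tables are
shipped CSV transcriptions of the standard NIST tabulations, interpolated
log-log. q is invariant to the fluence scale, so relative spectra are fine.
Over the diagnostic range q *increases* with beam hardening (E·μen/ρ falls
with energy, so a harder beam deposits less kerma per photon); the property
suite asserts this direction.

### Spectrum generator

A deliberately simple stand-in for a full spectrum calculator: Kramers
bremsstrahlung (Φ ∝ (kVp − E)/E, zero above kVp, 1 keV bins from 10 keV)
filtered through Al/Cu. Inherent tube filtration defaults to 2.5 mm Al
equivalent — the regulatory minimum total filtration for diagnostic tubes —
because a bare Kramers spectrum is unphysically soft and would produce q
values below anything a clinical beam shows. No anode self-filtration model
and no characteristic lines; published q values for a given system should
be entered as config overrides when exactness matters.

## Synthetic data: what it emulates

Every generator records its ground truth (`SyntheticGroundTruth`) so each
estimator is testable against a closed form:

- **Flat fields**: mean + optional quadratic trend + i.i.d. Gaussian noise.
  True NNPS is exactly σ²Δx²/μ². Gaussian (not Poisson) by default because
  every downstream formula consumes second-order statistics only; a Poisson
  option exists for dose-scaling sanity checks (NNPS ∝ 1/dose).
- **Edges**: the blurred step is integrated *analytically* over each square
  pixel aperture (repeated antiderivatives of the normal CDF, handling
  σ = 0 as the Heaviside limit), so the truth MTF
  exp(−2π²σ²f²)·|sinc(p·cosθ·f)·sinc(p·sinθ·f)| carries no rasterisation
  bias.
- **Beam-stop grids**: hard disks (no penumbra), shadow level
  primary·transmission + scatter — the measured ratio is exactly the truth.
- **Exposure series**: mean pixel value = polynomial(K), monotonicity
  validated.

Not emulated: focal-spot blur, detector lag, fixed-pattern noise, spatially
correlated (non-white) noise, realistic scatter point-spread. A green test
therefore establishes estimator correctness on its stated model, not
robustness to every artefact of real detectors.

### The default three-system study

`default_study()` states one synthetic world per protocol, taken from the
published component table of the three-system comparison this package
reimplements: TF, SF, detector-plane AK and q per system are the printed
values, and the flat-field noise is set so the true NNPS level
(1 − SF)²/eNEQ_max reproduces each system's printed peak eNEQ. PSF widths
(slot 0.20 mm, flat-panel 0.15 mm at pitches 0.254/0.143/0.139 mm) are
chosen once so the slot system is blurrier (scan motion) while the DR
systems keep the better high-frequency eMTF. The printed AK is treated as
already at the detector plane; the simulated dosimeter reading is its
back-projection to the SDD plane. Dosimeter distance (SID − 60 cm) and
object-plane offsets (phantom depth + 5 cm edge stand-off: 28 cm chest,
20 cm knee) are stated once here; the sources print neither.

Pipeline defaults are scaled for speed (edge ROI 40 mm, NNPS ROI 512 px,
beam-stop grid 12 mm pitch in a 1024² frame); a full three-system run takes
a few seconds on one CPU. The estimators are identical at full acquisition
scale, which the test suite exercises where variance matters.

## Statistics

Kruskal–Wallis (tie-corrected, df = k − 1) per frequency bin; pairwise
Mann–Whitney only when the global test is significant at 5%, without
multiplicity adjustment — replicating the reference procedure, including
its known anti-conservatism (adjacent frequency points are dependent; the
report footer says so). U is reported in the min(U_a, U_b) convention
(complete separation prints U = 0). Z = (U − nm/2)/σ_tie-corrected,
uncorrected, matching the published printouts; the *p*-value applies the
half-unit continuity correction to the normal tail (as R's `wilcox.test`
does) because without it the normal p cannot track the exact permutation
tail to 0.02 at n = m = 10 — U is discrete with p-steps of ~0.06 near the
null mean. An exact enumeration p is available for small samples.

Default frequency bins: eDQE 0.00–1.00 and 1.15–2.15 mm⁻¹; eNEQ 0.00–1.25
and 1.35–2.55 mm⁻¹; reporting grid step 0.1 mm⁻¹ (11/13 points per system
per low bin, 33/39 pooled across three systems).

## Known limitations

- The composition oracle (closed-form eDQE from truth vs the measured
  pipeline) holds to ~3% RMS at the reference acquisition scale, but a
  *uniform* 5% pointwise bound is a ~1.7σ-per-bin event across ~26
  reporting bins given the eNNPS variance floor above; the acceptance
  suite keeps the literal pointwise check (red by design) and the metrics
  suite asserts the variance-consistent RMS form.
- DICOM reading requires `pydicom`, which this build does not bundle;
  16-bit TIFF (with the pixel pitch in the resolution tags) is the on-disk
  format.
- The slot-scan direction's magnification and motion blur are not modelled
  beyond m = 1 on that axis; `magnification_axis` is explicit per geometry
  rather than guessed.
- Grid (anti-scatter) transmission and scatter-kernel modelling are out of
  scope; SF is a single scalar per configuration.
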