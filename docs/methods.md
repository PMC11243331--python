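# Methods

## Measurement model

A THz-TDS transmission measurement is modelled as a pair of sampled
electric-field transients: a reference `E_ref(t)` and a sample
`E_sam(t)`. The synthetic reference pulse is the first derivative of a
Gaussian,

    e(t) = -(t - t0)/w · exp(-(t - t0)² / 2w²),

normalised to unit peak amplitude — the simplest analytic single-cycle
waveform. Defaults: 2048 samples at Δt = 0.02 ps (41 ps record),
t0 = 5 ps, w = 0.10 ps. These were chosen together so that (a) the
record holds the slab group delay (~1.6 ps for a 1.11 mm tablet at
n = 1.42) and the resonant ringdown (1/πγ ≈ 6.4 ps at γ = 0.05 THz)
with room to spare, and (b) at the default signal-to-noise ratio the
spectral dynamic range exceeds 40 dB from roughly 0.3 to 3.5 THz,
covering every absorption line the package models (0.94–2.5 THz).
Noise is additive white Gaussian on the time-domain trace only, with
standard deviation max|e|/SNR; default SNR 1000, default seed 42.
`snr=inf` disables noise exactly.

### Dielectric functions

Sample media are described by a complex relative permittivity in the
physics sign convention (Im ε ≥ 0 for a passive medium):

* **Tablets**: ε(ν) = ε∞ + Σₖ sₖ ν₀ₖ² / (ν₀ₖ² − ν² − i γₖ ν), a constant
  background plus underdamped Lorentz oscillators (γ < ν₀). Each line
  produces an absorption peak at ~ν₀ and an S-shaped feature in n —
  anomalous dispersion — exactly the signature the analysis stage tests
  for. Default damping γ = 0.05 THz for crystalline tablets.
* **Liquid layers**: background = (1 − φ)·ε_Debye(ν) + φ·ε∞,solute with
  double-Debye water (ε_s = 78.36, ε₁ = 4.93, ε∞ = 2.50, τ₁ = 8.24 ps,
  τ₂ = 0.18 ps — fixed, literature-style room-temperature constants;
  any parameter set reproducing water's strong, monotonically rising
  THz absorption, here ~180–380 cm⁻¹ over 0.5–2 THz, would serve) plus
  solute oscillators broadened to γ = 0.15 THz for the dynamic liquid
  environment. Concentration c (g/mL) maps to volume fraction
  φ = c/ρ with ρ = 1.5 g/mL, linear mixing; oscillator strengths scale
  linearly with c (they are proportional to solute number density).

### Preset calibration

Oscillator centers are the published line positions. Strengths follow
sₖ ∝ 1/ν₀ₖ, which equalises the refractive-index swing of each line
(the swing goes as s·ν₀/γ); the overall scale is set so the model's
Re ñ stays inside the published index windows — mannitol 1.401–1.439
within [1.40, 1.45], erythritol 1.321–1.380 within [1.30, 1.40] — over
0.4–3.2 THz. This coupling is not adjustable independently: causality
ties the α peak height to the n swing (α_peak ≈ 838·ν₀·Δn cm⁻¹), so
the published index windows bound how strong the synthetic lines can
be, roughly 5–30 cm⁻¹ here. The weak mannitol 1.23 THz feature is
deliberately set near the bottom of that range. Two mannitol tablet
presets ship — the six-line list including 1.23 THz and a five-line
variant without it — because the published record itself reports both
readings; the package does not adjudicate between them.

### Propagation

Transmission through a slab of thickness d is single-pass:

    T(ω) = [4ñ/(ñ+1)²] · exp(−i(ñ−1)ωd/c),   ñ = sqrt(ε),

with the conjugate index used under the e^{−iωt} spectral convention so
the pulse is delayed and attenuated. No Fabry–Pérot echo terms: the
closed-form extraction below contains a single Fresnel factor, and the
forward model is kept exactly invertible by it. For the liquid cell the
reference arm is the matched chip, so the COC window interfaces cancel
and only the 50 µm layer appears in T.

## Extraction

The analysis chain is the standard closed-form THz-TDS inversion:

1. **FFT** of both traces (rectangular window by default, zero-padding
   to 4× the next power of two). Windowing is off by default because
   the single-pass model has no echoes to suppress and a window biases
   peak amplitudes; Hann is available for noisy inputs.
2. **Phase difference** φ(ν) = unwrap[arg E_ref − arg E_sam], the
   sample's phase retardation, positive for an optically dense medium.
   After unwrapping along increasing frequency, the curve is anchored:
   a least-squares line over 0.2–0.4 THz estimates the zero-frequency
   intercept, and the nearest integer multiple of 2π is removed. This
   fixes the branch ambiguity of the wrapped difference; the anchor
   band is standard low-frequency practice where the phase is nearly
   linear.
3. **Index** n = 1 + cφ/(ωd); **absorption**
   α = −(2/d)·ln[ρ(n+1)²/(4n)] in cm⁻¹, the intensity coefficient
   (field ratio carries e^{−αd/2}). No clamping: non-physical n < 1 or
   α < 0 excursions outside resonances are reported as-is and flagged
   by the validity band.
4. **Validity band**: the widest contiguous interval where the
   reference magnitude exceeds the noise floor (median magnitude above
   5 THz) by a dynamic-range margin. The bare `valid_band` default is
   20 dB — adequate for quoting optical constants. The pipeline
   (`RunConfig`) uses 40 dB for tablets and 60 dB for the liquid cell:
   peak *detection* needs more headroom, because amplitude noise maps
   to absorption noise as σ_α ≈ (2/d)·σ_ρ/ρ — about 2 cm⁻¹ at a 20 dB
   band edge for a 1.11 mm tablet and 22× worse for the 50 µm layer —
   which would otherwise seed spurious prominence peaks at the band
   edges.

In the noise-free limit extraction inverts the forward model to
~1e-4 in n over the instrument band (0.3–2.6 THz); the residual is the
neglected phase of the complex Fresnel factor near resonances, which
enters the closed form only through real n.

## Peak analysis

Detection runs on α inside the validity band: local maxima with
prominence ≥ 5% of the in-band maximum, centers refined by parabolic
interpolation through the three surrounding points (detection is
therefore invariant to rescaling α by any positive constant). For
solution spectra a rolling-minimum baseline (0.4 THz window) is
subtracted first — the differential water background otherwise sets the
prominence scale. The 5% threshold is chosen so the weakest modelled
line (mannitol 1.23 THz) survives at default settings while edge noise
does not.

Anomalous dispersion is flagged per peak when the least-squares slope
of n over ±max(fwhm/2, 0.02 THz) around the center is negative; windows
that leave the band give a skipped (None) flag.

The Kramers–Kronig check reconstructs
n_KK(ν) = n∞ + (c/2π²)·P∫ α(ν′)/(ν′²−ν²) dν′ with the Maclaurin
(alternating-point) principal-value quadrature on the uniform grid,
truncated to the validity band. Truncation is a known bias — the
package quantifies it by grid-density self-convergence (≤ 2e-6 here)
and by the analytic single-Lorentz case (≤ 5e-4 on the central
half-band). n∞ defaults to the extracted n at the high-frequency band
edge, which absorbs most of the truncated tail. On extracted tablet
spectra the mean |n_KK − n| over the central half-band is ~2e-3,
comfortably inside the 0.02 consistency bound used by the tests.

## Peak matching

One-to-one mode sorts all cross-list pairs by |Δν| and accepts
greedily while both members are free; it is order-independent and
equals the brute-force optimal assignment whenever line spacing
exceeds twice the tolerance (a property the suite checks by exhaustive
enumeration). Many-to-one mode maps each A-line to its nearest B-line
within tolerance, covering merged lines in simulated spectra (two
experimental lines sharing one computed line). Default tolerances:
0.10 THz one-to-one, 0.15 THz many-to-one — the smallest round values
consistent with the published solid/simulation correspondences;
overridable everywhere. Assignment strings are opaque pass-through
metadata; non-THz lists (e.g. Raman shifts) are legal inputs with units
declared in the label, no conversion attempted.

## Concentration series

Five equally spaced concentrations, 0.2–1.0 g/mL by default (the
published range is 0–1 g/mL with five unspecified values). Each
concentration shares one noise-free incident pulse and receives
independent, reproducible noise from seeds spawned off the root seed.
Signal strength is the time-domain peak-to-peak amplitude (a
frequency-domain integrated-magnitude metric is available behind a
flag); the module deliberately reports raw signal metrics rather than
per-concentration α, since the water background makes those
comparisons unreliable. The monotone strength–concentration
relationship follows from the mixing rule: solute is far less
absorbing than the water it displaces, so |T| rises pointwise with
concentration in-band.

## Numerical choices and degenerate inputs

* Units frozen: time ps, frequency THz, thickness mm at the API
  (cm/m internally where α and KK require), α in cm⁻¹.
* Phase referencing: spectra are referred to the start of the time
  axis, so a shifted axis does not masquerade as a phase delay.
* Parabolic refinement falls back to the grid point when the
  three-point stencil is not concave; band-edge maxima are not
  refined.
* Degenerate media (Re ñ ≈ 0), empty dynamic-range bands, mismatched
  grids/axes, non-uniform time axes (relative jitter > 1e-9), and
  out-of-domain parameters raise typed errors (CLI exit codes 2/3/4
  for validation / format / numerical-domain).
* Determinism: identical config (including seed) gives bit-identical
  traces and artifacts; per-stage seeds are derived from the root seed
  at fixed offsets so adding a stage never perturbs earlier noise.

## Scope of the synthetic generator, and limitations

The generator emulates the features the analysis depends on: a
single-cycle broadband pulse, slab delay and Fresnel loss, Lorentzian
lines with their anomalous-dispersion signature, water's double-Debye
background, concentration mixing, and stationary white noise. It does
not emulate water-vapour rotational lines (real purge environments at
~20% relative humidity leave residual narrow lines), Fabry–Pérot
echoes from tablet faces or cell windows, frequency-dependent window
dispersion, detector-response rolloff, delay-stage jitter, or
temperature effects. Passing tests therefore demonstrate that the
analysis chain is a correct inverse of this measurement model and that
the published peak lists, index windows, and matching structure are
recovered under realistic noise — not that the code would be robust to
every artefact of a physical spectrometer.

Problem sizes used throughout (2048-sample traces, 4× zero-padding,
~6 GHz grid spacing) keep every pipeline run in the tens of
milliseconds; they are the package's defaults, not limits.
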