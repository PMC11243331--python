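"""Optical-constant extraction from a reference/sample trace pair.

The chain is the standard THz-TDS closed-form analysis: Fourier
transform both transients, unwrap the spectral phase difference, read
the real refractive index off the phase delay,

    n(omega) = 1 + c * phi(omega) / (omega * d),

and the power absorption coefficient off the Fresnel-corrected
amplitude ratio rho = |E_sample| / |E_reference|,

    alpha(omega) = -(2/d) * ln[ rho * (n+1)^2 / (4 n) ],

valid for a single pass through a thick slab (no echo terms). Results
are trusted only inside a validity band where the reference spectrum
clears the noise floor by a stated dynamic-range margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyBandError,
    IncompatibleSpectraError,
    InsufficientDataError,
    NumericalDomainError,
    ValidationError,
)
from .forward import C_MM_PS, TimeTrace

#: Default low-frequency interval over which the unwrapped phase is
#: anchored by a straight-line fit (THz). Standard THz-TDS practice.
ANCHOR_BAND_THZ = (0.2, 0.4)

DEFAULT_FLOOR_DB = 20.0
DEFAULT_PAD_FACTOR = 4
NOISE_FLOOR_ABOVE_THZ = 5.0


@dataclass(frozen=True)
class Spectrum:
    """Complex one-sided spectrum of a trace.

    ``nu`` in THz (strictly increasing, positive only), ``amp`` the
    complex amplitude, ``phase_unwrapped`` the continuous phase in
    radians.
    """

    nu: np.ndarray
    amp: np.ndarray
    phase_unwrapped: np.ndarray

    def __post_init__(self):
        if not (len(self.nu) == len(self.amp) == len(self.phase_unwrapped)):
            raise ValidationError("nu, amp and phase_unwrapped must have equal length")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.amp)


@dataclass(frozen=True)
class OpticalConstants:
    """Extracted n(nu) and alpha(nu) with a validity band.

    ``alpha_cm`` is the power absorption coefficient in cm^-1. ``band``
    is the (nu_min, nu_max) interval, THz, inside which the reference
    dynamic range supports the extraction. ``meta`` records the options
    used.
    """

    nu: np.ndarray
    n: np.ndarray
    alpha_cm: np.ndarray
    band: tuple[float, float]
    meta: dict = field(default_factory=dict)

    @property
    def in_band(self) -> np.ndarray:
        return (self.nu >= self.band[0]) & (self.nu <= self.band[1])


# ---------------------------------------------------------------------------
# stage 1: Fourier transform
# ---------------------------------------------------------------------------

def fft_spectrum(trace: TimeTrace, window: str = "none",
                 pad_factor: int = DEFAULT_PAD_FACTOR) -> Spectrum:
    """One-sided discrete Fourier spectrum of a trace.

    Uses the e^{-i omega t} sign convention and approximates the
    continuous transform by the Riemann sum (the rFFT scaled by dt).
    The record is zero-padded to ``pad_factor`` times the next power of
    two; a Hann window is available for noisy inputs (``window="hann"``,
    default rectangular). Only strictly positive frequencies are
    returned; the frequency step is 1/(N_padded * dt).
    """
    if trace.t.size < 64:
        raise InsufficientDataError("need at least 64 samples")
    if pad_factor not in (1, 2, 4, 8):
        raise ValidationError("pad_factor must be one of {1, 2, 4, 8}")
    if window not in ("none", "hann"):
        raise ValidationError("window must be 'none' or 'hann'")

    e = trace.e
    if window == "hann":
        e = e * np.hanning(e.size)
    n_pad = pad_factor * (1 << int(math.ceil(math.log2(e.size))))
    dt = trace.dt_ps
    amp = np.fft.rfft(e, n=n_pad) * dt
    nu = np.fft.rfftfreq(n_pad, dt)
    # the pulse is offset from t=0; refer phases to the start of the axis
    amp = amp * np.exp(-2j * math.pi * nu * trace.t[0])
    phase = np.unwrap(np.angle(amp[1:]))
    return Spectrum(nu=nu[1:], amp=amp[1:], phase_unwrapped=phase)


# ---------------------------------------------------------------------------
# stage 2: phase difference
# ---------------------------------------------------------------------------

def phase_difference(sample: Spectrum, reference: Spectrum,
                     anchor_band_thz: tuple[float, float] = ANCHOR_BAND_THZ) -> np.ndarray:
    """Unwrapped spectral phase retardation of the sample.

    phi(nu) = unwrap[arg E_ref - arg E_sample] in the e^{-i omega t}
    convention, i.e. the physical phase delay accumulated in the sample,
    positive for an optically dense medium. After unwrapping along
    increasing frequency the curve is anchored: a straight line is
    fitted over ``anchor_band_thz`` and the integer multiple of 2*pi
    nearest its zero-frequency intercept is subtracted, removing the
    branch ambiguity of the wrapped difference.
    """
    if sample.nu.shape != reference.nu.shape or not np.allclose(
        sample.nu, reference.nu, rtol=0, atol=1e-12
    ):
        raise IncompatibleSpectraError("sample and reference spectra share no grid")

    phi = np.unwrap(np.angle(reference.amp * np.conj(sample.amp)))

    lo, hi = anchor_band_thz
    mask = (sample.nu >= lo) & (sample.nu <= hi)
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(sample.nu[mask], phi[mask], 1)
        phi = phi - 2.0 * math.pi * round(intercept / (2.0 * math.pi))
    return phi


# ---------------------------------------------------------------------------
# stage 3: refractive index
# ---------------------------------------------------------------------------

def refractive_index(phi: np.ndarray, nu: np.ndarray, d_mm: float) -> np.ndarray:
    """Real refractive index from the phase delay: n = 1 + c*phi/(omega*d).

    ``nu`` in THz, ``d_mm`` in millimetres. No clamping — non-physical
    values outside the validity band are reported as-is.
    """
    if d_mm <= 0:
        raise ValidationError("thickness must be positive")
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValidationError("frequencies must be positive")
    omega = 2.0 * math.pi * nu  # rad/ps
    return 1.0 + C_MM_PS * phi / (omega * d_mm)


# ---------------------------------------------------------------------------
# stage 4: absorption coefficient
# ---------------------------------------------------------------------------

def absorption_coefficient(amp_sample: np.ndarray, amp_reference: np.ndarray,
                           n: np.ndarray, d_mm: float) -> np.ndarray:
    """Power absorption coefficient, cm^-1, from the amplitude ratio.

    alpha = -(2/d) * ln[ rho * (n+1)^2 / (4n) ] with
    rho = |E_sample| / |E_reference|; the Fresnel factor 4n/(n+1)^2 is
    the lossless transmission of the two slab faces, so alpha vanishes
    exactly for a lossless slab. alpha is the intensity coefficient:
    the field ratio carries exp(-alpha d / 2).
    """
    if d_mm <= 0:
        raise ValidationError("thickness must be positive")
    amp_sample = np.abs(np.asarray(amp_sample))
    amp_reference = np.abs(np.asarray(amp_reference))
    n = np.asarray(n, dtype=float)
    if np.any(amp_reference <= 0):
        raise NumericalDomainError("reference magnitude vanishes on the grid")
    if np.any(n <= 0):
        raise NumericalDomainError("refractive index must be positive")
    rho = amp_sample / amp_reference
    d_cm = d_mm / 10.0
    with np.errstate(divide="ignore"):
        arg = rho * (n + 1.0) ** 2 / (4.0 * n)
        return np.where(arg > 0, -(2.0 / d_cm) * np.log(np.maximum(arg, 1e-300)), np.inf)


# ---------------------------------------------------------------------------
# stage 5: validity band
# ---------------------------------------------------------------------------

def valid_band(reference: Spectrum, floor_db: float = DEFAULT_FLOOR_DB) -> tuple[float, float]:
    """Widest contiguous interval with >= floor_db of dynamic range.

    The noise floor is estimated as the median reference magnitude above
    5 THz (outside any usable signal); the band is the longest run of
    grid points whose magnitude exceeds that floor by at least
    ``floor_db`` decibels.
    """
    if not floor_db > 0:
        raise ValidationError("floor_db must be positive")
    mag = reference.magnitude
    tail = mag[reference.nu > NOISE_FLOOR_ABOVE_THZ]
    if tail.size == 0:
        raise EmptyBandError("no grid points above the noise-floor reference region")
    floor = float(np.median(tail))
    ok = mag > floor * 10.0 ** (floor_db / 20.0)
    if not np.any(ok):
        raise EmptyBandError("no frequency clears the dynamic-range floor")
    # longest contiguous run of True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    k = int(np.argmax(stops - starts))
    return (float(reference.nu[starts[k]]), float(reference.nu[stops[k] - 1]))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def extract_optical_constants(
    sample: TimeTrace,
    reference: TimeTrace,
    d_mm: float,
    window: str = "none",
    pad_factor: int = DEFAULT_PAD_FACTOR,
    anchor_band_thz: tuple[float, float] = ANCHOR_BAND_THZ,
    floor_db: float = DEFAULT_FLOOR_DB,
) -> OpticalConstants:
    """Run the full extraction: FFT -> phase -> n -> alpha -> band.

    Both traces must share a time axis. All options are recorded in the
    result's ``meta``.
    """
    if sample.t.shape != reference.t.shape or not np.allclose(
        sample.t, reference.t, rtol=0, atol=1e-12
    ):
        raise IncompatibleSpectraError("sample and reference traces share no time axis")
    spec_s = fft_spectrum(sample, window=window, pad_factor=pad_factor)
    spec_r = fft_spectrum(reference, window=window, pad_factor=pad_factor)
    phi = phase_difference(spec_s, spec_r, anchor_band_thz=anchor_band_thz)
    n = refractive_index(phi, spec_s.nu, d_mm)
    band = valid_band(spec_r, floor_db=floor_db)
    inb = (spec_s.nu >= band[0]) & (spec_s.nu <= band[1])
    if np.any(spec_r.magnitude[inb] <= 0):
        raise NumericalDomainError("reference magnitude vanishes inside the band")
    # report everywhere the ratio exists; out-of-band values are flagged,
    # not suppressed (no clamping of n < 1 or alpha < 0 either)
    alpha = np.full(spec_s.nu.size, np.nan)
    ok = (spec_r.magnitude > 0) & (n > 0)
    alpha[ok] = absorption_coefficient(
        spec_s.magnitude[ok], spec_r.magnitude[ok], n[ok], d_mm
    )
    meta = {
        "window": window,
        "pad_factor": pad_factor,
        "anchor_band_thz": list(anchor_band_thz),
        "floor_db": floor_db,
        "d_mm": d_mm,
        "reference_convention": "matched reference path (empty holder or solvent-filled cell)",
    }
    return OpticalConstants(nu=spec_s.nu, n=n, alpha_cm=alpha, band=band, meta=meta)
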