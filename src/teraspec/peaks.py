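"""Absorption-peak detection and physical consistency checks.

Peaks are local maxima of the in-band absorption coefficient with a
relative prominence threshold, optionally after a rolling-minimum
baseline subtraction (needed for solution spectra riding on the water
background). Two causality checks accompany detection: anomalous
dispersion (n falling with frequency across each absorption line) and a
Kramers-Kronig reconstruction of n from alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .errors import InsufficientDataError, ValidationError
from .extract import OpticalConstants

DEFAULT_MIN_PROMINENCE_FRAC = 0.05
ROLLING_BASELINE_WINDOW_THZ = 0.4
C_CM_PER_S = 2.99792458e10


@dataclass(frozen=True)
class Peak:
    """A detected or literature absorption peak.

    ``center`` in THz; ``height`` (above local baseline) and
    ``prominence`` in cm^-1; ``fwhm`` in THz.
    """

    center: float
    height: float = float("nan")
    prominence: float = float("nan")
    fwhm: float = float("nan")


@dataclass(frozen=True)
class PeakSet:
    """An ordered list of peaks with provenance.

    ``source`` is one of {"extracted", "literature", "dft"}; ``label``
    free text (units of non-THz literature lists go here).
    """

    peaks: tuple[Peak, ...]
    source: str = "extracted"
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(self.peaks))
        centers = self.centers
        if centers.size > 1 and np.any(np.diff(centers) < 1e-6):
            raise ValidationError("peak centers must be strictly increasing (sep >= 1e-6 THz)")

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)

    @classmethod
    def from_centers(cls, centers, source: str = "literature", label: str = "") -> "PeakSet":
        return cls(peaks=tuple(Peak(center=float(c)) for c in sorted(centers)),
                   source=source, label=label)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the three points around index i."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    h = float(x[i + 1] - x[i])
    return float(x[i] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def rolling_min_baseline(alpha: np.ndarray, nu: np.ndarray,
                         window_thz: float = ROLLING_BASELINE_WINDOW_THZ) -> np.ndarray:
    """Rolling-minimum baseline estimate of a spectrum on a uniform grid."""
    dnu = float(nu[1] - nu[0])
    size = max(3, int(round(window_thz / dnu)) | 1)  # odd window
    return scipy.ndimage.minimum_filter1d(alpha, size=size, mode="nearest")


def detect_peaks(oc: OpticalConstants,
                 min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
                 baseline: str = "none",
                 baseline_window_thz: float = ROLLING_BASELINE_WINDOW_THZ) -> PeakSet:
    """Detect absorption peaks inside the validity band.

    Local maxima of alpha with prominence >= ``min_prominence_frac``
    times the in-band maximum of the (baseline-corrected) spectrum.
    ``baseline="rolling_min"`` subtracts a rolling-minimum envelope
    first — required for solution spectra, where the water background
    otherwise dominates the prominence scale. Centers are refined by
    parabolic interpolation through the three points around each
    maximum, so detection is invariant to rescaling alpha by a positive
    constant.
    """
    if not (0 < min_prominence_frac < 1):
        raise ValidationError("min_prominence_frac must be in (0, 1)")
    if baseline not in ("none", "rolling_min"):
        raise ValidationError("baseline must be 'none' or 'rolling_min'")

    inb = oc.in_band
    nu = oc.nu[inb]
    alpha = oc.alpha_cm[inb].copy()
    if nu.size < 3:
        raise InsufficientDataError("validity band too narrow for peak detection")
    alpha[~np.isfinite(alpha)] = 0.0
    if baseline == "rolling_min":
        alpha = alpha - rolling_min_baseline(alpha, nu, baseline_window_thz)

    peak_max = float(np.max(alpha))
    if peak_max <= 0:
        return PeakSet(peaks=(), source="extracted", label="")
    threshold = min_prominence_frac * peak_max
    idx, props = scipy.signal.find_peaks(alpha, prominence=threshold)
    if idx.size == 0:
        return PeakSet(peaks=(), source="extracted", label="")
    widths, _, _, _ = scipy.signal.peak_widths(alpha, idx, rel_height=0.5)
    dnu = float(nu[1] - nu[0])

    peaks = []
    for k, i in enumerate(idx):
        center, height = _parabolic_refine(nu, alpha, int(i))
        peaks.append(Peak(center=center, height=height,
                          prominence=float(props["prominences"][k]),
                          fwhm=float(widths[k] * dnu)))
    peaks.sort(key=lambda p: p.center)
    return PeakSet(peaks=tuple(peaks), source="extracted", label="")


# ---------------------------------------------------------------------------
# anomalous dispersion
# ---------------------------------------------------------------------------

def anomalous_dispersion_flags(oc: OpticalConstants, ps: PeakSet,
                               window_thz: float | None = None) -> list[bool | None]:
    """Per-peak flag: does n fall with frequency across the peak?

    For each peak the least-squares slope of n over
    [center - w, center + w] is computed; the flag is True iff the slope
    is negative. ``w`` defaults to each peak's fwhm/2 with a floor of
    0.02 THz. A peak whose window sticks out of the validity band is
    skipped (flag None).
    """
    if window_thz is not None and not window_thz > 0:
        raise ValidationError("window_thz must be positive")
    flags: list[bool | None] = []
    lo, hi = oc.band
    for p in ps.peaks:
        w = window_thz if window_thz is not None else max(p.fwhm / 2.0, 0.02)
        if not np.isfinite(w):
            w = 0.02
        if p.center - w < lo or p.center + w > hi:
            flags.append(None)
            continue
        m = (oc.nu >= p.center - w) & (oc.nu <= p.center + w)
        slope = np.polyfit(oc.nu[m], oc.n[m], 1)[0]
        flags.append(bool(slope < 0))
    return flags


# ---------------------------------------------------------------------------
# Kramers-Kronig consistency
# ---------------------------------------------------------------------------

def kk_refractive_index(oc: OpticalConstants, n_inf: float | None = None) -> np.ndarray:
    """Refractive index reconstructed from alpha by Kramers-Kronig.

    n_KK(nu) = n_inf + (c / 2 pi^2) * P-int alpha(nu') / (nu'^2 - nu^2) dnu'

    evaluated over the validity band by the Maclaurin (alternating-
    point) principal-value quadrature: the integrand is summed at grid
    points of parity opposite to the evaluation point with weight
    2*h, so the singular point is never sampled. The integral is
    truncated to the band, a known bias quantified by the package's
    self-convergence tests. ``n_inf`` defaults to the extracted n at the
    high-frequency band edge. Returns values on the in-band grid points
    (NaN outside).
    """
    inb = oc.in_band
    nu = oc.nu[inb]
    if nu.size < 10:
        raise InsufficientDataError("band narrower than 10 grid points")
    alpha = np.nan_to_num(oc.alpha_cm[inb], nan=0.0)
    if n_inf is None:
        n_inf = float(oc.n[inb][-1])
    if n_inf < 1:
        raise ValidationError("n_inf must be >= 1")

    h_hz = float(nu[1] - nu[0]) * 1e12
    nu_hz = nu * 1e12
    alpha_m = alpha * 100.0  # cm^-1 -> m^-1
    c = 2.99792458e8

    n_kk = np.empty(nu.size)
    parity = np.arange(nu.size) % 2
    # chunked evaluation keeps the (N x N) difference matrix small
    chunk = 512
    for s in range(0, nu.size, chunk):
        sl = slice(s, min(s + chunk, nu.size))
        denom = nu_hz[None, :] ** 2 - nu_hz[sl, None] ** 2
        mask = (parity[None, :] != parity[sl, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(mask, alpha_m[None, :] / denom, 0.0)
        n_kk[sl] = n_inf + (c / (2.0 * np.pi**2)) * integrand.sum(axis=1) * 2.0 * h_hz

    out = np.full(oc.nu.size, np.nan)
    out[inb] = n_kk
    return out
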