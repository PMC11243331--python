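"""Synthetic THz-TDS measurement generator.

Builds single-cycle reference pulses and propagates them through model
media — pressed tablets described by a constant background permittivity
plus Lorentz oscillators, and thin liquid layers described by a
double-Debye water background linearly mixed with a dissolved solute —
so that the extraction, peak-analysis and concentration-series stages
can be exercised without an instrument.

Conventions (frozen package-wide):

* time in picoseconds, frequency in THz, thickness in millimetres at the
  API surface; SI internally where it matters;
* spectra follow the e^{-i omega t} forward-transform sign, the one
  `numpy.fft` implements, so a pure delay multiplies the spectrum by
  e^{-i omega tau};
* the dielectric function is built in the physics convention
  Im eps >= 0 (passive, absorbing medium) and conjugated once at the
  propagation step to match the transform sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateMediumError, ValidationError

C_MM_PS = 0.299792458  # speed of light, mm/ps (== um/fs == m/ns)

#: Double-Debye parameters for liquid water at room temperature
#: (static / intermediate / high-frequency permittivity, slow and fast
#: relaxation times). Frozen here for reproducibility; any parameter set
#: with water's strong broadband THz absorption would serve.
WATER_DOUBLE_DEBYE = {
    "eps_static": 78.36,
    "eps_intermediate": 4.93,
    "eps_inf_w": 2.50,
    "tau1_ps": 8.24,
    "tau2_ps": 0.18,
}

#: Solute mass density used to map concentration (g/mL) to volume
#: fraction: phi = c / RHO_SOLUTE_G_PER_ML, linear mixing.
RHO_SOLUTE_G_PER_ML = 1.5

# Default pulse parameters: 2048 samples at 20 fs step give a 41 ps
# record — long enough for the slab delay and the resonant ringdown,
# short enough that broadband noise stays well below the signal across
# the band — and a 0.10 ps wide Gaussian-derivative cycle puts usable
# dynamic range across 0.2-2.6 THz.
DEFAULT_N_POINTS = 2048
DEFAULT_DT_PS = 0.02
DEFAULT_T0_PS = 5.0
DEFAULT_WIDTH_PS = 0.10
DEFAULT_SNR = 1000.0
DEFAULT_SEED = 42

# Oscillator damping defaults: sharp crystalline resonances for pressed
# tablets, broader lines for the dynamic liquid environment.
GAMMA_SOLID_THZ = 0.05
GAMMA_SOLUTION_THZ = 0.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeTrace:
    """A sampled electric-field transient.

    Attributes
    ----------
    t : ndarray
        Time axis, picoseconds, uniformly spaced.
    e : ndarray
        Field amplitude, arbitrary units.
    label : str
        Free-text description.
    d_mm : float or None
        Sample thickness traversed, millimetres (None for references).
    seed : int or None
        Noise seed used, if any.
    """

    t: np.ndarray
    e: np.ndarray
    label: str = ""
    d_mm: float | None = None
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "e", e)
        if t.ndim != 1 or t.size < 64:
            raise ValidationError("time axis must be 1-D with at least 64 samples")
        if e.shape != t.shape:
            raise ValidationError("t and e must have the same length")
        dt = np.diff(t)
        if dt.size == 0 or dt[0] <= 0:
            raise ValidationError("time axis must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * abs(dt[0]):
            raise ValidationError("time axis must be uniform (relative jitter < 1e-9)")
        if not np.all(np.isfinite(e)):
            raise ValidationError("field contains non-finite values")

    @property
    def dt_ps(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class LorentzOscillator:
    """A damped resonance contributing s*nu0^2/(nu0^2 - nu^2 - i*gamma*nu)
    to the relative permittivity.

    nu0 and gamma in THz; strength dimensionless. gamma < nu0 is required
    so the resonance is underdamped and produces a distinct absorption peak.
    """

    nu0: float
    strength: float
    gamma: float

    def __post_init__(self):
        if not (self.nu0 > 0 and self.strength > 0 and self.gamma > 0):
            raise ValidationError("nu0, strength and gamma must all be positive")
        if not self.gamma < self.nu0:
            raise ValidationError(
                f"gamma ({self.gamma}) must be < nu0 ({self.nu0}) for an underdamped resonance"
            )


@dataclass(frozen=True)
class MaterialModel:
    """Complex dielectric function: background + Lorentz oscillators.

    Without a solvent the background is the constant ``eps_inf``. With a
    solvent, the background is a linear volume-fraction mix of the
    double-Debye solvent permittivity and the solute's ``eps_inf``:
    (1 - phi) * eps_Debye(nu) + phi * eps_inf.
    """

    eps_inf: float
    oscillators: tuple[LorentzOscillator, ...] = ()
    solvent: dict | None = None
    solute_volume_fraction: float | None = None
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "oscillators", tuple(self.oscillators))
        if self.eps_inf < 1.0:
            raise ValidationError("eps_inf must be >= 1")
        if (self.solvent is None) != (self.solute_volume_fraction is None):
            raise ValidationError(
                "solute_volume_fraction must be given exactly when a solvent is present"
            )
        if self.solute_volume_fraction is not None and not (
            0.0 <= self.solute_volume_fraction <= 1.0
        ):
            raise ValidationError("solute_volume_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SampleGeometry:
    """Propagation path through the material."""

    d_mm: float
    kind: str = "tablet"  # {"tablet", "liquid_cell"}

    def __post_init__(self):
        if self.d_mm <= 0:
            raise ValidationError("thickness must be positive")
        if self.kind not in ("tablet", "liquid_cell"):
            raise ValidationError(f"unknown geometry kind {self.kind!r}")


# ---------------------------------------------------------------------------
# pulse synthesis
# ---------------------------------------------------------------------------

def generate_reference_pulse(
    n_points: int = DEFAULT_N_POINTS,
    dt_ps: float = DEFAULT_DT_PS,
    t0_ps: float = DEFAULT_T0_PS,
    width_ps: float = DEFAULT_WIDTH_PS,
    snr: float = DEFAULT_SNR,
    seed: int | None = DEFAULT_SEED,
) -> TimeTrace:
    """Synthesize a single-cycle THz reference pulse.

    The pulse is the first derivative of a Gaussian,
    e(t) = -(t-t0)/w * exp(-(t-t0)^2 / (2 w^2)), normalised to unit peak
    amplitude, with additive zero-mean Gaussian noise of standard
    deviation max|e| / snr. ``snr=inf`` disables noise. Identical
    arguments (including seed) give bit-identical traces.
    """
    if n_points < 64:
        raise ValidationError("n_points must be >= 64")
    if dt_ps <= 0:
        raise ValidationError("dt_ps must be positive")
    if not (0 < width_ps < n_points * dt_ps):
        raise ValidationError("width_ps must be positive and shorter than the record")
    if not snr > 0:
        raise ValidationError("snr must be positive")

    t = np.arange(n_points) * dt_ps
    x = (t - t0_ps) / width_ps
    e = -x * np.exp(-0.5 * x * x)
    e /= np.max(np.abs(e))
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        e = e + rng.normal(0.0, 1.0 / snr, size=n_points)
    return TimeTrace(t=t, e=e, label="reference", seed=seed)


def add_noise(trace: TimeTrace, snr: float, seed: int | None) -> TimeTrace:
    """Return a copy of ``trace`` with additive white Gaussian noise of
    standard deviation max|e|/snr (no-op for infinite snr)."""
    if not snr > 0:
        raise ValidationError("snr must be positive")
    if not np.isfinite(snr):
        return replace(trace, seed=seed)
    rng = np.random.default_rng(seed)
    sigma = np.max(np.abs(trace.e)) / snr
    return replace(trace, e=trace.e + rng.normal(0.0, sigma, trace.e.size), seed=seed)


# ---------------------------------------------------------------------------
# dielectric function
# ---------------------------------------------------------------------------

def _debye(params: dict, nu: np.ndarray) -> np.ndarray:
    """Double-Debye permittivity, physics convention (Im eps >= 0)."""
    w = 2.0 * math.pi * nu  # rad/ps when nu in THz
    d1 = params["eps_static"] - params["eps_intermediate"]
    d2 = params["eps_intermediate"] - params["eps_inf_w"]
    return (
        params["eps_inf_w"]
        + d1 / (1.0 - 1j * w * params["tau1_ps"])
        + d2 / (1.0 - 1j * w * params["tau2_ps"])
    )


def permittivity(model: MaterialModel, nu: np.ndarray) -> np.ndarray:
    """Evaluate the complex relative permittivity on a THz frequency grid.

    eps(nu) = background(nu) + sum_k s_k nu0k^2 / (nu0k^2 - nu^2 - i gamma_k nu)

    where background is ``eps_inf`` or, with a solvent, the linear
    volume-fraction mix (1-phi)*eps_Debye + phi*eps_inf. Im eps >= 0
    everywhere on nu > 0 (passive medium).
    """
    nu = np.asarray(nu, dtype=float)
    if nu.size == 0:
        raise ValidationError("frequency grid is empty")
    if np.any(nu <= 0):
        raise ValidationError("frequencies must be positive")

    if model.solvent is not None:
        phi = model.solute_volume_fraction
        eps = (1.0 - phi) * _debye(model.solvent, nu) + phi * model.eps_inf
    else:
        eps = np.full(nu.shape, model.eps_inf, dtype=complex)
    for osc in model.oscillators:
        eps = eps + osc.strength * osc.nu0**2 / (
            osc.nu0**2 - nu**2 - 1j * osc.gamma * nu
        )
    return eps


def refractive_index_model(model: MaterialModel, nu: np.ndarray) -> np.ndarray:
    """Complex refractive index sqrt(eps) with Im >= 0 (physics branch)."""
    n = np.sqrt(permittivity(model, nu))
    # principal sqrt already lands in the upper half plane for Im eps >= 0,
    # but guard the Im eps == 0, Re eps > 0 axis against -0.0 artefacts
    return np.where(n.imag < 0, -n, n)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def transmission(model: MaterialModel, geom: SampleGeometry, nu: np.ndarray) -> np.ndarray:
    """Single-pass field transmission coefficient on a THz grid.

    T(nu) = 4 n~ / (n~+1)^2 * exp(-i (n~*-1) omega d / c) in the
    e^{-i omega t} spectral convention (n~* the conjugate of the
    physics-branch index, so the wave is delayed and attenuated). No
    Fabry-Perot echo terms. For a liquid cell the reference arm is the
    matched empty/solvent-filled chip, so window interfaces cancel and
    only the layer itself appears here.
    """
    nref = refractive_index_model(model, nu)
    if np.any(nref.real < 1e-6):
        raise DegenerateMediumError("model refractive index is degenerate (Re n ~ 0)")
    n_eng = np.conj(nref)  # engineering sign to match e^{-i omega t}
    w = 2.0 * math.pi * nu  # rad/ps
    fresnel = 4.0 * n_eng / (n_eng + 1.0) ** 2
    return fresnel * np.exp(-1j * (n_eng - 1.0) * w * geom.d_mm / C_MM_PS)


def transmit(reference: TimeTrace, model: MaterialModel, geom: SampleGeometry) -> TimeTrace:
    """Propagate a reference trace through a sample slab.

    The reference spectrum is multiplied by the single-pass transmission
    and returned in the time domain on the reference time axis.
    """
    n = reference.t.size
    dt = reference.dt_ps
    spec = np.fft.rfft(reference.e)
    nu = np.fft.rfftfreq(n, dt)  # THz
    t_coef = np.ones(nu.size, dtype=complex)
    t_coef[1:] = transmission(model, geom, nu[1:])
    # DC: Fresnel factor at the zero-frequency index (real, phase-free)
    n0 = refractive_index_model(model, np.array([min(1e-6, nu[1] if nu.size > 1 else 1e-6)]))[0]
    t_coef[0] = (4.0 * n0 / (n0 + 1.0) ** 2).real
    e_out = np.fft.irfft(spec * t_coef, n=n)
    label = f"{reference.label}|{model.label or 'sample'}"
    return TimeTrace(t=reference.t.copy(), e=e_out, label=label, d_mm=geom.d_mm, seed=reference.seed)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _solid(nu0s: Sequence[float], strengths: Sequence[float], eps_inf: float,
           d_mm: float, label: str) -> tuple[MaterialModel, SampleGeometry]:
    osc = tuple(
        LorentzOscillator(nu0=f, strength=s, gamma=GAMMA_SOLID_THZ)
        for f, s in zip(nu0s, strengths)
    )
    return (
        MaterialModel(eps_inf=eps_inf, oscillators=osc, label=label),
        SampleGeometry(d_mm=d_mm, kind="tablet"),
    )


def _solution(nu0s: Sequence[float], strengths: Sequence[float], eps_inf: float,
              phi: float, label: str) -> tuple[MaterialModel, SampleGeometry]:
    osc = tuple(
        LorentzOscillator(nu0=f, strength=s, gamma=GAMMA_SOLUTION_THZ)
        for f, s in zip(nu0s, strengths)
    )
    return (
        MaterialModel(
            eps_inf=eps_inf,
            oscillators=osc,
            solvent=dict(WATER_DOUBLE_DEBYE),
            solute_volume_fraction=phi,
            label=label,
        ),
        SampleGeometry(d_mm=0.050, kind="liquid_cell"),
    )


# Peak centres are the reported experimental lists; strengths are
# calibrated so the model's refractive index stays inside the reported
# ranges (mannitol 1.40-1.45, erythritol 1.30-1.40) over 0.5-2.6 THz,
# with the 1.23 THz mannitol feature deliberately weak.
# Strengths scale as 1/nu0 so each line produces a comparable
# refractive-index swing (the swing goes as s*nu0/gamma while the
# absorption peak goes as s*nu0^2/gamma, favouring the high-frequency
# lines in alpha just as the measured spectra do); the 1.23 THz
# mannitol feature is deliberately weak.
_MANNITOL_SOLID_NU0 = (0.94, 1.23, 1.73, 1.96, 2.17, 2.43)
_MANNITOL_SOLID_S = (0.00425, 0.00114, 0.00231, 0.00204, 0.00184, 0.00165)
_ERYTHRITOL_SOLID_NU0 = (1.81, 1.96, 2.02, 2.43)
_ERYTHRITOL_SOLID_S = (0.00276, 0.00255, 0.00248, 0.00206)
# Solution lists: solid-correlated peaks plus the solution-only features
# (mannitol 2.25; erythritol 1.51, 1.73), broadened for the liquid phase.
_MANNITOL_SOLN_NU0 = (0.98, 1.46, 1.84, 1.96, 2.13, 2.25, 2.43)
_MANNITOL_SOLN_S = (0.020, 0.016, 0.014, 0.012, 0.012, 0.012, 0.012)
_ERYTHRITOL_SOLN_NU0 = (1.51, 1.73, 1.82, 1.96, 2.16, 2.50)
_ERYTHRITOL_SOLN_S = (0.016, 0.015, 0.018, 0.014, 0.013, 0.012)

_PHI_1G_PER_ML = 1.0 / RHO_SOLUTE_G_PER_ML


def preset(name: str) -> tuple[MaterialModel, SampleGeometry]:
    """Return the packaged (MaterialModel, SampleGeometry) for a named sample.

    Available: ``mannitol_solid`` (six oscillators incl. the weak 1.23 THz
    feature), ``mannitol_solid_fig3`` (the five-peak reading),
    ``erythritol_solid``, ``mannitol_solution``, ``erythritol_solution``
    (1 g/mL in the 50 um cell), ``water`` (pure solvent, no oscillators).
    """
    if name == "mannitol_solid":
        return _solid(_MANNITOL_SOLID_NU0, _MANNITOL_SOLID_S, 1.42**2, 1.11, name)
    if name == "mannitol_solid_fig3":
        nu0 = tuple(f for f in _MANNITOL_SOLID_NU0 if f != 1.23)
        s = tuple(s for f, s in zip(_MANNITOL_SOLID_NU0, _MANNITOL_SOLID_S) if f != 1.23)
        return _solid(nu0, s, 1.42**2, 1.11, name)
    if name == "erythritol_solid":
        return _solid(_ERYTHRITOL_SOLID_NU0, _ERYTHRITOL_SOLID_S, 1.35**2, 1.15, name)
    if name == "mannitol_solution":
        return _solution(_MANNITOL_SOLN_NU0, _MANNITOL_SOLN_S, 1.42**2, _PHI_1G_PER_ML, name)
    if name == "erythritol_solution":
        return _solution(_ERYTHRITOL_SOLN_NU0, _ERYTHRITOL_SOLN_S, 1.35**2, _PHI_1G_PER_ML, name)
    if name == "water":
        return (
            MaterialModel(
                eps_inf=1.0,
                oscillators=(),
                solvent=dict(WATER_DOUBLE_DEBYE),
                solute_volume_fraction=0.0,
                label=name,
            ),
            SampleGeometry(d_mm=0.050, kind="liquid_cell"),
        )
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = (
    "mannitol_solid",
    "mannitol_solid_fig3",
    "erythritol_solid",
    "mannitol_solution",
    "erythritol_solution",
    "water",
)
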