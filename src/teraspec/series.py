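"""Concentration-series analysis for microfluidic solution measurements.

Simulates a set of liquid-cell measurements across solute
concentrations and quantifies the relationship between concentration
and raw time-domain signal strength. The physical mechanism: the
solute is far less absorbing than water in the THz band, so raising the
concentration displaces water, lowers the layer's absorption and
enhances the transmitted signal. By design this module reports raw
signal metrics, not absorption coefficients — the water background
makes per-concentration alpha comparisons unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.stats

from .errors import InsufficientDataError, ValidationError
from .forward import (
    RHO_SOLUTE_G_PER_ML,
    MaterialModel,
    SampleGeometry,
    TimeTrace,
    add_noise,
    generate_reference_pulse,
    preset,
    transmit,
)

#: Default series: five equally spaced concentrations, g/mL.
DEFAULT_CONCENTRATIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Traces and signal strengths across a concentration gradient."""

    concentrations: tuple[float, ...]
    traces: tuple[TimeTrace, ...]
    strengths: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        if not (len(self.concentrations) == len(self.traces) == len(self.strengths)):
            raise ValidationError("concentrations, traces and strengths must align")


def concentration_to_volume_fraction(c_g_per_ml: float) -> float:
    """Map concentration (g/mL) to solute volume fraction, linear mixing."""
    if not 0.0 <= c_g_per_ml <= RHO_SOLUTE_G_PER_ML:
        raise ValidationError("concentration outside the physical range")
    return c_g_per_ml / RHO_SOLUTE_G_PER_ML


def model_at_concentration(solution_model: MaterialModel, c_g_per_ml: float) -> MaterialModel:
    """Rescale a 1 g/mL solution model to another concentration.

    The solute volume fraction follows the linear mixing rule and the
    oscillator strengths scale proportionally with concentration (they
    are proportional to the number density of solute molecules).
    """
    if solution_model.solvent is None:
        raise ValidationError("model has no solvent; not a solution model")
    phi = concentration_to_volume_fraction(c_g_per_ml)
    scale = c_g_per_ml / 1.0
    osc = tuple(replace(o, strength=o.strength * scale) for o in solution_model.oscillators
                if o.strength * scale > 0) if scale > 0 else ()
    return replace(solution_model, oscillators=osc, solute_volume_fraction=phi)


def signal_strength(trace: TimeTrace) -> float:
    """Peak-to-peak amplitude of the time-domain field, max(e) - min(e)."""
    return float(np.max(trace.e) - np.min(trace.e))


def spectral_strength(trace: TimeTrace, band_thz: tuple[float, float] = (0.2, 2.6)) -> float:
    """Alternative metric: integrated spectral magnitude over a band."""
    spec = np.fft.rfft(trace.e)
    nu = np.fft.rfftfreq(trace.t.size, trace.dt_ps)
    m = (nu >= band_thz[0]) & (nu <= band_thz[1])
    return float(np.trapezoid(np.abs(spec[m]), nu[m]))


def simulate_series(
    solute_preset: str,
    concentrations=DEFAULT_CONCENTRATIONS,
    snr: float = 1000.0,
    seed: int = 42,
    n_points: int | None = None,
    metric: str = "time_ptp",
) -> ConcentrationSeries:
    """Simulate one liquid-cell measurement per concentration.

    All concentrations share one noise-free incident pulse (the
    empty-chip reference path); each transmitted trace then receives
    independent but reproducible noise — child seeds are spawned from
    ``seed`` so adding a concentration never perturbs the others'
    noise. Concentration 0 reduces exactly to the pure-water layer.
    """
    conc = tuple(float(c) for c in concentrations)
    if any(not 0.0 <= c <= 1.0 for c in conc):
        raise ValidationError("concentrations must lie in [0, 1] g/mL")
    if any(c2 <= c1 for c1, c2 in zip(conc, conc[1:])):
        raise ValidationError("concentrations must be strictly increasing")
    if metric not in ("time_ptp", "spectral"):
        raise ValidationError("metric must be 'time_ptp' or 'spectral'")

    model_1g, geom = preset(solute_preset)
    if model_1g.solvent is None:
        raise ValidationError(f"preset {solute_preset!r} is not a solution preset")
    kwargs = {"snr": math.inf, "seed": None}
    if n_points is not None:
        kwargs["n_points"] = n_points
    ref = generate_reference_pulse(**kwargs)

    child_seeds = np.random.SeedSequence(seed).generate_state(len(conc)) % (2**31)
    traces, strengths = [], []
    metric_fn = signal_strength if metric == "time_ptp" else spectral_strength
    for c, s in zip(conc, child_seeds):
        model_c = model_at_concentration(model_1g, c)
        tr = transmit(ref, model_c, geom)
        tr = add_noise(tr, snr, int(s))
        tr = replace(tr, label=f"{solute_preset} {c:g} g/mL")
        traces.append(tr)
        strengths.append(metric_fn(tr))
    return ConcentrationSeries(
        concentrations=conc, traces=tuple(traces), strengths=tuple(strengths),
        label=solute_preset,
    )


def strength_concentration_relation(series: ConcentrationSeries) -> dict:
    """Spearman rank correlation between concentration and strength.

    Returns ``{"spearman_rho", "monotone", "slope_sign"}``; ``monotone``
    is True iff the strengths are strictly increasing, ``slope_sign``
    the sign of the least-squares slope.
    """
    if len(series.concentrations) < 3:
        raise InsufficientDataError("need at least 3 concentrations")
    c = np.asarray(series.concentrations)
    s = np.asarray(series.strengths)
    rho = scipy.stats.spearmanr(c, s).statistic
    slope = np.polyfit(c, s, 1)[0]
    return {
        "spearman_rho": float(rho),
        "monotone": bool(np.all(np.diff(s) > 0)),
        "slope_sign": int(np.sign(slope)),
    }
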