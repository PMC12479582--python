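"""Time-domain SRP traces, lock-in demodulation, and modulation sweeps.

The optical readout is quasi-static: thermal timescales (>= tens of ns) are
many orders slower than the optical transit, so the collected probe power at
any instant is the steady propagation result for the instantaneous lens. In
the small-phase regime (probe phase ~0.02 rad here) the collected power is
linear in the lens amplitude, so the default trace evaluation maps the
focal-center temperature waveform through a precomputed sensitivity
(relative contrast per kelvin) instead of re-propagating per sample; full
per-snapshot propagation is available via ``optics="full"``.

Demodulation amplitude convention: peak amplitude of the fundamental (a pure
A*sin(2*pi*f*t + phi) demodulates to amplitude A, not A/sqrt(2)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import ExcitationParams, FocalVolume, MediumProps, ProbeGeometry
from .physics import (
    energy_per_pulse_pair,
    index_field,
    periodic_temperature_waveform,
    temperature_field,
)

__all__ = [
    "TimeTrace",
    "NoiseModel",
    "lens_sensitivity",
    "srp_time_trace",
    "demodulate",
    "ModulationMap",
    "duty_frequency_map",
]


@dataclass
class TimeTrace:
    """Uniformly sampled detected-power trace under square-wave modulation."""

    times: np.ndarray
    values: np.ndarray
    mod_freq: float
    duty: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("sampling must be uniform")
        if dt.size:
            per_period = 1.0 / (self.mod_freq * dt[0])
            if per_period < 32 - 1e-9:
                raise ValueError(
                    f"{per_period:.1f} samples per modulation period; need >= 32"
                )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class NoiseModel:
    """Detector/probe noise amplitude model: white floor plus 1/f.

    The RMS noise amplitude referred to the demodulation output at reference
    frequency f and equivalent noise bandwidth B is

        sigma(f) = scale * white_floor * sqrt(B) * sqrt(1 + knee / f).

    The knee mirrors the probe laser's excess low-frequency noise; it is an
    instrument property, not a physics prediction.
    """

    white_floor: float = 1e-6  # power / sqrt(Hz), same units as the trace
    one_over_f_knee: float = 600e3  # Hz
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.white_floor < 0 or self.one_over_f_knee < 0:
            raise ValueError("white_floor and knee must be >= 0")

    def amplitude(self, f: float, bandwidth: float = 1.0) -> float:
        if f <= 0:
            raise ValueError("noise amplitude needs f > 0")
        return (
            self.scale
            * self.white_floor
            * math.sqrt(bandwidth)
            * math.sqrt(1.0 + self.one_over_f_knee / f)
        )


def lens_sensitivity(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    g: ProbeGeometry,
    na: float,
    **grid_kw,
) -> tuple[float, float]:
    """(P_off within NA, relative contrast per kelvin of peak lens heating).

    Propagates the probe once through the single-deposition-event lens and
    normalizes the relative contrast by that event's peak temperature.
    """
    from .propagation import na_contrast_scan
    from .physics import single_pulse_peak

    energy = energy_per_pulse_pair(p)
    res = na_contrast_scan(
        p, f, m, g, np.array([na]), metric="relative", **grid_kw
    )
    if energy == 0.0:
        return float(res.p_off[0]), 0.0
    dT0 = single_pulse_peak(energy, f, m)
    return float(res.p_off[0]), float(res.contrast[0] / dT0)


def srp_time_trace(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    g: ProbeGeometry,
    na: float,
    n_periods: int = 4,
    *,
    n_points: int = 64,
    optics: str = "linear",
    waveform_kw: dict | None = None,
    **grid_kw,
) -> TimeTrace:
    """Collected probe power over ``n_periods`` of steady-state modulation.

    The thermal waveform is the periodic steady-state focal-center
    temperature; the lens spatial profile is frozen to the fresh-deposition
    Gaussian (the modulated part of the field is dominated by the most
    recent depositions). ``optics="full"`` re-propagates the probe for each
    temperature sample instead of using the small-signal sensitivity.
    """
    t_one, wave = periodic_temperature_waveform(
        p, f, m, n_points, **(waveform_kw or {})
    )
    if optics == "linear":
        p_off, sens = lens_sensitivity(p, f, m, g, na, **grid_kw)
        power_one = p_off * (1.0 + sens * wave)
    elif optics == "full":
        from .propagation import collected_power, _lens_far_fields
        from .physics import single_pulse_peak

        energy = energy_per_pulse_pair(p)
        if energy == 0.0:
            from .propagation import na_contrast_scan

            res = na_contrast_scan(p, f, m, g, np.array([na]),
                                   metric="relative", **grid_kw)
            power_one = np.full(n_points, res.p_off[0])
        else:
            dT0 = single_pulse_peak(energy, f, m)
            unit = _single_event_dn(p, f, m, **grid_kw)
            power_one = np.empty(n_points)
            for i, dT in enumerate(wave):
                from .fields import ScalarField3D

                dn = ScalarField3D(
                    unit.values * (dT / dT0), unit.spacing, unit.origin
                )
                ff_on, _ = _lens_far_fields(
                    dn, g, m.n0,
                    n_grid=grid_kw.get("n_grid", 256),
                    extent=grid_kw.get("extent", 15e-6),
                    pad_factor=grid_kw.get("pad_factor", 4),
                )
                power_one[i] = collected_power(ff_on, na)
    else:
        raise ValueError(f"unknown optics mode {optics!r}")
    period = 1.0 / p.mod_freq
    times = np.arange(n_points * n_periods) * (period / n_points)
    values = np.tile(power_one, n_periods)
    return TimeTrace(times, values, p.mod_freq, p.duty_cycle)


def _single_event_dn(p, f, m, *, n_z: int = 40, z_span_sigmas: float = 3.0,
                     xy_span_sigmas: float = 5.0, **_ignored):
    energy = energy_per_pulse_pair(p)
    shape = (n_z + 1, n_z + 1, n_z + 1)
    spacing = (
        2 * xy_span_sigmas * f.sigma_x / n_z,
        2 * xy_span_sigmas * f.sigma_y / n_z,
        2 * z_span_sigmas * f.sigma_z / n_z,
    )
    dT = temperature_field(p, f, m, 0.0, shape=shape, spacing=spacing,
                           energy=energy)
    return index_field(dT, m)


def demodulate(trace: TimeTrace, f_ref: float) -> tuple[float, float]:
    """Single-bin lock-in projection at ``f_ref``: (amplitude, phase).

    Uses an integer number of reference periods (the trace tail is trimmed
    with a warning otherwise) and returns the peak amplitude and phase of
    the fundamental in the sine convention
    ``x(t) ~ A * sin(2 pi f_ref t + phi)``.
    """
    n = trace.values.size
    dt = trace.dt
    total_t = n * dt
    n_per = total_t * f_ref
    if n_per < 4 - 1e-9:
        raise ValueError(
            f"trace spans {n_per:.2f} reference periods; need >= 4"
        )
    n_keep = int(round(math.floor(n_per) / (f_ref * dt)))
    if n_keep < n:
        warnings.warn(
            f"trace is {n_per:.3f} reference periods; trimming to "
            f"{math.floor(n_per):.0f} full periods",
            stacklevel=2,
        )
    x = trace.values[:n_keep]
    t = trace.times[:n_keep]
    c = 2.0 / n_keep * np.sum(x * np.exp(-2j * math.pi * f_ref * t))
    amplitude = float(np.abs(c))
    phase = float(np.angle(c)) + math.pi / 2.0
    phase = (phase + math.pi) % (2.0 * math.pi) - math.pi
    return amplitude, phase


@dataclass
class ModulationMap:
    """Demodulated signal and SNR over a (duty, modulation-frequency) grid."""

    duty_grid: np.ndarray
    freq_grid: np.ndarray
    signal: np.ndarray  # [i_duty, j_freq]
    snr: np.ndarray
    best_signal: tuple[float, float]  # (duty, mod_freq) maximizing the signal
    best_snr: tuple[float, float]  # (duty, mod_freq) maximizing the SNR


def duty_frequency_map(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    g: ProbeGeometry,
    na: float,
    duty_grid: np.ndarray,
    freq_grid: np.ndarray,
    noise: NoiseModel | None = None,
    *,
    n_points: int = 64,
    waveform_kw: dict | None = None,
    **grid_kw,
) -> ModulationMap:
    """Sweep duty cycle and modulation frequency at fixed laser peak power.

    Peak power is held fixed: the per-pulse deposited energy is identical at
    every duty cycle and only the gating changes, which is the comparison
    mode of a peak-power-limited fiber laser. The demodulated fundamental of
    the thermal square-wave response is proportional to sin(pi * duty) for
    an LTI medium, so the sweep peaks at 50% duty.
    """
    duty_grid = np.asarray(duty_grid, dtype=float)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if duty_grid.size == 0 or freq_grid.size == 0:
        raise ValueError("duty_grid and freq_grid must be non-empty")
    noise = noise or NoiseModel()
    p_off, sens = lens_sensitivity(p, f, m, g, na, **grid_kw)
    signal = np.empty((duty_grid.size, freq_grid.size))
    snr = np.empty_like(signal)
    for i, d in enumerate(duty_grid):
        for j, fm in enumerate(freq_grid):
            pp = p.replace(duty_cycle=float(d), mod_freq=float(fm))
            _, wave = periodic_temperature_waveform(
                pp, f, m, n_points, **(waveform_kw or {})
            )
            power = p_off * (1.0 + sens * wave)
            period = 1.0 / fm
            times = np.arange(n_points * 4) * (period / n_points)
            trace = TimeTrace(times, np.tile(power, 4), fm, float(d))
            amp, _ = demodulate(trace, fm)
            signal[i, j] = amp
            snr[i, j] = amp / noise.amplitude(float(fm))
    i0, j0 = np.unravel_index(int(np.argmax(signal)), signal.shape)
    i1, j1 = np.unravel_index(int(np.argmax(snr)), snr.shape)
    return ModulationMap(
        duty_grid, freq_grid, signal, snr,
        best_signal=(float(duty_grid[i0]), float(freq_grid[j0])),
        best_snr=(float(duty_grid[i1]), float(freq_grid[j1])),
    )
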