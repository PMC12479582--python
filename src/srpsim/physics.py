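"""SRS energy deposition and thermal-lens temperature fields.

The heat source is the vibrational energy left in the sample by stimulated
Raman scattering: each pump/Stokes pulse pair converts pump photons to Stokes
photons, and the energy difference (the Raman-shift quantum per converted
photon) thermalizes at the focus. Each deposition event is treated as an
instantaneous 3D Gaussian source (the picosecond pulse is far shorter than
any thermal timescale), which evolves under free diffusion in an infinite
homogeneous medium:

    dT(r, tau) = E / (rho c (2 pi)^{3/2} sx sy sz) * exp(-sum r_i^2 / 2 s_i^2),
    s_i^2(tau) = sigma_i0^2 + 2 D tau,   D = k / (rho c).

Pulse trains superpose linearly; modulation gates which pulses fire.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np

from .fields import ScalarField3D
from .params import ExcitationParams, FocalVolume, MediumProps

__all__ = [
    "energy_per_pulse_pair",
    "single_pulse_peak",
    "pulse_times",
    "temperature_field",
    "peak_temperature",
    "periodic_temperature_waveform",
    "index_field",
]

_TWO_PI_32 = (2.0 * math.pi) ** 1.5


def energy_per_pulse_pair(p: ExcitationParams, f_on: float | None = None) -> float:
    """Heat deposited per pump/Stokes pulse pair during the on state, in J.

    The lock-in-referred SRS modulation depth ``md`` on the pump reports the
    fundamental of a square-wave pump loss; for 50%-duty modulation the
    fractional pump loss while the Stokes is on is ``f_on = 2 * md``. Only
    the vibrational quantum stays in the sample, so the deposited fraction
    of the lost pump energy is ``raman_shift / pump_wavenumber``.

    Parameters
    ----------
    p : ExcitationParams
    f_on : float, optional
        On-state fractional pump loss. If given it overrides the
        ``2 * srs_mod_depth`` convention (useful when the loss has been
        measured directly rather than through a lock-in).
    """
    if f_on is None:
        f_on = 2.0 * p.srs_mod_depth
    if f_on < 0:
        raise ValueError("on-state pump loss must be >= 0")
    pump_wn = p.pump_wavenumber
    if p.raman_shift >= pump_wn:
        raise ValueError("raman shift must be below the pump photon wavenumber")
    pulse_energy = p.pump_power / p.rep_rate
    return f_on * pulse_energy * (p.raman_shift / pump_wn)


def single_pulse_peak(energy: float, f: FocalVolume, m: MediumProps) -> float:
    """Instantaneous peak temperature rise of one deposition event, K."""
    sx, sy, sz = f.sigmas
    return energy / (m.density * m.specific_heat * _TWO_PI_32 * sx * sy * sz)


def pulse_times(
    p: ExcitationParams,
    t: float,
    mode: Literal["burst", "modulated"] = "burst",
) -> np.ndarray:
    """Deposition times in [0, min(t, heating_duration)] (burst) or the
    modulation on-windows of [0, t] (modulated).

    ``burst`` models an unmodulated pulse train of length ``heating_duration``
    starting at t=0; ``modulated`` gates the train with the square wave
    (on-window at the start of each modulation period).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    eps = 1e-6 / p.rep_rate  # tolerance for exact-boundary pulses
    t_end = min(t, p.heating_duration) if mode == "burst" else t
    n = int(math.floor(t_end * p.rep_rate + 1e-6)) + 1
    times = np.arange(n) / p.rep_rate
    times = times[times <= t + eps]
    if mode == "modulated":
        period = 1.0 / p.mod_freq
        phase = np.mod(times, period)
        times = times[phase < p.duty_cycle * period - eps]
    return times


def _green_amplitude(
    energy: float, f: FocalVolume, m: MediumProps, tau: np.ndarray
) -> np.ndarray:
    """Peak (center) amplitude of a deposition event after delay tau >= 0."""
    two_d_tau = 2.0 * m.diffusivity * np.asarray(tau, dtype=float)
    var = [(s**2 + two_d_tau) for s in f.sigmas]
    denom = m.density * m.specific_heat * _TWO_PI_32 * np.sqrt(var[0] * var[1] * var[2])
    return energy / denom


def temperature_field(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    t: float,
    *,
    shape: tuple[int, int, int] = (65, 65, 65),
    spacing: tuple[float, float, float] | None = None,
    extent_sigmas: float = 8.0,
    pulse_mode: Literal["burst", "modulated"] = "burst",
    energy: float | None = None,
) -> ScalarField3D:
    """Temperature rise field at time ``t`` from the gated pulse train.

    The default grid spans ``extent_sigmas`` initial PSF sigmas per axis,
    centered on the focus. A per-event ``energy`` can be supplied to bypass
    the modulation-depth bookkeeping (e.g. single-pulse oracles).

    Raises if the grid is too coarse to resolve the initial PSF
    (spacing > sigma/2 on any axis).
    """
    if energy is None:
        energy = energy_per_pulse_pair(p)
    sig = f.sigmas
    if spacing is None:
        spacing = tuple(extent_sigmas * s / (n - 1) for s, n in zip(sig, shape))
    for d, s in zip(spacing, sig):
        if d > s / 2.0:
            raise ValueError(
                f"grid spacing {d:.3g} m is too coarse to resolve PSF sigma "
                f"{s:.3g} m; need spacing <= sigma/2"
            )
    origin = tuple(
        c - d * (n - 1) / 2.0 for c, d, n in zip(f.center, spacing, shape)
    )
    axes = [
        origin[i] + spacing[i] * np.arange(shape[i]) - f.center[i] for i in range(3)
    ]
    out = np.zeros(shape, dtype=float)
    times = pulse_times(p, t, mode=pulse_mode)
    if times.size == 0 or energy == 0.0:
        return ScalarField3D(out, spacing, origin, unit="K")
    rho_c = m.density * m.specific_heat
    two_d = 2.0 * m.diffusivity
    for t_k in times:
        tau = max(t - t_k, 0.0)
        var = [s**2 + two_d * tau for s in sig]
        amp = energy / (rho_c * _TWO_PI_32 * math.sqrt(var[0] * var[1] * var[2]))
        gx = np.exp(-0.5 * axes[0] ** 2 / var[0])
        gy = np.exp(-0.5 * axes[1] ** 2 / var[1])
        gz = np.exp(-0.5 * axes[2] ** 2 / var[2])
        out += amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return ScalarField3D(out, spacing, origin, unit="K")


def peak_temperature(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    t: float,
    *,
    pulse_mode: Literal["burst", "modulated"] = "burst",
    energy: float | None = None,
) -> float:
    """Focal-center temperature rise at time ``t`` (closed form, no grid)."""
    if energy is None:
        energy = energy_per_pulse_pair(p)
    times = pulse_times(p, t, mode=pulse_mode)
    if times.size == 0:
        return 0.0
    tau = np.clip(t - times, 0.0, None)
    return float(np.sum(_green_amplitude(energy, f, m, tau)))


def periodic_temperature_waveform(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    n_points: int = 128,
    *,
    rel_tol: float = 1e-3,
    max_periods: int = 4000,
    energy: float | None = None,
    n_history: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One modulation period of the focal-center temperature at steady state.

    Returns ``(times, dT)`` with ``times`` spanning [0, 1/mod_freq). The
    on-window occupies the first ``duty_cycle`` fraction of the period.
    History periods are accumulated until the waveform peak changes by less
    than ``rel_tol`` between successive periods; ``n_history`` instead fixes
    the history length exactly (no convergence check), which is mainly
    useful for cross-checking against direct pulse superposition.
    """
    if energy is None:
        energy = energy_per_pulse_pair(p)
    period = 1.0 / p.mod_freq
    t_samp = np.arange(n_points) / n_points * period
    if energy == 0.0 or p.duty_cycle == 0.0:
        return t_samp, np.zeros(n_points)
    # deposition offsets within one period's on-window
    eps = 1e-6 / p.rep_rate
    n_pp = int(math.floor(p.duty_cycle * period * p.rep_rate + 1e-6)) + 1
    offs = np.arange(n_pp) / p.rep_rate
    offs = offs[offs < p.duty_cycle * period - eps]
    wave = np.zeros(n_points)
    prev_peak = 0.0
    cap = n_history if n_history is not None else max_periods
    for n_hist in range(cap):
        # pulses fired n_hist periods before the observed one
        tau = t_samp[:, None] + n_hist * period - offs[None, :]
        # a pulse exactly at a sample time counts with tau = 0
        tau = np.where(tau > -eps, np.clip(tau, 0.0, None), np.inf)
        wave += np.sum(_green_amplitude(energy, f, m, tau), axis=1)
        peak = wave.max()
        if n_history is None and n_hist > 0 and \
                abs(peak - prev_peak) < rel_tol * peak:
            return t_samp, wave
        prev_peak = peak
    if n_history is not None:
        return t_samp, wave
    raise RuntimeError(
        f"periodic steady state not reached within {max_periods} periods "
        f"(rel_tol={rel_tol}); slow thermal decay relative to the modulation "
        "period — raise max_periods or rel_tol"
    )


def index_field(dT: ScalarField3D, m: MediumProps) -> ScalarField3D:
    """Pointwise thermo-optic conversion dn = dT * dn/dT."""
    if dT.unit not in ("K", ""):
        raise ValueError(f"expected a temperature field in K, got unit {dT.unit!r}")
    return ScalarField3D(
        dT.values * m.dn_dT, dT.spacing, dT.origin, unit=""
    )
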