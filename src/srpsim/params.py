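"""Instrument and medium parameter containers.

All quantities are SI internally (W, Hz, m, s, K). Raman shifts follow the
Raman convention and are carried in cm^-1; conversions to photon wavenumbers
happen at the point of use. Presets reflect a picosecond dual-output fiber
laser driving a 1.2-NA water-immersion objective, probed by a 765 nm CW beam
through a tunable-NA (<= 0.55) air condenser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ExcitationParams",
    "MediumProps",
    "FocalVolume",
    "ProbeGeometry",
    "DMSO",
    "WATER",
    "UREA_8M",
    "MEDIUM_PRESETS",
    "default_excitation",
    "default_focal_volume",
    "default_probe",
]


@dataclass(frozen=True)
class ExcitationParams:
    """Pump/Stokes excitation and modulation parameters.

    Parameters
    ----------
    pump_power : float
        Average pump power on sample, W. The pump is unmodulated; the SRS
        process transfers a small fraction of it per pulse to the sample.
    stokes_peak_power : float
        Peak (on-state) Stokes power, W.
    rep_rate : float
        Laser repetition rate, Hz.
    duty_cycle : float
        On-fraction of the square-wave Stokes modulation, in (0, 1].
    mod_freq : float
        Modulation (lock-in reference) frequency, Hz.
    raman_shift : float
        Targeted Raman shift, cm^-1.
    stokes_wavelength : float
        Stokes wavelength, m.
    srs_mod_depth : float
        SRS modulation depth on the pump as read by a lock-in at the
        modulation fundamental, dimensionless fraction in [0, 1).
    heating_duration : float
        Duration of the heating burst used for single-shot temperature maps, s.
    """

    pump_power: float = 28e-3
    stokes_peak_power: float = 180e-3
    rep_rate: float = 40e6
    duty_cycle: float = 0.5
    mod_freq: float = 125e3
    raman_shift: float = 2912.0
    stokes_wavelength: float = 1031e-9
    srs_mod_depth: float = 0.0072
    heating_duration: float = 8e-6

    def __post_init__(self) -> None:
        if self.pump_power < 0 or self.stokes_peak_power < 0:
            raise ValueError("powers must be >= 0")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be > 0")
        if self.mod_freq >= self.rep_rate:
            raise ValueError("mod_freq must be below the repetition rate")
        if self.raman_shift <= 0:
            raise ValueError("raman_shift must be > 0 cm^-1")
        if self.stokes_wavelength <= 0:
            raise ValueError("stokes_wavelength must be > 0")
        if not (0.0 <= self.srs_mod_depth < 1.0):
            raise ValueError("srs_mod_depth must be in [0, 1)")
        if self.heating_duration < 0:
            raise ValueError("heating_duration must be >= 0")

    @property
    def pump_wavenumber(self) -> float:
        """Pump photon wavenumber in cm^-1 (Stokes wavenumber + Raman shift)."""
        return 1.0 / (self.stokes_wavelength * 100.0) + self.raman_shift

    def replace(self, **kw) -> "ExcitationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class MediumProps:
    """Bulk thermal and optical properties of the immersion/sample medium."""

    density: float  # kg m^-3
    specific_heat: float  # J kg^-1 K^-1
    conductivity: float  # W m^-1 K^-1
    dn_dT: float  # K^-1
    n0: float  # refractive index at the probe wavelength
    name: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0 or self.specific_heat <= 0 or self.conductivity <= 0:
            raise ValueError("density, specific_heat and conductivity must be > 0")
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity D = k / (rho * c), m^2 s^-1."""
        return self.conductivity / (self.density * self.specific_heat)

    def replace(self, **kw) -> "MediumProps":
        return replace(self, **kw)


# Literature bulk values at room temperature.
DMSO = MediumProps(
    density=1100.0, specific_heat=1950.0, conductivity=0.20,
    dn_dT=-4.93e-4, n0=1.477, name="DMSO",
)
WATER = MediumProps(
    density=997.0, specific_heat=4182.0, conductivity=0.606,
    dn_dT=-1.0e-4, n0=1.330, name="water",
)
# Aqueous 8 M urea used as a clearing medium; thermal properties close to
# water, thermo-optic response roughly doubled by the solute.
UREA_8M = MediumProps(
    density=1115.0, specific_heat=3210.0, conductivity=0.50,
    dn_dT=-2.0e-4, n0=1.400, name="urea_8M",
)

MEDIUM_PRESETS: dict[str, MediumProps] = {
    "dmso": DMSO, "water": WATER, "urea_8m": UREA_8M,
}


@dataclass(frozen=True)
class FocalVolume:
    """3D Gaussian footprint of the SRS excitation point-spread function."""

    sigma_x: float = 0.17e-6
    sigma_y: float = 0.17e-6
    sigma_z: float = 0.45e-6
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("all PSF sigmas must be > 0")

    @property
    def sigmas(self) -> tuple[float, float, float]:
        return (self.sigma_x, self.sigma_y, self.sigma_z)

    def replace(self, **kw) -> "FocalVolume":
        return replace(self, **kw)


@dataclass(frozen=True)
class ProbeGeometry:
    """Focused CW probe beam.

    ``focus_offset_dz`` is the axial position of the probe waist relative to
    the SRS focus (positive = probe focuses after the heated volume along
    the propagation direction). A nonzero offset is what converts the
    symmetric thermal lens into a first-order power redistribution in the
    far field.
    """

    waist: float = 0.60e-6
    focus_offset_dz: float = -2.5e-6
    wavelength: float = 765e-9

    def __post_init__(self) -> None:
        if self.waist <= 0:
            raise ValueError("waist must be > 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    @property
    def rayleigh_range(self) -> float:
        import math

        return math.pi * self.waist**2 / self.wavelength

    def replace(self, **kw) -> "ProbeGeometry":
        return replace(self, **kw)


def default_excitation(**overrides) -> ExcitationParams:
    return ExcitationParams(**overrides)


def default_focal_volume(**overrides) -> FocalVolume:
    return FocalVolume(**overrides)


def default_probe(**overrides) -> ProbeGeometry:
    return ProbeGeometry(**overrides)
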