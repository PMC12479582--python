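"""Scalar angular-spectrum propagation of the probe through the thermal lens.

The thermal lens is a weak (|dn| < 5e-3), smooth phase object, so scalar
split-step propagation is adequate: thin phase screens phi = k0 * dn * dz
alternate with angular-spectrum free-space steps at the medium wavenumber
k = n0 * k0. Far fields are Fraunhofer transforms onto vacuum-referred
direction cosines kx/k0, which for a sample in a medium of index n0 coincide
with the air-side collection NA of the condenser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fields import ComplexField2D, FarFieldPattern, ScalarField3D
from .params import (
    ExcitationParams,
    FocalVolume,
    MediumProps,
    ProbeGeometry,
)

__all__ = [
    "gaussian_probe_field",
    "free_space_propagate",
    "split_step_propagate",
    "far_field",
    "collected_power",
    "NAContrastResult",
    "na_contrast_scan",
    "probe_offset_scan",
]


def gaussian_probe_field(
    g: ProbeGeometry,
    z_plane: float,
    *,
    n_grid: int = 512,
    extent: float = 20e-6,
    n0: float = 1.0,
) -> ComplexField2D:
    """Paraxial Gaussian probe amplitude at ``z_plane``, unit total power.

    The beam waist sits at ``g.focus_offset_dz`` (relative to the SRS focus
    at z=0); all z are in the same frame. Propagation is inside the medium,
    so the Rayleigh range uses the medium wavelength ``wavelength / n0``.
    """
    spacing = extent / n_grid
    if spacing > g.waist / 4.0:
        raise ValueError(
            f"grid spacing {spacing:.3g} m under-resolves the probe waist "
            f"{g.waist:.3g} m; need >= 8 samples across the spot"
        )
    lam = g.wavelength / n0
    k = 2.0 * math.pi / lam
    zr = math.pi * g.waist**2 / lam
    z = z_plane - g.focus_offset_dz
    w = g.waist * math.sqrt(1.0 + (z / zr) ** 2)
    gouy = math.atan2(z, zr)
    c = (np.arange(n_grid) - n_grid / 2) * spacing
    r2 = c[:, None] ** 2 + c[None, :] ** 2
    amp = (g.waist / w) * np.exp(-r2 / w**2)
    phase = -gouy * np.ones_like(r2)
    if z != 0.0:
        radius = z * (1.0 + (zr / z) ** 2)
        phase = phase + k * r2 / (2.0 * radius)
    field = amp * np.exp(1j * phase)
    field /= math.sqrt(np.sum(np.abs(field) ** 2) * spacing**2)
    return ComplexField2D(field, spacing, g.wavelength, z_position=z_plane)


def _kz_grid(field: ComplexField2D, n0: float) -> np.ndarray:
    """Axial wavenumber for each plane-wave component; evanescent -> 0."""
    n = field.n
    fx = np.fft.fftfreq(n, d=field.spacing)
    kx = 2.0 * math.pi * fx
    k = 2.0 * math.pi * n0 / field.wavelength
    kz2 = k**2 - kx[:, None] ** 2 - kx[None, :] ** 2
    return np.sqrt(np.clip(kz2, 0.0, None))


def free_space_propagate(
    field: ComplexField2D, dz: float, n0: float = 1.0
) -> ComplexField2D:
    """Exact angular-spectrum transfer over distance ``dz`` (+ or -)."""
    kz = _kz_grid(field, n0)
    spec = np.fft.fft2(field.amplitude)
    # evanescent components are discarded rather than amplified
    mask = kz > 0
    spec = np.where(mask, spec * np.exp(1j * kz * dz), 0.0)
    out = np.fft.ifft2(spec)
    return ComplexField2D(out, field.spacing, field.wavelength,
                          z_position=field.z_position + dz)


def _resample_slices(
    dn: ScalarField3D, field: ComplexField2D
) -> tuple[np.ndarray, np.ndarray, float]:
    """Interpolate dn z-slices onto the field's transverse grid.

    Returns (slices[n_z, n, n], z_centers, dz_slice). Outside the dn volume
    the perturbation is zero.
    """
    xs, ys, zs = dn.axes()
    c = (np.arange(field.n) - field.n / 2) * field.spacing
    pts_x, pts_y = np.meshgrid(c, c, indexing="ij")
    flat = np.stack([pts_x.ravel(), pts_y.ravel()], axis=-1)
    out = np.empty((len(zs), field.n, field.n))
    for iz in range(len(zs)):
        itp = RegularGridInterpolator(
            (xs, ys), dn.values[:, :, iz], bounds_error=False, fill_value=0.0
        )
        out[iz] = itp(flat).reshape(field.n, field.n)
    return out, zs, dn.spacing[2]


def split_step_propagate(
    field: ComplexField2D,
    dn_volume: ScalarField3D,
    n0: float,
    *,
    alias_check: bool = True,
) -> ComplexField2D:
    """Propagate through the index perturbation with symmetric split steps.

    The input field must be located at (or before) the first z-slice; it is
    first carried to the entry plane by free-space propagation. Each slice
    of thickness dz contributes a thin phase screen exp(i k0 dn dz)
    sandwiched between two half-steps. Pure phase screens conserve power.
    With ``dn_volume`` identically zero the result equals free-space
    propagation over the same distance.
    """
    slices, zs, dz = _resample_slices(dn_volume, field)
    k0 = 2.0 * math.pi / field.wavelength
    entry = zs[0] - dz / 2.0
    if field.z_position > entry + 1e-15:
        raise ValueError(
            f"field plane z={field.z_position:.3g} is past the first lens "
            f"slice at z={entry:.3g}"
        )
    out = free_space_propagate(field, entry - field.z_position, n0)
    kz = _kz_grid(out, n0)
    mask = kz > 0
    half = np.where(mask, np.exp(1j * kz * dz / 2.0), 0.0)
    for iz in range(len(zs)):
        spec = np.fft.fft2(out.amplitude) * half
        mid = np.fft.ifft2(spec)
        mid *= np.exp(1j * k0 * slices[iz] * dz)
        spec = np.fft.fft2(mid) * half
        out = ComplexField2D(
            np.fft.ifft2(spec), out.spacing, out.wavelength,
            z_position=zs[iz] + dz / 2.0,
        )
    if alias_check:
        _assert_no_aliasing(out)
    return out


def _assert_no_aliasing(field: ComplexField2D, frac: float = 0.90,
                        tol: float = 1e-3) -> None:
    spec = np.abs(np.fft.fft2(field.amplitude)) ** 2
    n = field.n
    f = np.fft.fftfreq(n)
    rad = np.hypot(f[:, None], f[None, :]) / 0.5
    edge = spec[rad > frac].sum()
    total = spec.sum()
    if total > 0 and edge / total > tol:
        raise RuntimeError(
            f"{edge / total:.2%} of the power sits at grid-edge angles; "
            "enlarge the transverse grid or reduce the propagation distance"
        )


def far_field(field: ComplexField2D, pad_factor: int = 4) -> FarFieldPattern:
    """Fraunhofer pattern over vacuum direction cosines (kx/k0, ky/k0).

    Zero-padding by ``pad_factor`` refines the angular sampling to
    wavelength / (pad_factor * extent) without changing the physics; the
    angular integral of the intensity equals the field power (Parseval).
    """
    n = field.n
    npad = n * pad_factor
    a = np.zeros((npad, npad), dtype=complex)
    a[:n, :n] = field.amplitude
    spec = np.fft.fftshift(np.fft.fft2(a)) * field.spacing**2
    fx = np.fft.fftshift(np.fft.fftfreq(npad, d=field.spacing))
    s = field.wavelength * fx  # kx/k0
    # intensity per unit (sx, sy): |A(f)|^2 df^2/ds^2 = |A|^2 / wavelength^2
    intensity = np.abs(spec) ** 2 / field.wavelength**2
    ds = s[1] - s[0]
    total = float(intensity.sum() * ds * ds)
    return FarFieldPattern(intensity=intensity, sx=s, sy=s, total_power=total)


def collected_power(ff: FarFieldPattern, na: float) -> float:
    """Power collected within the air-side cone sin(theta) <= na."""
    if not (0.0 <= na <= 1.0):
        raise ValueError(f"collection NA must lie in [0, 1], got {na}")
    if na == 0.0:
        return 0.0
    rad = ff.radial_na()
    ds = ff.sx[1] - ff.sx[0]
    return float(ff.intensity[rad <= na].sum() * ds * ds)


@dataclass
class NAContrastResult:
    """NA scan of the relative SRS-on/off transmitted-power contrast."""

    na: np.ndarray
    p_on: np.ndarray
    p_off: np.ndarray
    contrast: np.ndarray
    optimal_na: float | None  # None when the lens is absent (flat zero curve)

    @property
    def has_signal(self) -> bool:
        return self.optimal_na is not None


def _lens_far_fields(
    dn_volume: ScalarField3D,
    g: ProbeGeometry,
    n0: float,
    *,
    n_grid: int,
    extent: float,
    pad_factor: int,
) -> tuple[FarFieldPattern, FarFieldPattern]:
    """Far fields of the probe with the lens present and absent."""
    zs = dn_volume.axes()[2]
    z_entry = zs[0] - dn_volume.spacing[2]
    probe = gaussian_probe_field(g, z_entry, n_grid=n_grid, extent=extent, n0=n0)
    on = split_step_propagate(probe, dn_volume, n0)
    zero = ScalarField3D(
        np.zeros_like(dn_volume.values), dn_volume.spacing, dn_volume.origin
    )
    off = split_step_propagate(probe, zero, n0)
    return far_field(on, pad_factor), far_field(off, pad_factor)


def na_contrast_scan(
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    g: ProbeGeometry,
    na_grid: np.ndarray,
    *,
    dn_volume: ScalarField3D | None = None,
    n_grid: int = 512,
    extent: float = 20e-6,
    n_z: int = 40,
    z_span_sigmas: float = 3.0,
    xy_span_sigmas: float = 5.0,
    pad_factor: int = 4,
    metric: str = "absolute",
) -> NAContrastResult:
    """SRS-on/off collected-power contrast vs collection NA, and its argmax.

    The lens defaults to the thermo-optic perturbation of a single on-state
    deposition event (the peak instantaneous lens); SRS-off is free-space
    propagation.

    ``metric`` selects the contrast definition:

    * ``"absolute"`` (default): P_on(NA) - P_off(NA). This is the far-field
      on/off difference pattern integrated over the collection cone. Power
      conservation pins it to zero at NA -> 0 and at full aperture, so it
      has an interior optimum — the collection NA at which the condenser
      captures the entire redistributed lobe of the thermal-lens signal.
    * ``"relative"``: (P_on - P_off) / P_off, the fractional modulation a
      detector behind the aperture sees. For a weak Gaussian-ish lens this
      is flat at small NA and decays monotonically, so it carries no
      interior optimum; it is reported for detector-sizing, not for the
      optimal-NA search.
    """
    from .physics import energy_per_pulse_pair, index_field, temperature_field

    na_grid = np.asarray(na_grid, dtype=float)
    if na_grid.size == 0:
        raise ValueError("na_grid is empty")
    if dn_volume is None:
        energy = energy_per_pulse_pair(p)
        zspan = 2 * z_span_sigmas * f.sigma_z
        shape = (n_z + 1, n_z + 1, n_z + 1)
        spacing = (
            2 * xy_span_sigmas * f.sigma_x / n_z,
            2 * xy_span_sigmas * f.sigma_y / n_z,
            zspan / n_z,
        )
        dT = temperature_field(
            p, f, m, 0.0, shape=shape, spacing=spacing, energy=energy
        )
        dn_volume = index_field(dT, m)
    ff_on, ff_off = _lens_far_fields(
        dn_volume, g, m.n0, n_grid=n_grid, extent=extent, pad_factor=pad_factor
    )
    p_on = np.array([collected_power(ff_on, na) for na in na_grid])
    p_off = np.array([collected_power(ff_off, na) for na in na_grid])
    if metric not in ("absolute", "relative"):
        raise ValueError(f"unknown contrast metric {metric!r}")
    if metric == "absolute":
        contrast = p_on - p_off
    else:
        contrast = np.where(p_off > 0, (p_on - p_off) / p_off, 0.0)
    if np.max(np.abs(contrast)) < 1e-12:
        return NAContrastResult(na_grid, p_on, p_off, contrast, None)
    best = float(na_grid[int(np.argmax(np.abs(contrast)))])
    return NAContrastResult(na_grid, p_on, p_off, contrast, best)


def probe_offset_scan(
    dz_grid: np.ndarray,
    p: ExcitationParams,
    f: FocalVolume,
    m: MediumProps,
    g: ProbeGeometry,
    na: float,
    **scan_kw,
) -> tuple[np.ndarray, float | None]:
    """Signed contrast at fixed NA vs probe focus offset; argmax of |contrast|.

    The curve is antisymmetric for a thin symmetric lens: at dz=0 the probe
    wavefront is flat at the lens and the first-order photothermal term
    vanishes, so |contrast| has a near-null there.
    """
    dz_grid = np.asarray(dz_grid, dtype=float)
    out = np.empty(dz_grid.size)
    for i, dz in enumerate(dz_grid):
        res = na_contrast_scan(
            p, f, m, g.replace(focus_offset_dz=float(dz)),
            np.array([na]), **scan_kw,
        )
        out[i] = res.contrast[0]
    if np.max(np.abs(out)) < 1e-12:
        return out, None
    return out, float(dz_grid[int(np.argmax(np.abs(out)))])
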