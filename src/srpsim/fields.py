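"""Gridded field containers shared by the heat and optics solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalarField3D", "ComplexField2D", "FarFieldPattern"]


@dataclass
class ScalarField3D:
    """Real scalar field on a regular (x, y, z) grid.

    ``values`` is indexed [ix, iy, iz]; ``spacing`` is (dx, dy, dz) in m;
    ``origin`` is the physical coordinate of the [0, 0, 0] sample. ``unit``
    is a free-text label ("K" for temperature, "" for refractive index).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if min(self.spacing) <= 0:
            raise ValueError("grid spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.values.shape[i])
            for i in range(3)
        )

    def integral(self) -> float:
        """Volume integral of the field (trapezoid-free Riemann sum)."""
        dv = self.spacing[0] * self.spacing[1] * self.spacing[2]
        return float(self.values.sum() * dv)

    def same_grid(self, other: "ScalarField3D") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ComplexField2D:
    """Transverse complex scalar amplitude on a square grid.

    Total power is sum(|a|^2) * dx^2. Grids are square and power-of-two
    sized so angular-spectrum FFTs stay cheap and well conditioned.
    """

    amplitude: np.ndarray
    spacing: float
    wavelength: float
    z_position: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.ndim != 2 or self.amplitude.shape[0] != self.amplitude.shape[1]:
            raise ValueError("amplitude must be a square 2D array")
        n = self.amplitude.shape[0]
        if n & (n - 1) != 0:
            raise ValueError("grid size must be a power of two")
        if self.spacing <= 0 or self.wavelength <= 0:
            raise ValueError("spacing and wavelength must be > 0")

    @property
    def n(self) -> int:
        return self.amplitude.shape[0]

    @property
    def extent(self) -> float:
        return self.n * self.spacing

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered physical coordinates (x[:, None], y[None, :])."""
        c = (np.arange(self.n) - self.n / 2) * self.spacing
        return c[:, None], c[None, :]

    def power(self) -> float:
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.spacing**2)


@dataclass
class FarFieldPattern:
    """Angular intensity over direction cosines (vacuum-referred).

    ``sx``/``sy`` are kx/k0 and ky/k0 (k0 the vacuum wavenumber), so the
    radial coordinate sqrt(sx^2 + sy^2) is directly the air-side collection
    NA for a sample in a medium of index n0. ``intensity`` integrates to the
    beam power over d(sx) d(sy).
    """

    intensity: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    total_power: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < -1e-12 * max(self.intensity.max(), 1e-300)):
            raise ValueError("far-field intensity must be non-negative")
        self.intensity = np.clip(self.intensity, 0.0, None)

    def radial_na(self) -> np.ndarray:
        return np.hypot(self.sx[:, None], self.sy[None, :])
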