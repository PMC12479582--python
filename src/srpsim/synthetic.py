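"""Seeded synthetic inputs for the hyperspectral analysis chain.

The generators emulate the statistical structure the analyses assume:
sum-of-Gaussian pseudo-Raman reference spectra in the C-H (2800-3050 cm^-1)
and C-D (2000-2300 cm^-1) windows, smooth cell-like phantom concentration
maps, additive Gaussian detector noise, multiplicative interference fringes
from a long-coherence probe, and linear serial-dilution intensity series for
limit-of-detection calibration. All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .unmixing import HyperspectralStack, SpectraMatrix

__all__ = [
    "BandSpec",
    "FringeParams",
    "PhantomTruth",
    "make_reference_spectra",
    "default_ch_bands",
    "cell_phantom_maps",
    "make_phantom_stack",
    "DilutionResult",
    "dilution_series",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian pseudo-Raman band."""

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


@dataclass(frozen=True)
class FringeParams:
    """Multiplicative sinusoidal fringe (etalon pattern of a long-coherence
    probe at refractive-index steps)."""

    period: float = 6.0  # pixels
    amplitude: float = 0.1  # relative modulation depth
    orientation: float = 0.0  # radians, 0 = fringes along y


@dataclass
class PhantomTruth:
    """Ground truth for a phantom stack: maps, noise, fringes, seed."""

    maps: np.ndarray  # (K, y, x), >= 0
    names: list[str]
    noise_sigma: float = 0.0
    fringe: FringeParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (K, y, x)")
        if np.any(self.maps < 0):
            raise ValueError("concentration maps must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_reference_spectra(
    bands: dict[str, list[BandSpec]],
    wavenumbers: np.ndarray,
) -> SpectraMatrix:
    """Sum-of-Gaussian reference spectra on the given ascending grid."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if np.any(np.diff(wavenumbers) <= 0):
        raise ValueError("wavenumber grid must be strictly increasing")
    if not bands:
        raise ValueError("at least one component with bands is required")
    rows = []
    for name, blist in bands.items():
        if not blist:
            raise ValueError(f"component {name!r} has no bands")
        row = np.zeros_like(wavenumbers)
        for b in blist:
            row += b.amplitude * np.exp(
                -0.5 * ((wavenumbers - b.center) / b.width) ** 2
            )
        rows.append(row)
    spectra = np.stack(rows)
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if np.allclose(spectra[i], spectra[j]):
                warnings.warn(
                    f"components {list(bands)[i]!r} and {list(bands)[j]!r} "
                    "have identical spectra; unmixing cannot separate them",
                    stacklevel=2,
                )
    return SpectraMatrix(spectra, list(bands.keys()), wavenumbers)


def default_ch_bands() -> dict[str, list[BandSpec]]:
    """Four-component C-H window model: lipid (CH2), protein (CH3),
    cholesterol, and a nucleus-weighted component."""
    return {
        "lipid": [BandSpec(2848, 13, 1.0), BandSpec(2888, 18, 0.35)],
        "protein": [BandSpec(2930, 20, 1.0), BandSpec(2875, 16, 0.2)],
        "cholesterol": [BandSpec(2870, 8, 1.0), BandSpec(2904, 9, 0.6)],
        "nucleus": [BandSpec(2955, 12, 1.0), BandSpec(2995, 18, 0.35)],
    }


def _gaussian_blob(ny: int, nx: int, cy: float, cx: float, ry: float,
                   rx: float, theta: float = 0.0) -> np.ndarray:
    y, x = np.mgrid[0:ny, 0:nx]
    yc, xc = y - cy, x - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * xc + st * yc
    v = -st * xc + ct * yc
    return np.exp(-0.5 * ((u / rx) ** 2 + (v / ry) ** 2))


def cell_phantom_maps(
    ny: int = 32,
    nx: int = 32,
    names: tuple[str, ...] = ("lipid", "protein", "cholesterol", "nucleus"),
    seed: int = 0,
) -> np.ndarray:
    """Smooth cell-like component maps: a cytoplasm ellipse (protein), a
    nucleus blob, and scattered lipid/cholesterol droplets. Deterministic
    for a given (shape, names, seed)."""
    rng = np.random.default_rng(seed)
    maps = np.zeros((len(names), ny, nx))
    cy, cx = ny / 2 + rng.uniform(-2, 2), nx / 2 + rng.uniform(-2, 2)
    cell = _gaussian_blob(ny, nx, cy, cx, ny * 0.32, nx * 0.38,
                          rng.uniform(0, math.pi))
    for k, name in enumerate(names):
        if name == "protein":
            maps[k] = 1.0 * cell
        elif name == "nucleus":
            maps[k] = 1.2 * _gaussian_blob(
                ny, nx, cy + rng.uniform(-3, 3), cx + rng.uniform(-3, 3),
                ny * 0.12, nx * 0.12)
        else:  # droplet-like components
            n_drop = int(rng.integers(3, 7))
            for _ in range(n_drop):
                dy = cy + rng.uniform(-0.3, 0.3) * ny
                dx = cx + rng.uniform(-0.3, 0.3) * nx
                r = rng.uniform(1.0, 2.5)
                maps[k] += rng.uniform(0.5, 1.5) * _gaussian_blob(
                    ny, nx, dy, dx, r, r)
            maps[k] *= cell
    return maps


def make_phantom_stack(
    truth: PhantomTruth, s: SpectraMatrix
) -> HyperspectralStack:
    """Assemble the generative model D = sum_k map_k (x) spectrum_k, then
    apply the optional multiplicative fringe and additive Gaussian noise.

    At zero noise and no fringe the stack satisfies the unmixing model
    exactly, enabling exact-recovery tests. Byte-reproducible per seed.
    """
    if truth.maps.shape[0] != s.k:
        raise ValueError(
            f"{truth.maps.shape[0]} maps but {s.k} reference spectra"
        )
    data = np.tensordot(truth.maps, s.spectra, axes=([0], [0]))
    ny, nx = data.shape[:2]
    if truth.fringe is not None:
        fr = truth.fringe
        y, x = np.mgrid[0:ny, 0:nx]
        u = x * math.cos(fr.orientation) + y * math.sin(fr.orientation)
        pattern = 1.0 + fr.amplitude * np.sin(2.0 * math.pi * u / fr.period)
        data = data * pattern[:, :, None]
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        data = data + rng.normal(0.0, truth.noise_sigma, size=data.shape)
    return HyperspectralStack(data, s.wavenumbers.copy())


@dataclass
class DilutionResult:
    """Fitted serial-dilution calibration and its limit of detection."""

    table: pd.DataFrame  # columns: concentration, replicate, intensity
    slope: float
    intercept: float
    r_squared: float
    sigma_blank: float
    lod: float  # 3 * sigma_blank / slope


def dilution_series(
    concentrations: np.ndarray,
    response_slope: float,
    noise_sigma: float,
    n_repl: int = 1,
    seed: int = 0,
    intercept: float = 0.0,
) -> DilutionResult:
    """Simulate a linear intensity-concentration series and estimate the LOD.

    Intensities are ``slope * c + intercept + N(0, sigma)``; the calibration
    line is ordinary least squares over all replicates, ``sigma_blank`` is
    the replicate standard deviation at the lowest concentration (the blank
    when 0 is included, noise_sigma when replication is insufficient), and
    LOD follows the 3-sigma convention ``3 * sigma_blank / slope``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 concentrations")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    c_all = np.repeat(conc, n_repl)
    noise = rng.normal(0.0, noise_sigma, size=c_all.size) if noise_sigma > 0 \
        else np.zeros(c_all.size)
    intens = response_slope * c_all + intercept + noise
    table = pd.DataFrame({
        "concentration": c_all,
        "replicate": np.tile(np.arange(n_repl), conc.size),
        "intensity": intens,
    })
    slope, icept = np.polyfit(c_all, intens, 1)
    pred = slope * c_all + icept
    ss_res = float(np.sum((intens - pred) ** 2))
    ss_tot = float(np.sum((intens - intens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    blank_mask = c_all == conc.min()
    if noise_sigma == 0:
        sigma_blank = 0.0
    elif blank_mask.sum() >= 3:
        sigma_blank = float(np.std(intens[blank_mask], ddof=1))
    else:
        sigma_blank = noise_sigma
    lod = 3.0 * sigma_blank / slope if slope != 0 else math.inf
    return DilutionResult(table, float(slope), float(icept), r2,
                          sigma_blank, float(lod))
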