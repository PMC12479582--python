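"""Per-pixel LASSO spectral unmixing and small hyperspectral analysis ops.

Each pixel spectrum d (length N_lambda) is decomposed against K reference
spectra S (K x N_lambda) by

    min_c  1/2 ||d - c S||_2^2 + beta ||c||_1,

solved by cyclic coordinate descent with soft-thresholding. Reference rows
are L2-normalized internally and the coefficients rescaled back, so beta is
always referred to unit-norm references regardless of how the inputs were
scaled; this is the convention under which the default beta heuristic
(0.1 * max |S d|) is stated.

The companion operators cover the rest of the image-analysis workflow:
two-color ratio histology, Pearson spectral fidelity, median despeckling of
interference fringes, and Gaussian bead-profile resolution with quadrature
deconvolution of the bead diameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "HyperspectralStack",
    "SpectraMatrix",
    "ConcentrationMaps",
    "lasso_solve",
    "lasso_objective",
    "default_beta",
    "unmix_stack",
    "beta_grid_report",
    "pearson_fidelity",
    "ratio_map",
    "median_despeckle",
    "profile_resolution",
]


@dataclass
class HyperspectralStack:
    """Image cube (y, x, lambda) with an ascending wavenumber axis in cm^-1."""

    data: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (y, x, lambda)")
        if self.data.shape[2] != self.wavenumbers.size:
            raise ValueError(
                f"spectral axis has {self.data.shape[2]} planes but "
                f"{self.wavenumbers.size} wavenumbers"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SpectraMatrix:
    """K reference spectra on a common wavenumber grid."""

    spectra: np.ndarray  # (K, N_lambda)
    names: list[str]
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.spectra.shape[1] != self.wavenumbers.size:
            raise ValueError("spectra and wavenumber grid disagree")
        if len(self.names) != self.spectra.shape[0]:
            raise ValueError("one name per spectrum required")
        norms = np.linalg.norm(self.spectra, axis=1)
        if np.any(norms == 0):
            raise ValueError("reference spectra must be non-zero")

    @property
    def k(self) -> int:
        return self.spectra.shape[0]

    def resample(self, wavenumbers: np.ndarray) -> "SpectraMatrix":
        """Linear resampling onto a new grid (zero outside support)."""
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        out = np.stack([
            np.interp(wavenumbers, self.wavenumbers, row, left=0.0, right=0.0)
            for row in self.spectra
        ])
        return SpectraMatrix(out, list(self.names), wavenumbers)


@dataclass
class ConcentrationMaps:
    """Per-component coefficient maps from pixel-wise unmixing."""

    maps: np.ndarray  # (K, y, x)
    beta: float
    names: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps contain non-finite values")


def lasso_solve(
    d: np.ndarray,
    s: SpectraMatrix | np.ndarray,
    beta: float,
    *,
    nonnegative: bool = False,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Solve the single-pixel LASSO by cyclic coordinate descent.

    Returns coefficients on the scale of the *input* reference spectra
    (internal unit-norm rescaling is undone). ``nonnegative=True`` projects
    each coordinate update to [0, inf) (one-sided soft threshold).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    S = s.spectra if isinstance(s, SpectraMatrix) else np.atleast_2d(np.asarray(s, float))
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size != S.shape[1]:
        raise ValueError(
            f"spectrum length {d.size} does not match references ({S.shape[1]})"
        )
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ValueError("reference spectra must be non-zero")
    Sn = S / norms[:, None]
    k = Sn.shape[0]
    c = np.zeros(k)
    r = d.copy()  # residual d - c @ Sn
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(k):
            z = c[j] + Sn[j] @ r
            if nonnegative:
                cj = max(z - beta, 0.0)
            else:
                cj = math.copysign(max(abs(z) - beta, 0.0), z)
            if cj != c[j]:
                r += (c[j] - cj) * Sn[j]
                delta = max(delta, abs(cj - c[j]))
                c[j] = cj
        if delta < tol:
            break
    else:
        warnings.warn(
            f"coordinate descent hit max_sweeps={max_sweeps} "
            f"(last max update {delta:.2e})",
            stacklevel=2,
        )
    return c / norms


def lasso_objective(d: np.ndarray, S: np.ndarray, c: np.ndarray, beta: float,
                    *, normalized: bool = True) -> float:
    """Objective 1/2||d - cS||^2 + beta ||c||_1 (unit-norm-row convention)."""
    S = np.atleast_2d(np.asarray(S, float))
    norms = np.linalg.norm(S, axis=1)
    Sn = S / norms[:, None] if normalized else S
    cn = np.asarray(c, float) * norms if normalized else np.asarray(c, float)
    resid = d - cn @ Sn
    return 0.5 * float(resid @ resid) + beta * float(np.abs(cn).sum())


def default_beta(stack_or_spectrum: np.ndarray, s: SpectraMatrix,
                 fraction: float = 0.1) -> float:
    """Heuristic beta: ``fraction`` of the largest |correlation| between any
    pixel spectrum and any unit-norm reference (beta >= that maximum gives
    an all-zero solution, so this sits safely inside the solution path)."""
    Sn = s.spectra / np.linalg.norm(s.spectra, axis=1)[:, None]
    data = np.asarray(stack_or_spectrum, float)
    flat = data.reshape(-1, Sn.shape[1])
    return fraction * float(np.max(np.abs(flat @ Sn.T)))


def unmix_stack(
    stack: HyperspectralStack,
    s: SpectraMatrix,
    beta: float | None = None,
    **solve_kw,
) -> ConcentrationMaps:
    """Pixel-by-pixel LASSO over the stack.

    Reference spectra are linearly resampled onto the stack's wavenumber
    axis when the grids differ; the overlap must cover at least 80% of the
    stack's spectral range.
    """
    if not np.array_equal(s.wavenumbers, stack.wavenumbers):
        lo, hi = stack.wavenumbers[0], stack.wavenumbers[-1]
        overlap = (min(hi, s.wavenumbers[-1]) - max(lo, s.wavenumbers[0]))
        if overlap < 0.8 * (hi - lo):
            raise ValueError(
                "reference spectra cover "
                f"{max(overlap, 0) / (hi - lo):.0%} of the stack's spectral "
                "range; need >= 80%"
            )
        s = s.resample(stack.wavenumbers)
    if beta is None:
        beta = default_beta(stack.data, s)
    ny, nx, _ = stack.shape
    maps = np.empty((s.k, ny, nx))
    for i in range(ny):
        for j in range(nx):
            maps[:, i, j] = lasso_solve(stack.data[i, j], s, beta, **solve_kw)
    return ConcentrationMaps(maps, beta, list(s.names))


def beta_grid_report(
    stack: HyperspectralStack,
    s: SpectraMatrix,
    betas: np.ndarray,
    **solve_kw,
):
    """Reconstruction-error / sparsity trade-off over a beta grid.

    Returns a pandas DataFrame with columns (beta, rmse, nonzero_fraction)
    to support the empirical choice of the regularization strength.
    """
    import pandas as pd

    rows = []
    for beta in np.asarray(betas, float):
        cm = unmix_stack(stack, s, float(beta), **solve_kw)
        sn = s if np.array_equal(s.wavenumbers, stack.wavenumbers) \
            else s.resample(stack.wavenumbers)
        recon = np.tensordot(cm.maps, sn.spectra, axes=([0], [0]))
        rmse = float(np.sqrt(np.mean((recon - stack.data) ** 2)))
        nz = float(np.mean(np.abs(cm.maps) > 0))
        rows.append({"beta": float(beta), "rmse": rmse, "nonzero_fraction": nz})
    return pd.DataFrame(rows)


def pearson_fidelity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two spectra (spectral fidelity score)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1D spectra of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("spectral fidelity is undefined for constant spectra")
    return float(stats.pearsonr(a, b).statistic)


def ratio_map(
    img_a: np.ndarray, img_b: np.ndarray, floor: float
) -> np.ma.MaskedArray:
    """Two-color ratio a/b, masked where the denominator is below ``floor``."""
    img_a = np.asarray(img_a, float)
    img_b = np.asarray(img_b, float)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape")
    mask = img_b < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, 0.0, img_a / np.where(mask, 1.0, img_b))
    return np.ma.MaskedArray(ratio, mask=mask)


def median_despeckle(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with reflected edges; suppresses coherent-probe fringes
    and impulse noise after spatial oversampling."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    return ndimage.median_filter(np.asarray(img, float), size=window,
                                 mode="reflect")


@dataclass
class ResolutionResult:
    fwhm: float
    resolution: float
    sigma: float
    center: float
    bead_limited: bool  # True when FWHM <= bead diameter (deconvolution moot)


_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def profile_resolution(
    profile: np.ndarray,
    spacing: float,
    bead_diameter: float = 0.0,
) -> ResolutionResult:
    """Gaussian-fit FWHM of a bead line profile and deconvolved resolution.

    The measured profile is the instrument PSF convolved with the bead; for
    Gaussian-on-Gaussian blurring widths add in quadrature, so the reported
    resolution is sqrt(FWHM^2 - d_bead^2). When the fitted FWHM does not
    exceed the bead diameter the result is flagged ``bead_limited`` and the
    raw FWHM is returned as the resolution.
    """
    profile = np.asarray(profile, float)
    if profile.ndim != 1 or profile.size < 5:
        raise ValueError("need a 1D profile with >= 5 samples")
    x = np.arange(profile.size) * spacing
    base = float(profile.min())
    amp0 = float(profile.max() - base)
    if amp0 <= 0:
        raise ValueError("profile has no peak above its baseline")
    c0 = float(x[np.argmax(profile)])
    s0 = max(spacing, float(np.sqrt(np.clip(
        np.sum((x - c0) ** 2 * (profile - base)) /
        max(np.sum(profile - base), 1e-300), spacing**2, None))))

    def gauss(x, amp, center, sigma, offset):
        return offset + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gauss, x, profile, p0=(amp0, c0, s0, base), maxfev=10_000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit did not converge (initial center {c0:.3g}, "
            f"sigma {s0:.3g}): {exc}"
        ) from exc
    sigma = abs(float(popt[2]))
    fwhm = _FWHM * sigma
    if fwhm > bead_diameter:
        resolution = math.sqrt(fwhm**2 - bead_diameter**2)
        limited = False
    else:
        resolution = fwhm
        limited = True
    return ResolutionResult(fwhm=fwhm, resolution=resolution, sigma=sigma,
                            center=float(popt[1]), bead_limited=limited)
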