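"""File formats: multi-page TIFF stacks with JSON sidecars, CSV spectra,
and the YAML run configuration with explicit units.

Hyperspectral stacks and 3D fields travel as float32 multi-page TIFF (one
page per wavenumber or z-plane) with a ``<name>.json`` sidecar holding the
axis metadata; reference spectra and scan curves are plain CSV. Config
files carry units on every physical quantity ("28 mW", "2912 cm^-1"); bare
numbers are taken as SI (wavenumbers as cm^-1).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fields import ScalarField3D
from .params import (
    MEDIUM_PRESETS,
    ExcitationParams,
    FocalVolume,
    MediumProps,
    ProbeGeometry,
)
from .unmixing import HyperspectralStack, SpectraMatrix

__all__ = [
    "write_stack",
    "read_stack",
    "write_field3d",
    "read_field3d",
    "write_spectra",
    "read_spectra",
    "parse_quantity",
    "RunConfig",
    "load_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: HyperspectralStack, path: str | Path) -> None:
    """Stack as float32 multi-page TIFF (one page per wavenumber) plus a
    JSON sidecar with the wavenumber axis and pixel size."""
    path = Path(path)
    pages = np.moveaxis(stack.data.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata=None)
    meta = {
        "wavenumbers_cm1": [float(w) for w in stack.wavenumbers],
        "pixel_size_m": float(stack.pixel_size),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> HyperspectralStack:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing wavenumber sidecar {side.name} next to {path.name}"
        )
    meta = json.loads(side.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    wn = np.asarray(meta["wavenumbers_cm1"], dtype=float)
    if pages.shape[0] != wn.size:
        raise ValueError(
            f"{pages.shape[0]} TIFF pages but {wn.size} wavenumbers in sidecar"
        )
    data = np.moveaxis(pages, 0, 2)
    return HyperspectralStack(data, wn, pixel_size=meta.get("pixel_size_m", 1.0))


def write_field3d(field: ScalarField3D, path: str | Path) -> None:
    """ScalarField3D as float32 multi-page TIFF (z as pages) + metadata."""
    path = Path(path)
    pages = np.moveaxis(field.values.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata=None)
    meta = {
        "spacing_m": [float(s) for s in field.spacing],
        "origin_m": [float(o) for o in field.origin],
        "unit": field.unit,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_field3d(path: str | Path) -> ScalarField3D:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing field metadata sidecar {side.name} next to {path.name}"
        )
    meta = json.loads(side.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    values = np.moveaxis(pages, 0, 2)
    return ScalarField3D(values, tuple(meta["spacing_m"]),
                         tuple(meta["origin_m"]), unit=meta.get("unit", ""))


def write_spectra(s: SpectraMatrix, path: str | Path) -> None:
    """CSV with a wavenumber column and one intensity column per component."""
    df = pd.DataFrame({"wavenumber_cm1": s.wavenumbers})
    for name, row in zip(s.names, s.spectra):
        df[name] = row
    df.to_csv(path, index=False)


def read_spectra(path: str | Path) -> SpectraMatrix:
    df = pd.read_csv(path)
    if "wavenumber_cm1" not in df.columns:
        raise ValueError("spectra CSV must have a 'wavenumber_cm1' column")
    names = [c for c in df.columns if c != "wavenumber_cm1"]
    if not names:
        raise ValueError("spectra CSV has no component columns")
    return SpectraMatrix(
        df[names].to_numpy().T, names, df["wavenumber_cm1"].to_numpy()
    )


# ---------------------------------------------------------------------------
# units and run configuration

_UNIT_SCALE = {
    "W": 1.0, "mW": 1e-3, "uW": 1e-6,
    "Hz": 1.0, "kHz": 1e3, "MHz": 1e6, "GHz": 1e9,
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9,
    "cm^-1": 1.0, "cm-1": 1.0, "1/cm": 1.0,  # Raman convention: stays cm^-1
    "%": 0.01, "K": 1.0, "": 1.0,
}
_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]*)\s*$")


def parse_quantity(value) -> float:
    """'28 mW' -> 0.028; bare numbers pass through (SI / cm^-1)."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).replace("µ", "u").replace("μ", "u")
    m = _QTY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = m.groups()
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNIT_SCALE[unit]


def _build(cls, section: dict, quantity_fields: set[str], name: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(section) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {name!r}; "
            f"expected a subset of {sorted(known)}"
        )
    kw = {}
    for key, val in section.items():
        kw[key] = parse_quantity(val) if key in quantity_fields else val
    return cls(**kw)


class RunConfig:
    """Validated run configuration.

    Sections: ``excitation``, ``medium`` (preset name or explicit
    properties), ``focal``, ``probe``, ``grids`` (free-form numeric kwargs
    passed to the optics), ``noise``, ``unmixing``, plus top-level ``seed``
    and ``outdir``. Unknown keys anywhere are rejected.
    """

    _TOP = {"excitation", "medium", "focal", "probe", "grids", "noise",
            "unmixing", "seed", "outdir"}

    def __init__(self, raw: dict):
        unknown = set(raw) - self._TOP
        if unknown:
            raise ValueError(
                f"unknown top-level config key(s) {sorted(unknown)}; "
                f"expected a subset of {sorted(self._TOP)}"
            )
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.outdir = Path(raw.get("outdir", "."))
        exc = dict(raw.get("excitation", {}))
        self.excitation = _build(
            ExcitationParams, exc,
            {"pump_power", "stokes_peak_power", "rep_rate", "duty_cycle",
             "mod_freq", "raman_shift", "stokes_wavelength", "srs_mod_depth",
             "heating_duration"},
            "excitation",
        )
        med = raw.get("medium", "dmso")
        if isinstance(med, str):
            key = med.lower()
            if key not in MEDIUM_PRESETS:
                raise ValueError(
                    f"unknown medium preset {med!r}; options: "
                    f"{sorted(MEDIUM_PRESETS)}"
                )
            self.medium = MEDIUM_PRESETS[key]
        else:
            self.medium = _build(
                MediumProps, dict(med),
                {"density", "specific_heat", "conductivity", "dn_dT", "n0"},
                "medium",
            )
        foc = dict(raw.get("focal", {}))
        if "center" in foc:
            foc["center"] = tuple(parse_quantity(v) for v in foc["center"])
        self.focal = _build(
            FocalVolume, foc, {"sigma_x", "sigma_y", "sigma_z"}, "focal"
        )
        self.probe = _build(
            ProbeGeometry, dict(raw.get("probe", {})),
            {"waist", "focus_offset_dz", "wavelength"}, "probe",
        )
        grids = dict(raw.get("grids", {}))
        for key in ("extent",):
            if key in grids:
                grids[key] = parse_quantity(grids[key])
        self.grids = grids
        self.noise = dict(raw.get("noise", {}))
        self.unmixing = dict(raw.get("unmixing", {}))


def load_config(path: str | Path | None) -> RunConfig:
    import yaml

    if path is None:
        return RunConfig({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(raw)
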