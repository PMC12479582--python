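# srpsim

Forward simulation and hyperspectral analysis for **stimulated Raman
photothermal (SRP) microscopy**.

SRP detects chemical bonds indirectly: a pump/Stokes pulse pair drives
stimulated Raman scattering (SRS) at a chosen vibrational frequency, the
deposited vibrational energy heats the focal volume, the thermo-optic
effect (dn/dT) turns that heat into a weak lens, and a third CW probe
beam reads the lens out as a far-field power redistribution demodulated
by a lock-in amplifier. Designing such an instrument raises quantitative
questions this package answers by simulation:

* how much energy does a measured SRS modulation depth deposit per pulse
  pair, and how hot does the focus get;
* which condenser collection NA maximizes the SRS-on/off probe contrast;
* how do duty cycle and modulation frequency shape the demodulated signal
  and SNR;
* and, on the analysis side, how to decompose hyperspectral SRP stacks
  into chemical maps by per-pixel LASSO unmixing, with the surrounding
  operators (two-color ratio histology, Pearson spectral fidelity, median
  despeckling of coherence fringes, bead-profile resolution with
  quadrature deconvolution).

It is aimed at builders of photothermal/SRS microscopes and at analysts
of their hyperspectral data. All simulations are deterministic; synthetic
data generators are seeded.

## Core models

Energy per pulse pair, from the lock-in SRS depth `md` on the pump:

    E = 2·md · (P_pump / f_rep) · Ω / (1/λ_S + Ω)

(Ω the Raman shift in cm⁻¹). Heating is a superposition of instantaneous
3D Gaussian sources diffusing in an infinite medium,

    ΔT(r, τ) = E/(ρc (2π)^{3/2} σxσyσz) · e^{−Σ rᵢ²/2σᵢ²},  σᵢ² = σᵢ₀² + 2Dτ,

the lens is Δn = ΔT·dn/dT, and the probe is propagated through it by
split-step scalar angular-spectrum beam propagation; far fields live on
direction cosines kx/k₀ = air-side collection NA. Unmixing solves, per
pixel, `min_c ½‖d − cS‖² + β‖c‖₁` by cyclic coordinate descent with
soft-thresholding. See `docs/methods.md` for assumptions, defaults, and
numerical choices.

## Worked example

```python
import numpy as np
from srpsim import (DMSO, ExcitationParams, FocalVolume, ProbeGeometry,
                    energy_per_pulse_pair, single_pulse_peak,
                    na_contrast_scan)

p = ExcitationParams()        # 28 mW pump, 40 MHz, 0.72% depth, 2912 cm^-1
f = FocalVolume()             # 1.2-NA excitation PSF (0.17/0.45 um sigmas)

E = energy_per_pulse_pair(p)
print(f"{E*1e12:.3f} pJ per pulse pair")
print(f"{single_pulse_peak(E, f, DMSO):.2f} K peak focal heating")

res = na_contrast_scan(p, f, DMSO, ProbeGeometry(),
                       np.arange(0.05, 0.551, 0.01),
                       n_grid=512, extent=20e-6, pad_factor=8)
print(f"optimal collection NA = {res.optimal_na:.2f}")
```

prints (the NA scan takes ~30 s at the production grid):

```
2.328 pJ per pulse pair
5.30 K peak focal heating
optimal collection NA = 0.33
```

2.33 pJ is the heat left in DMSO by one pulse pair at the measured 0.72%
SRS modulation depth; a single deposition event heats the focal center by
5.3 K; and a condenser NA of ≈ 0.33 captures the full redistributed lobe
of the thermal-lens signal, past which the on/off difference integrates
back toward zero.

The same chains are scriptable from the shell; each subcommand writes
CSV/TIFF outputs plus a provenance record (config hash, seed, versions):

```
srpsim simulate-temperature --out run/      # ΔT and Δn volumes (TIFF+JSON)
srpsim scan-na --out run/                   # NA ↦ P_on, P_off, contrast (CSV)
srpsim sweep-modulation --out run/          # duty × f_mod signal/SNR maps
srpsim phantom --out run/ --seed 3          # synthetic hyperspectral stack
srpsim unmix run/phantom.tiff run/references.csv --out run/
srpsim dilution --out run/ --seed 1         # calibration series + 3σ LOD
```

Example: `srpsim simulate-temperature --out run/` prints

```
energy/pulse-pair = 2.328 pJ; peak dT = 5.30 K; peak dn = -2.612e-03
```

Configuration files are YAML with explicit units
(`pump_power: 28 mW`, `raman_shift: 2912 cm^-1`); unknown keys are
rejected.

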