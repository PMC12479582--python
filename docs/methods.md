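# Methods

`srpsim` models the signal chain of a stimulated Raman photothermal (SRP)
microscope — SRS energy deposition, focal heating, the thermo-optic lens,
far-field probe redistribution, and lock-in readout — and implements the
hyperspectral analysis operators used around such an instrument. This note
records the model assumptions, the defaults and why they were chosen, the
numerical choices, and what the synthetic-data tests do and do not show.

## Energy deposition

Each pump/Stokes pulse pair converts pump photons to Stokes photons when
their frequency difference matches a vibration; the vibrational quantum
(h·c·Ω per converted photon, Ω the Raman shift) thermalizes in the focal
volume. The deposited energy per pulse pair is

    E = f_on · (P_pump / f_rep) · Ω / ν̃_pump,

where `f_on` is the fractional pump loss while the Stokes beam is on and
`ν̃_pump = 1/λ_Stokes + Ω` is the pump photon wavenumber. A lock-in
referenced to a 50%-duty square modulation reports the fundamental of the
pump loss, so the measured modulation depth `md` maps to `f_on = 2·md`.
With the default fiber-laser operating point (28 mW pump, 40 MHz, 0.72%
depth, 2912 cm⁻¹, Stokes 1031 nm) this gives E = 2.33 pJ. `f_on` can also
be supplied directly when the on-state loss has been measured without a
lock-in.

The Stokes wavelength (1031 nm) is the package default for this laser
class and is configurable; only the ratio Ω/ν̃_pump depends on it, so the
sensitivity is mild.

## Focal heating

The SRS excitation point-spread function is modeled as a 3D Gaussian
(default σ_lateral = 0.17 µm, σ_axial = 0.45 µm for a 1.2-NA
excitation near 800 nm; configurable). Each deposition event is treated as
instantaneous — picosecond pulses against ≥ tens-of-ns thermal scales —
and evolves by free diffusion in an infinite homogeneous medium:

    ΔT(r, τ) = E / (ρc (2π)^{3/2} σx σy σz) · exp(−Σ rᵢ²/2σᵢ²),
    σᵢ²(τ) = σᵢ₀² + 2Dτ,   D = k/(ρc).

Pulse trains superpose linearly; square-wave modulation gates which pulses
fire. No coverslip heat sinking, convection, or temperature-dependent
properties are modeled. The closed-form amplitude, energy conservation
(ρc·∫ΔT dV = ΣE), linearity, and the second-moment growth law are enforced
as tests at the 0.5–1% level; they are the hard correctness surface of
this module.

Medium presets are literature bulk values (DMSO: ρ = 1100 kg·m⁻³,
c = 1950 J·kg⁻¹·K⁻¹, k = 0.20 W·m⁻¹·K⁻¹, dn/dT = −4.93×10⁻⁴ K⁻¹,
n = 1.477; plus water and 8 M urea), all overridable in the config.

**What "peak temperature" means here.** A single 2.33 pJ deposition with
the default focal volume raises the focal center by 5.3 K, of the same
order as the ~4 K a Gaussian-PSF energy-deposition model reports for these
conditions. Superposing a full 40 MHz train for 8 µs instead accumulates
to ~10⁲ K at the center, because the 3D diffusion tail (τ^{−3/2}) decays
slowly against the 25 ns pulse spacing. The package therefore reads the
single-map heating question as the per-deposition-event profile, and uses
that event's thermo-optic lens — whose ~0.02 rad probe phase also matches
the few-percent probe modulation depths such instruments report — for the
collection-NA analysis. The train-accumulation machinery remains available
(`temperature_field` at t > 0, `periodic_temperature_waveform`) and is
what the lock-in module uses for waveform *shapes*, where only the
linear-response shape, not the absolute scale, matters. A real scanned
measurement never parks the focus long enough to realize the static
accumulated value; modeling scan motion is out of scope.

## Thermal lens and probe propagation

Δn = ΔT · dn/dT pointwise. The probe (765 nm CW, paraxial Gaussian) is
propagated through the Δn volume by symmetric split-step scalar
angular-spectrum propagation: thin phase screens φ = k₀·Δn·dz between
half free-space steps at the medium wavenumber n₀k₀. The lens is weak
(|Δn| < 5×10⁻³) and smooth, so a scalar treatment is standard;
polarization and high-NA vector effects are not modeled. Evanescent
angular components are discarded, phase screens conserve power exactly,
and a Δn ≡ 0 volume reduces to pure free-space propagation (tested to
1e−10 relative).

Far fields are Fraunhofer transforms onto vacuum-referred direction
cosines kx/k₀, which equal the air-side collection NA of the condenser for
a sample in a medium of index n₀ (Snell invariance of the transverse
wavevector). Zero-padding (default 8× for production scans) refines the
angular sampling to ~0.005 NA so a 0.01 NA scan step is meaningful;
Parseval consistency is exact by construction.

Default numerical grid: 512×512 transverse points over 20 µm, 40 z-slices
over ±3σ_z (lateral extent of the lens volume ±5σ). Grid-refinement moves
the optimal NA by at most one 0.01 step (tested at 256² vs 512²).

### Contrast metric and the optimal collection NA

Two contrast definitions are implemented:

* **absolute**, `P_on(NA) − P_off(NA)` — the far-field on/off difference
  pattern integrated over the collection cone. Power conservation pins it
  to zero at NA → 0 and at full aperture, so it has an interior maximum:
  the NA at which the condenser has captured the whole redistributed lobe
  of the thermal-lens signal. This is the default for the optimal-NA
  search, and with the default DMSO lens it peaks at NA ≈ 0.33.
* **relative**, `(P_on − P_off)/P_off` — the fractional modulation a
  detector behind the aperture sees. For a weak, approximately Gaussian
  lens this is flat at small NA and decays monotonically (a standard
  thermal-lens result recovered by a small-phase Gaussian-beam
  calculation), so it has no interior optimum and is reported for
  detector sizing, not for the NA search.

### Probe geometry defaults

The probe waist (0.6 µm) corresponds to a 2×-expanded ~1.5 mm beam
under-filling a 60×/1.2-NA objective; its far-field 1/e² divergence
(air-side NA ≈ 0.41) sits inside the 0.55 condenser range. The probe
focus offset is the lever that converts the symmetric lens into a
first-order far-field signal: at zero offset the contrast nulls, and the
offset scan is antisymmetric. The default offset, −2.5 µm ≈ −1.15
Rayleigh ranges (in-medium), is the argmax of that scan at NA 0.32. Both
are configurable; the optimal NA moves by roughly ∓0.03 per ±0.1 µm of
probe waist, which is why the optimum is quoted with a ±0.05 band.

## Lock-in model

The optics are quasi-static: thermal timescales dwarf the optical
transit, so each temperature snapshot maps to a steady collected power.
In the small-phase regime the collected power is linear in the lens
amplitude; the default trace path therefore multiplies the periodic
steady-state center-temperature waveform by a precomputed sensitivity
(relative contrast per kelvin, one propagation pair), with
`optics="full"` re-propagating per snapshot for verification. The lens
spatial profile is frozen to the fresh-deposition Gaussian; the modulated
part of the field is dominated by the most recent depositions, which
retain near-initial width.

Demodulation is a single-bin projection over an integer number of
reference periods; the amplitude convention is the **peak** fundamental
amplitude (a pure A·sin demodulates to A). The periodic steady state is
declared when the waveform peak changes < 0.1% between successive history
periods.

Duty/frequency sweeps hold the laser **peak** power fixed (the
power-limited fiber-laser comparison): per-pulse energy is constant and
only the gating changes. The thermal response is linear and
time-invariant, so the demodulated fundamental scales as sin(π·duty) and
peaks at 50% duty — an exact grid argmax, not a fitted one. The noise
model (white floor plus 1/f with a configurable knee, default 600 kHz) is
an instrument description, not a physics prediction: with white-only noise
the SNR is non-increasing in modulation frequency above the thermal
corner, and a 1/f knee produces an interior SNR optimum. The knee value
is probe-laser-specific and deliberately excluded from any quantitative
claim. SNR is defined as fundamental amplitude over noise amplitude in
the demodulation bandwidth (default 1 Hz).

## LASSO unmixing

Per pixel, minimize ½‖d − cS‖² + β‖c‖₁ by cyclic coordinate descent with
soft-thresholding (convergence: max coefficient change < 1e−8, default
cap 10⁴ sweeps). The solver is written out rather than wrapped because
the objective is the package's core analysis; external solvers
(scikit-learn, a brute-force sign-pattern QP) appear only as test
oracles. Reference rows are L2-normalized internally and coefficients
rescaled back, so β is always referred to unit-norm references — this
changes the meaning of β and is therefore stated everywhere β is
documented. The default heuristic β = 0.1·max|S·d| sits safely inside the
solution path (β above the max correlation yields the all-zero solution);
`beta_grid_report` tabulates the reconstruction-error/sparsity trade-off
for empirical tuning. Nonnegativity is off by default (the unmixing
objective does not require it) and available as a one-sided threshold.

Companion operators: Pearson spectral fidelity; two-color (e.g.
2850/2930 cm⁻¹) ratio maps with a masked floor on the denominator;
median despeckling with reflected edges for coherent-probe interference
fringes; and bead-profile resolution by least-squares Gaussian fit with
quadrature deconvolution of the bead diameter,
resolution = √(FWHM² − d_bead²) — the conventional Gaussian-on-Gaussian
assumption, flagged `bead_limited` when FWHM ≤ d_bead. (E.g. a 260 nm
fitted FWHM with 100 nm beads deconvolves to 240 nm.)

## Synthetic data

Generators are pure functions of (parameters, seed). Reference spectra
are sums of Gaussian bands; the default four-component C-H set (lipid
2848/2888, protein 2930/2875, cholesterol 2870/2904, nucleus 2955/2995
cm⁻¹) keeps realistic assignments while bounding pairwise spectral
correlation at ≈ 0.54, the discriminability under which support recovery
at pixel SNR 20 with the default β heuristic reaches F1 ≥ 0.9. Phantoms
are smooth cell-like blobs (cytoplasm ellipse, nucleus blob, droplets) —
deliberately not realistic morphology. Noise is additive Gaussian (no
Poisson shot noise); fringes are multiplicative sinusoids, the etalon
signature of a long-coherence probe at refractive-index steps. At zero
noise a phantom satisfies the unmixing generative model exactly, enabling
exact-recovery tests; passing them demonstrates solver correctness, not
robustness to real-cell spectral variability, baselines, or scattering.

Serial-dilution series are linear with Gaussian noise; the limit of
detection uses the 3σ_blank/slope convention (σ_blank from blank
replicates when ≥ 3 are present). Measured instrument LODs are not
reproduced — only the estimator's calibration behavior is tested.

## Problem sizes

Production scans use the 512²/8×-padded optics grid (optimal-NA scan
≈ 30 s); unit tests use 64–256² grids and 16–32-pixel phantoms, chosen so
the full suite runs in under a minute while every oracle keeps its stated
tolerance.

## Known limitations

Scalar paraxial optics (no vector focusing, apodization, aberrations);
infinite-medium thermodynamics (no interfaces or flow); frozen lens shape
in the time-trace path; Gaussian (not physical-optics) excitation PSF; no
electronics chain beyond the noise model; no baseline correction or
denoising beyond the median filter.
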