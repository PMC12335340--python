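# mrsiglx

Separate mapping of glutamate (Glu) and glutamine (Gln) by long-TE sLASER
<sup>1</sup>H MR spectroscopic imaging at 3 T — simulation, fitting and
absolute quantification, testable end-to-end on synthetic data.

## The problem

Glu and Gln are key metabolites in glioma biology with distinct roles, but
their proton spectra overlap almost completely at clinical field strengths,
so conventional MRS reports only their sum (Glx). Their multiplets are
J-coupled, however, and J-modulation makes the spectral patterns evolve
with echo time: at TE ≈ 120 ms with an sLASER echo train the Glu pattern
stays largely in phase while Gln develops distinctive anti-phase
components, enough for a linear-combination fit to separate the two.

This package implements that method for researchers working on MRSI
protocol design and tumor metabolism:

* **`spin_sim`** — density-matrix simulation of metabolite spin systems
  (shipped chemical shifts and J-couplings for the 15-metabolite fitting
  basis plus 2HG) under an idealized sLASER echo train at arbitrary TE,
  producing per-proton-normalized basis sets:
  H = Σᵢ 2πνᵢ I<sub>z,i</sub> + Σ<sub>i&lt;j</sub> 2πJᵢⱼ **Iᵢ·Iⱼ**, with
  ideal 90°/180° rotations and T₂ neglected during the train.
* **`synthetic_data`** — phantoms and brain-tumor MRSI grids with
  subregion label maps, tissue fractions, a PSF-matched water reference
  and scan–rescan replicates (SNR ≈ 27, linewidth ≈ 0.029 ppm).
* **`lcm_fit`** — frequency-domain linear-combination fitting with
  non-negative amplitudes, phases, a global shift, Lorentzian–Gaussian
  damping and a rigid spline baseline; uncertainty via the Fisher
  information: CRLB% = 100·√([F⁻¹]ₘₘ)/Cₘ, and the coefficient of modeling
  covariance CMC(m₁,m₂) = [F⁻¹]₁₂/√([F⁻¹]₁₁[F⁻¹]₂₂) — near −1 means the
  two metabolites cannot be told apart. Spectral QC: reject FWHM > 0.1 ppm,
  SNR < 3, or tCho CRLB ≥ 10 %.
* **`quantify`** — internal-water referencing,
  C<sub>met</sub> = (S<sub>met</sub>/S<sub>W</sub>)·(N<sub>W</sub>/N<sub>met</sub>)·C<sub>W</sub>,
  with tissue-water maps from WM/GM/CSF fractions, k-space PSF matching,
  contralateral referencing and steady-state T₁/T₂ corrections.
* **`subregions`** — voxel→{ET, NETC, SNFH, CL} assignment: exact
  label-fraction counting, VOI-edge exclusion, the >50 % rule and top-3
  selection with tie extension.
* **`stats_report`** — Bland–Altman scan–rescan analysis, Shapiro–Wilk
  gated ANOVA/Tukey vs Kruskal–Wallis/Dunn(BH) subregion comparisons, and
  the full pipeline orchestration.

## Worked example

Fit a noiseless simulation of the brain-mimicking phantom (10 mM Cr,
10 mM Glu, 5 mM Gln, 3 mM Cho, 3 mM GSH, 2 mM GABA, 7.5 mM mI, 5 mM Lac,
12.5 mM NAA) at TE 120 ms:

```python
from mrsiglx import (PHANTOM_2, NoiseModel, fit_spectrum,
                     generate_phantom_spectrum)
from mrsiglx.spin_sim import AcquisitionParams, make_basis_set

acq = AcquisitionParams()                      # 127.73 MHz, 2000 Hz, 2048 pts
basis = make_basis_set(list(PHANTOM_2.concentrations), te=120.0, acq=acq)
quiet = NoiseModel(noise_sd=0.0, linewidth_jitter_hz=0.0,
                   freq_jitter_sd=0.0, phase_jitter_sd=0.0)
grid = generate_phantom_spectrum(PHANTOM_2, basis, quiet, seed=0)
fit = fit_spectrum(grid.spectra[0, 0], basis)

cr = fit.concentrations["Cr"]
for m in ("Glu", "Gln", "Cho", "Lac"):
    print(f"{m}/Cr = {fit.concentrations[m] / cr:.3f}")
print(f"FWHM = {fit.fwhm_ppm:.4f} ppm")
```

prints

```
Glu/Cr = 1.000
Gln/Cr = 0.500
Cho/Cr = 0.300
Lac/Cr = 0.500
FWHM = 0.0281 ppm
```

i.e. the fit recovers the true concentration ratios of the phantom
(10/10, 5/10, 3/10, 5/10 relative to creatine) exactly in the noiseless,
relaxation-free setting; the linewidth is the applied Lorentzian–Gaussian
broadening. With Cr known to be 10 mM, `fit.concentrations["Gln"] * 10 / cr`
is the absolute Gln concentration (5.0 mM).

A full synthetic tumor study — basis simulation, grid generation, fitting,
QC, water-referenced quantification, subregion assignment and statistics —
runs from one config:

```bash
mrsiglx run --seed 5 --out demo_run          # writes fits.csv, summary.json,
                                             # Glu/Gln/CMC maps (NIfTI)
mrsiglx simulate-basis --te 120 --out basis_te120.h5
```

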