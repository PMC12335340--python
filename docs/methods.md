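# Methods

This note records the models, conventions and design choices behind
`mrsiglx`, and what the synthetic experiments do and do not demonstrate.

## Spin simulation

Metabolite signals are computed by density-matrix evolution of each
coupled proton block under the full strong-coupling rotating-frame
Hamiltonian (Zeeman offsets plus scalar couplings `2πJ Iᵢ·Iⱼ`). The
sLASER sequence is idealized: an instantaneous 90° excitation
(Iz → Ix), four instantaneous 180° rotations about x, free evolution in
between, acquisition from the top of the final echo. T₂ decay during the
echo train is neglected, so TE enters only through J-modulation and
strong-coupling mixing. Mutually uncoupled blocks (e.g. the N-trimethyl
protons of choline, acetyl CH₃ groups) are propagated independently and
summed; magnetically equivalent protons are simulated as distinct spins
with identical shifts, with a hard cap of 8 spins per coupled block
(Hilbert dimension 256) and an explicit error rather than truncation.

Production propagation diagonalizes the block Hamiltonian once and
evaluates the FID from eigenbasis transition amplitudes; the test suite
contains an independent brute-force propagator (repeated matrix
exponentials at 1 µs steps) that agrees to relative L2 ≲ 1e−12 on all
shipped systems with blocks ≤ 6 spins.

**Echo-train timing.** The five free-evolution delays are configurable.
Two schemes ship:

* `vendor` (default): the two adiabatic refocusing pairs are applied
  promptly after excitation — delays (e, 2e, 2e, (TE−4e)/2, (TE−4e)/2−e)
  with pair spacing e = 6 ms — matching how clinical sLASER uses the
  pulse pairs for slice localization immediately after excitation and
  leaves the remainder of the echo time as free evolution.
* `symmetric`: evenly spread pulses (TE/8, TE/4, TE/4, TE/4, TE/8).

Both refocus chemical shift exactly and are identical in the weak-coupling
limit; they differ in strong-coupling evolution. The vendor scheme is the
default because it reproduces the known phenomenology of the method: the
Glu/Gln spectral-overlap minimum falls at TE ≈ 110–120 ms (the TE at which
the protocol operates), whereas the symmetric scheme would put it near
80 ms. The choice was made on this physical ground; the timing vector
remains injectable for other implementations.

**Normalization.** Basis FIDs are scaled so one proton contributes unit
amplitude at TE → 0; a basis entry's TE-0 amplitude equals its proton
count. Fitted amplitudes are therefore on the same mM scale as the
generator concentrations when data and basis share the simulation.

**Constants.** Chemical shifts and J-couplings are shipped as plain-text
TSVs transcribed from the standard proton compendium values. GPC is
modelled by its choline moiety (the glycerol backbone lies under water);
glucose by the β anomer; a few NAAG/GSH/2HG couplings are approximate
literature values. Since the same tables drive both simulation and
fitting, closure experiments are insensitive to small constant errors;
absolute pattern fidelity matters only for the TE-behaviour results, which
are dominated by the accurately known Glu/Gln/NAA/Cr parameters.

## Synthetic data

The generator emulates a 2D sLASER MRSI protocol at 3 T
(127.73 MHz, 2000 Hz spectral width, 2048 points, carrier on water at
4.70 ppm; all configurable). Per-voxel spectra are concentration-weighted
sums of basis FIDs with:

* Lorentzian 1.5 Hz + Gaussian 2.7 Hz damping (Voigt FWHM ≈ 3.6 Hz
  ≈ 0.028 ppm), per-voxel Gaussian-width jitter SD 1.1 Hz to emulate the
  observed FWHM spread (≈ 0.03 ± 0.01 ppm);
* frequency jitter SD 0.8 Hz and zero-order phase jitter SD 2°;
* i.i.d. complex Gaussian time-domain noise. When a target SNR is given
  (default 27), the noise SD is calibrated from the grid-mean noiseless
  peak height so the fitted spectral SNR lands on target.

**SNR scale.** Spectral SNR is reported on the LCModel scale — maximum
fitted metabolite peak over *twice* the frequency-domain noise SD —
because the in vivo quality figures this generator emulates (SNR ≈ 27,
and the SNR < 3 rejection rule) are quoted on that scale. The factor
matters: with the plain peak/σ convention, all simulated CRLB levels
would sit a uniform ~2× above the corresponding in vivo values.

Healthy scenes use standard brain concentrations (tNAA 14, tCr 8,
tCho 2, mI 6.5 mM, …) with Glu 10.84 and Gln 2.94 mM, the contralateral
means of the glioma cohort that also serve as the CL subregion defaults.
Tumor scenes draw per-voxel Glu/Gln from the reported subregion
distributions (NETC 5.35 ± 4.45 / 4.92 ± 3.38, SNFH 7.39 ± 2.62 /
9.17 ± 6.84, ET 7.60 ± 4.16 / 7.20 ± 4.42 mM; draws truncated at 0) in
concentric NETC/ET/SNFH regions, and scale the remaining metabolites by
conventional tumor factors (reduced NAA, elevated choline and lactate).
Contralateral tissue is 72.9 % WM / 18.8 % GM / 8.3 % CSF. The default
16×16 grid with a centered 12×12 VOI yields exactly 100 analyzed voxels
after edge exclusion. The unsuppressed water companion is a single
resonance at the carrier with amplitude 2 protons × tissue-water
concentration, low-pass filtered in k-space (default 8×8) to emulate the
coarser water acquisition.

What the generator does **not** model: macromolecule/lipid backgrounds at
short TE are off by default (broad Gaussian humps are injectable),
relaxation-weighted signal amplitudes (generation is relaxation-free; the
correction machinery is exercised separately), colored noise, k-space
reconstruction artifacts, B₀/B₁ field maps, and real segmentation errors.
Passing tests therefore demonstrate method correctness and calibrated
self-consistency, not in vivo robustness.

## Fitting

The frequency-domain model over the 0.2–4.2 ppm window is
`exp(i(φ₀+φ₁ν)) Σₘ Cₘ Bₘ(ν−δ) L(ν) + baseline(ν)`, with a common
Lorentzian–Gaussian damping L applied in the time domain, one global
shift δ (|δ| ≤ 0.05 ppm) and a cubic B-spline baseline with knots every
5 ppm — over a 4-ppm window this is a cubic polynomial, i.e. deliberately
rigid, appropriate at TE 120 ms where short-T₂ baseline signals have
decayed below ~0.5 %. For short-TE comparison runs a denser knot spacing
(e.g. 0.3 ppm) and fixed macromolecule/lipid Gaussians at
0.9/1.3/1.4/1.7/2.0 ppm can be enabled in `FitConfig`.

For fixed nonlinear parameters the amplitudes are solved by NNLS after
QR-projecting out the unconstrained baseline columns (real and imaginary
channels stacked); the five nonlinear parameters are optimized by bounded
trust-region least squares with deterministic multi-starts over the shift
(0, ∓0.03 ppm), skipping remaining starts once the residual RMS reaches
1.2× the noise floor. Non-convergence is flagged, not raised. Noise SD is
estimated from the signal-free 9–11 ppm tail unless supplied.

**Uncertainty.** The Fisher matrix is F = JᵀJ/σ² with J the design over
metabolite amplitudes at the fit point (nuisance conditioned). CRLB% and
CMC are read off F⁻¹. A nuisance-marginalized covariance (full Jacobian
over amplitudes, baseline, phases, shift and damping) is available as
`marginalized_covariance` / `FitConfig(marginalize_nuisance=True)`; it is
the bound an efficient estimator can actually attain when the nuisance
parameters are free, and the Monte-Carlo consistency test checks the
empirical spread against it. The amplitude-conditioned CMC at short TE is
strongly negative (≈ −0.5 between Glu and Gln at TE 40 ms); regularized
fitters that impose soft amplitude priors report milder correlations for
the same data — re-implementing such regularization is out of scope here.

## Quantification

Water concentration per voxel is the fraction-weighted sum of
compartment water contents (WM 36 080, GM 43 300, CSF 53 840 mM;
editable YAML, optional CSF-exclusion mode). PSF matching truncates the
map's 2D spectrum to a Hermitian-symmetric pass-band |k| ≤ keep/2
(half-weight edges for even extents, optional Hamming weighting with unit
DC gain), conserving means and sums. Water amplitudes are integrated over
4.2–5.2 ppm as a complex band sum after subtracting the one-sided-DFT
pedestal (half the first FID point spread flat across all bins); residual
Lorentzian-tail leakage keeps absolute closure within ~2–3 %. Relaxation
corrections use exp(−TE/T₂)(1−exp(−TR/T₁)) with literature 3 T values
(TR default 1700 ms) in an editable table; contralateral referencing
scales a voxel's signal by a QC-accepted CL reference concentration and
is exactly consistent with direct water referencing under spatially
uniform water and relaxation.

## Subregions and statistics

Subregion fractions are exact integer cell counts per MRSI voxel
footprint; ties in the top-3 selection compare those counts, avoiding
float ambiguity. VOI-edge exclusion erodes the mask with 8-adjacency.
Assignment requires fraction > 0.5; fewer than three candidates are used
as-is and flagged, none excludes the subregion for that case.

Group comparisons operate on case-level subregion means (one value per
scene/subject). Shapiro–Wilk at α = 0.05 on each group gates the branch:
ANOVA + Tukey HSD when all pass, otherwise Kruskal–Wallis followed by
Dunn's rank-sum z-tests (tie-corrected) with Benjamini–Hochberg
adjustment. Degenerate (zero-variance) inputs are flagged rather than
tested. Bland–Altman bias and ±1.96 SD limits of agreement summarize
scan–rescan agreement; the reproducibility experiment pools the voxel
pairs of ten simulated session pairs into one analysis, mirroring how
multi-subject sessions are pooled in practice, and additionally checks
that per-pair biases are centered on zero.

## Problem sizes and determinism

The shipped experiments run at desk scale: 100-voxel grids, 10 scan-rescan
pairs, 1000 statistical-calibration replicates, oracle checks on ≤ 6-spin
blocks — the full suite and the acceptance script each complete in a few
minutes on one CPU. Every generator output is a pure function of
(configuration, seed); identical config+seed reproduce CSV outputs
bit-for-bit.

## Known limitations

* Ideal-pulse simulation: finite adiabatic pulse durations partially
  suppress J-evolution during the pulses; strongly coupled patterns shift
  slightly with the true vendor timing. The delay vector is injectable.
* The amplitude-conditioned CMC/CRLB differ from regularized-fitter
  outputs (see Fitting).
* Water-referenced absolute values carry a ~2–3 % band-integration bias;
  ratio and contralateral-referenced results are unaffected.
* Spin-constant approximations for NAAG/GSH/2HG limit pattern fidelity
  for those metabolites.
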