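"""Synthetic phantoms and brain-tumor MRSI grids.

The generators emulate the study conditions of a 2D sLASER MRSI protocol at
3 T: per-voxel spectra built as concentration-weighted sums of simulated
basis spectra, Lorentzian-Gaussian linewidths around 0.029 ppm, i.i.d.
complex Gaussian time-domain noise calibrated to a target SNR of ~27, a
companion unsuppressed-water grid at lower nominal resolution, and
scan-rescan replicates sharing ground truth but not noise. The default
16x16 grid with a 12x12 VOI yields 100 interior voxels after edge exclusion.

Every generator output is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spin_sim import AcquisitionParams, BasisSet, LineShape

__all__ = [
    "Composition",
    "NoiseModel",
    "GroundTruthScene",
    "MRSIGrid",
    "SceneGeometry",
    "PHANTOM_1",
    "PHANTOM_2",
    "HEALTHY_BRAIN_MM",
    "SUBREGION_CLASSES",
    "SUBREGION_GLU_MM",
    "SUBREGION_GLN_MM",
    "generate_phantom_spectrum",
    "make_tumor_scene",
    "make_healthy_scene",
    "generate_mrsi_grid",
    "generate_scan_rescan",
]

#: subregion label codes: contralateral/normal, enhancing tumor,
#: non-enhancing tumor core, surrounding non-enhancing FLAIR hyperintensity
SUBREGION_CLASSES = ("CL", "ET", "NETC", "SNFH")

#: healthy-brain metabolite concentrations (mM) used for the synthetic
#: contralateral/normal tissue; Glu and Gln follow the contralateral means
#: of the glioma cohort, the rest are standard healthy-brain values.
HEALTHY_BRAIN_MM: dict[str, float] = {
    "NAA": 12.5, "NAAG": 1.5, "Cho": 1.0, "GPC": 1.0, "Cr": 8.0,
    "Glu": 10.84, "Gln": 2.94, "mI": 6.5, "Lac": 0.6, "GABA": 1.5,
    "GSH": 2.0, "Gly": 1.0, "Ala": 0.4, "Glc": 1.5, "Val": 0.3,
}

#: tumor-subregion Glu/Gln distributions (mean, SD in mM)
SUBREGION_GLU_MM = {"CL": (10.84, 2.94), "NETC": (5.35, 4.45),
                    "SNFH": (7.39, 2.62), "ET": (7.60, 4.16)}
SUBREGION_GLN_MM = {"CL": (2.94, 1.35), "NETC": (4.92, 3.38),
                    "SNFH": (9.17, 6.84), "ET": (7.20, 4.42)}

#: multiplicative change of the remaining metabolites inside tumor tissue
#: relative to normal brain (reduced neuronal markers, elevated choline and
#: lactate), used when drawing tumor concentration maps.
_TUMOR_SCALE = {
    "ET":   {"NAA": 0.45, "NAAG": 0.45, "Cr": 0.75, "Cho": 1.8, "GPC": 1.8,
             "mI": 1.2, "Lac": 4.0, "Gly": 2.0},
    "NETC": {"NAA": 0.25, "NAAG": 0.25, "Cr": 0.5, "Cho": 1.2, "GPC": 1.2,
             "mI": 0.8, "Lac": 6.0, "Gly": 2.5},
    "SNFH": {"NAA": 0.7, "NAAG": 0.7, "Cr": 0.9, "Cho": 1.4, "GPC": 1.4,
             "mI": 1.3, "Lac": 2.0, "Gly": 1.5},
}


@dataclass(frozen=True)
class Composition:
    """A phantom composition: metabolite -> concentration (mM)."""

    concentrations: Mapping[str, float]
    ph_label: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")


PHANTOM_1 = Composition({"Glu": 20.0, "Gln": 20.0, "Cr": 10.0}, ph_label="pH 7.1")
PHANTOM_2 = Composition(
    {"Cr": 10.0, "Glu": 10.0, "Gln": 5.0, "Cho": 3.0, "GSH": 3.0,
     "GABA": 2.0, "mI": 7.5, "Lac": 5.0, "NAA": 12.5},
    ph_label="pH 7.2",
)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition imperfections applied per voxel.

    ``noise_sd`` is the time-domain complex-noise SD per real/imaginary
    component; 0 with a ``target_snr`` passed to the generator means
    "calibrate to that SNR". Linewidths are FWHM in Hz; the per-voxel
    Gaussian width is jittered with SD ``linewidth_jitter_hz`` (truncated
    at 0) to emulate the in vivo FWHM spread.
    """

    noise_sd: float = 0.0
    lorentz_hz: float = 1.5
    gauss_hz: float = 2.7
    linewidth_jitter_hz: float = 1.1
    freq_jitter_sd: float = 0.8    # Hz
    phase_jitter_sd: float = 2.0   # degrees
    water_lorentz_hz: float = 4.0

    def __post_init__(self) -> None:
        if min(self.noise_sd, self.lorentz_hz, self.gauss_hz,
               self.linewidth_jitter_hz, self.freq_jitter_sd,
               self.phase_jitter_sd) < 0:
            raise ValueError("noise-model SDs must be non-negative")


@dataclass
class SceneGeometry:
    """Concentric tumor-subregion geometry on the MRSI grid: an NETC core,
    an ET shell and an SNFH shell centred at ``tumor_center`` inside a
    normal background; radii in voxel units, strictly increasing."""

    grid_dims: tuple[int, int] = (16, 16)
    voxel_size_mm: tuple[float, float, float] = (6.0, 6.0, 12.0)
    voi: tuple[int, int] = (12, 12)
    tumor_center: tuple[float, float] = (7.0, 6.5)
    netc_radius: float = 1.2
    et_radius: float = 2.4
    snfh_radius: float = 3.8

    def __post_init__(self) -> None:
        if not (0 < self.netc_radius < self.et_radius < self.snfh_radius):
            raise ValueError("subregion radii must be strictly increasing "
                             "(overlapping regions are not allowed)")


@dataclass
class GroundTruthScene:
    """Per-voxel ground truth driving a synthetic MRSI acquisition."""

    grid_dims: tuple[int, int]
    voxel_size_mm: tuple[float, float, float]
    labels: np.ndarray                      # int codes into SUBREGION_CLASSES
    tissue_fractions: np.ndarray            # (ny, nx, 3) WM/GM/CSF
    conc_maps: dict[str, np.ndarray]        # metabolite -> (ny, nx) mM
    voi_mask: np.ndarray                    # boolean (ny, nx)

    def __post_init__(self) -> None:
        fsum = self.tissue_fractions.sum(axis=-1)
        if not np.allclose(fsum, 1.0, atol=1e-9):
            raise ValueError("tissue fractions must sum to 1 per voxel")
        for m, c in self.conc_maps.items():
            if np.any(c < 0):
                raise ValueError(f"negative concentration map for {m}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    def label_names(self) -> np.ndarray:
        return np.asarray(SUBREGION_CLASSES)[self.labels]


@dataclass
class MRSIGrid:
    """Per-voxel complex spectra plus acquisition metadata."""

    spectra: np.ndarray                     # (ny, nx, n_points), fftshifted
    acq: AcquisitionParams
    te: float
    noise_sd: float
    seed: int
    water_spectra: np.ndarray | None = None
    water_matrix: tuple[int, int] | None = None
    scene: GroundTruthScene | None = None

    @property
    def grid_dims(self) -> tuple[int, int]:
        return self.spectra.shape[:2]

    @property
    def ppm_axis(self) -> np.ndarray:
        return self.acq.ppm_axis()


# ---------------------------------------------------------------------------

def _broadened_voxel_spectra(
    fids: np.ndarray,           # (nvox, n_points) noiseless metabolite FIDs
    acq: AcquisitionParams,
    noise: NoiseModel,
    rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    nvox, npts = fids.shape
    t = acq.time_axis()
    gauss = np.clip(
        noise.gauss_hz + noise.linewidth_jitter_hz * rng.standard_normal(nvox),
        0.0, None,
    )
    dfreq = noise.freq_jitter_sd * rng.standard_normal(nvox)
    dphase = np.deg2rad(noise.phase_jitter_sd) * rng.standard_normal(nvox)
    env = np.exp(
        -np.pi * noise.lorentz_hz * t[None, :]
        - (np.pi * gauss[:, None] * t[None, :]) ** 2 / (4 * np.log(2))
        + 1j * (2 * np.pi * dfreq[:, None] * t[None, :] + dphase[:, None])
    )
    fids = fids * env
    if noise_sd > 0:
        fids = fids + noise_sd * (
            rng.standard_normal((nvox, npts)) + 1j * rng.standard_normal((nvox, npts))
        )
    return np.fft.fftshift(np.fft.fft(fids, axis=1), axes=1)


def _mix_fids(conc: np.ndarray, basis: BasisSet, metabolites: Sequence[str]) -> np.ndarray:
    if not metabolites:
        return np.zeros((conc.shape[0], basis.acq.n_points), dtype=complex)
    bmat = np.stack([basis.entries[m].fid for m in metabolites])
    return conc @ bmat


def _check_composition(names, basis: BasisSet) -> None:
    missing = [m for m in names if m not in basis.entries]
    if missing:
        raise KeyError(f"metabolites missing from basis: {missing}")


def noiseless_peak_height(
    conc: np.ndarray, basis: BasisSet, metabolites: Sequence[str],
    noise: NoiseModel, window: tuple[float, float] = (0.2, 4.2),
) -> float:
    """Mean (over voxels) maximum real peak of the broadened noiseless
    spectra inside the fit window; used for SNR calibration."""
    acq = basis.acq
    fids = _mix_fids(conc, basis, metabolites)
    t = acq.time_axis()
    ls = LineShape(noise.lorentz_hz, noise.gauss_hz)
    spec = np.fft.fftshift(np.fft.fft(fids * ls.envelope(t)[None, :], axis=1), axes=1)
    ax = acq.ppm_axis()
    sel = (ax >= window[0]) & (ax <= window[1])
    return float(spec.real[:, sel].max(axis=1).mean())


def noise_sd_for_snr(
    target_snr: float, conc: np.ndarray, basis: BasisSet,
    metabolites: Sequence[str], noise: NoiseModel,
) -> float:
    """Time-domain noise SD giving the target spectral SNR on the LCModel
    scale used by the fitter's estimator (peak height over twice the
    frequency-domain noise SD)."""
    peak = noiseless_peak_height(conc, basis, metabolites, noise)
    return peak / (2 * target_snr * np.sqrt(basis.acq.n_points))


def generate_phantom_spectrum(
    comp: Composition,
    basis: BasisSet,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> MRSIGrid:
    """Single-voxel phantom acquisition: concentration-weighted basis sum,
    broadened per the noise model, plus complex Gaussian noise."""
    noise = noise or NoiseModel()
    _check_composition(comp.concentrations, basis)
    rng = np.random.default_rng(seed)
    mets = list(comp.concentrations)
    conc = np.array([[comp.concentrations[m] for m in mets]])
    fids = _mix_fids(conc, basis, mets)
    spectra = _broadened_voxel_spectra(fids, basis.acq, noise, rng, noise.noise_sd)
    return MRSIGrid(
        spectra=spectra.reshape(1, 1, -1),
        acq=basis.acq,
        te=basis.te,
        noise_sd=noise.noise_sd,
        seed=seed,
    )


def _region_fractions(label: str, cl_mix: tuple[float, float, float],
                      tumor_mix: tuple[float, float, float]) -> tuple[float, ...]:
    return cl_mix if label == "CL" else tumor_mix


def make_tumor_scene(
    geometry: SceneGeometry | None = None,
    seed: int = 0,
    glu_mm: Mapping[str, tuple[float, float]] = SUBREGION_GLU_MM,
    gln_mm: Mapping[str, tuple[float, float]] = SUBREGION_GLN_MM,
    cl_tissue_mix: tuple[float, float, float] = (0.729, 0.188, 0.083),
    tumor_tissue_mix: tuple[float, float, float] = (0.50, 0.40, 0.10),
    background: Mapping[str, float] = HEALTHY_BRAIN_MM,
) -> GroundTruthScene:
    """Draw a tumor scene: concentric ET/NETC/SNFH subregions in a normal
    background, per-voxel Glu/Gln drawn from the configured subregion
    means/SDs (truncated at 0), tissue fractions fixed per region."""
    geom = geometry or SceneGeometry()
    ny, nx = geom.grid_dims
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - geom.tumor_center[0], xx - geom.tumor_center[1])
    labels = np.zeros((ny, nx), dtype=int)                       # CL
    labels[r <= geom.snfh_radius] = SUBREGION_CLASSES.index("SNFH")
    labels[r <= geom.et_radius] = SUBREGION_CLASSES.index("ET")
    labels[r <= geom.netc_radius] = SUBREGION_CLASSES.index("NETC")

    fractions = np.empty((ny, nx, 3))
    is_cl = labels == 0
    fractions[is_cl] = cl_tissue_mix
    fractions[~is_cl] = tumor_tissue_mix

    conc_maps: dict[str, np.ndarray] = {}
    for met, table in (("Glu", glu_mm), ("Gln", gln_mm)):
        out = np.empty((ny, nx))
        for code, name in enumerate(SUBREGION_CLASSES):
            mean, sd = table[name]
            sel = labels == code
            out[sel] = np.clip(mean + sd * rng.standard_normal(sel.sum()), 0.0, None)
        conc_maps[met] = out
    for met, c0 in background.items():
        if met in ("Glu", "Gln"):
            continue
        out = np.full((ny, nx), float(c0))
        for name, scales in _TUMOR_SCALE.items():
            sel = labels == SUBREGION_CLASSES.index(name)
            out[sel] = c0 * scales.get(met, 1.0)
        conc_maps[met] = out

    voi = np.zeros((ny, nx), dtype=bool)
    oy, ox = (ny - geom.voi[0]) // 2, (nx - geom.voi[1]) // 2
    voi[oy:oy + geom.voi[0], ox:ox + geom.voi[1]] = True

    return GroundTruthScene(
        grid_dims=geom.grid_dims,
        voxel_size_mm=geom.voxel_size_mm,
        labels=labels,
        tissue_fractions=fractions,
        conc_maps=conc_maps,
        voi_mask=voi,
    )


def make_healthy_scene(
    grid_dims: tuple[int, int] = (16, 16),
    voi: tuple[int, int] = (12, 12),
    concentrations: Mapping[str, float] = HEALTHY_BRAIN_MM,
    tissue_mix: tuple[float, float, float] = (0.729, 0.188, 0.083),
    voxel_size_mm: tuple[float, float, float] = (6.0, 6.0, 12.0),
) -> GroundTruthScene:
    """Uniform healthy-brain scene (all voxels contralateral/normal class)."""
    ny, nx = grid_dims
    labels = np.zeros((ny, nx), dtype=int)
    fractions = np.broadcast_to(np.asarray(tissue_mix), (ny, nx, 3)).copy()
    conc = {m: np.full((ny, nx), float(c)) for m, c in concentrations.items()}
    voi_mask = np.zeros((ny, nx), dtype=bool)
    oy, ox = (ny - voi[0]) // 2, (nx - voi[1]) // 2
    voi_mask[oy:oy + voi[0], ox:ox + voi[1]] = True
    return GroundTruthScene(grid_dims, voxel_size_mm, labels, fractions, conc, voi_mask)


def generate_mrsi_grid(
    scene: GroundTruthScene,
    basis: BasisSet,
    noise: NoiseModel | None = None,
    seed: int = 0,
    target_snr: float | None = 27.0,
    water_matrix: tuple[int, int] = (8, 8),
) -> MRSIGrid:
    """Synthesize a water-suppressed MRSI grid plus its unsuppressed-water
    companion from a ground-truth scene.

    If ``noise.noise_sd`` is 0 and ``target_snr`` is given, the noise SD is
    calibrated so the grid-mean spectral SNR matches the target. The water
    grid carries one resonance at the carrier with amplitude proportional to
    the PSF-filtered tissue-water concentration times 2 protons; its "lower
    resolution" is emulated by k-space truncation to ``water_matrix``.
    """
    from .quantify import psf_match, water_concentration_map, WaterContentTable

    noise = noise or NoiseModel()
    mets = [m for m in scene.conc_maps if m in basis.entries]
    _check_composition(mets, basis)
    acq = basis.acq
    ny, nx = scene.grid_dims
    conc = np.stack([scene.conc_maps[m].ravel() for m in mets], axis=1)

    noise_sd = noise.noise_sd
    if noise_sd == 0.0 and target_snr is not None:
        noise_sd = noise_sd_for_snr(target_snr, conc, basis, mets, noise)

    rng = np.random.default_rng(seed)
    fids = _mix_fids(conc, basis, mets)
    spectra = _broadened_voxel_spectra(fids, acq, noise, rng, noise_sd)

    cw_true = water_concentration_map(scene.tissue_fractions, WaterContentTable())
    wm = (min(water_matrix[0], ny), min(water_matrix[1], nx))
    cw_psf = psf_match(cw_true, wm)
    t = acq.time_axis()
    wenv = np.exp(-np.pi * noise.water_lorentz_hz * t)
    wfids = (2.0 * cw_psf.ravel())[:, None] * wenv[None, :]
    if noise_sd > 0:
        wfids = wfids + noise_sd * (
            rng.standard_normal(wfids.shape) + 1j * rng.standard_normal(wfids.shape)
        )
    wspec = np.fft.fftshift(np.fft.fft(wfids, axis=1), axes=1)

    return MRSIGrid(
        spectra=spectra.reshape(ny, nx, -1),
        acq=acq,
        te=basis.te,
        noise_sd=float(noise_sd),
        seed=seed,
        water_spectra=wspec.reshape(ny, nx, -1),
        water_matrix=water_matrix,
        scene=scene,
    )


def generate_scan_rescan(
    scene: GroundTruthScene,
    basis: BasisSet,
    noise: NoiseModel | None = None,
    seed_pair: tuple[int, int] = (0, 1),
    target_snr: float | None = 27.0,
) -> tuple[MRSIGrid, MRSIGrid]:
    """Two sessions of the same scene with independent noise realizations."""
    a = generate_mrsi_grid(scene, basis, noise, seed_pair[0], target_snr)
    b = generate_mrsi_grid(scene, basis, noise, seed_pair[1], target_snr)
    return a, b
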