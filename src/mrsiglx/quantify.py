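"""Absolute metabolite quantification.

Internal-water referencing converts fitted metabolite amplitudes into
millimolar tissue concentrations,

    C_met = (S_met / S_W) * (N_W / N_met) * C_W,

where S are signals, N proton counts (N_W = 2) and C_W the per-voxel tissue
water concentration derived from WM/GM/CSF fractions and literature water
content. Because metabolite and water are measured with the same sequence
and VOI, receive/transmit gain cancels in the ratio. The water-reference
grid has a much poorer point spread function than the segmentation-derived
water map, so the map is low-pass filtered in k-space to match before the
division. Once a contralateral reference concentration is known, tumor
voxels are scaled by their signal ratio to that reference. Relaxation
corrections use the standard mono-exponential steady-state factor
exp(-TE/T2) * (1 - exp(-TR/T1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "WaterContentTable",
    "RelaxationTable",
    "water_concentration_map",
    "psf_match",
    "resample_to_grid",
    "water_signal_from_spectrum",
    "relaxation_correction",
    "quantify_internal_water",
    "quantify_contralateral_ref",
]

N_WATER_PROTONS = 2


def _relaxation_yaml() -> dict:
    text = resources.files("mrsiglx.data").joinpath("relaxation.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class WaterContentTable:
    """Water concentration (mM) per tissue compartment."""

    wm: float = 36080.0
    gm: float = 43300.0
    csf: float = 53840.0

    def __post_init__(self) -> None:
        if not (self.csf >= self.gm >= self.wm > 0):
            raise ValueError("expected CSF >= GM >= WM > 0 water content")

    @classmethod
    def from_package_data(cls) -> "WaterContentTable":
        d = _relaxation_yaml()["water_content_mM"]
        return cls(wm=d["WM"], gm=d["GM"], csf=d["CSF"])

    def as_vector(self) -> np.ndarray:
        return np.array([self.wm, self.gm, self.csf])


@dataclass(frozen=True)
class RelaxationTable:
    """Literature T1/T2 (ms) for metabolites and tissue water, with TR/TE."""

    tr_ms: float = 1700.0
    te_ms: float = 120.0

    def metabolite(self, name: str) -> tuple[float, float]:
        d = _relaxation_yaml()
        entry = d["metabolite_relaxation_ms"].get(
            name, d["default_metabolite_relaxation_ms"])
        return float(entry["T1"]), float(entry["T2"])

    def water(self, tissue: str) -> tuple[float, float]:
        entry = _relaxation_yaml()["water_relaxation_ms"][tissue]
        return float(entry["T1"]), float(entry["T2"])


def water_concentration_map(
    fractions: np.ndarray,
    table: WaterContentTable | None = None,
    exclude_csf: bool = False,
) -> np.ndarray:
    """Per-voxel water concentration (mM) from (..., 3) WM/GM/CSF fractions.

    With ``exclude_csf`` the concentration refers to the non-CSF (brain
    parenchyma) compartment; pure-CSF voxels come back NaN.
    """
    table = table or WaterContentTable()
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[-1] != 3:
        raise ValueError("fractions must have a trailing WM/GM/CSF axis of 3")
    if not np.allclose(fractions.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("tissue fractions must sum to 1 per voxel")
    if not exclude_csf:
        return fractions @ table.as_vector()
    parenchyma = fractions[..., 0] + fractions[..., 1]
    num = fractions[..., 0] * table.wm + fractions[..., 1] * table.gm
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(parenchyma > 0, num / np.where(parenchyma > 0, parenchyma, 1.0), np.nan)
    return out


def psf_match(
    image: np.ndarray,
    acq_matrix: tuple[int, int],
    hamming: bool = False,
) -> np.ndarray:
    """Low-pass filter a map to the point spread function of an MRSI
    acquisition: its 2D spectrum is truncated (optionally Hamming-weighted)
    to the central ``acq_matrix`` k-space extent and transformed back on the
    original pixel grid. Conserves the DC component (spatially uniform maps
    pass unchanged) and the image sum."""
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    ky, kx = acq_matrix
    if ky > ny or kx > nx:
        raise ValueError("acq_matrix must not exceed the map dimensions")
    wy = _kspace_weights(ny, ky, hamming)
    wx = _kspace_weights(nx, kx, hamming)
    k = np.fft.fft2(image) * np.outer(wy, wx)
    return np.real(np.fft.ifft2(k))


def _kspace_weights(n: int, keep: int, hamming: bool) -> np.ndarray:
    """Hermitian-symmetric pass-band of nominal extent ``keep`` on the raw
    (unshifted) frequency axis; even extents carry half-weight edges so real
    maps stay real after filtering."""
    k = np.rint(np.fft.fftfreq(n, d=1.0 / n)).astype(int)
    half = keep // 2
    w = np.zeros(n)
    if keep % 2:
        w[np.abs(k) <= half] = 1.0
    else:
        w[np.abs(k) < half] = 1.0
        w[np.abs(k) == half] = 0.5
    if hamming:
        profile = 0.54 + 0.46 * np.cos(np.pi * k / max(half, 1))
        w = w * np.where(np.abs(k) <= half, profile, 0.0) / (0.54 + 0.46)
        w[k == 0] = 1.0  # unit DC weight: uniform maps unchanged
    return w


def resample_to_grid(image: np.ndarray, grid_dims: tuple[int, int]) -> np.ndarray:
    """Block-average a high-resolution map onto the MRSI grid (mean
    preserving); map dimensions must be integer multiples of the grid."""
    ny, nx = image.shape
    gy, gx = grid_dims
    if ny % gy or nx % gx:
        raise ValueError("map dimensions must be integer multiples of the grid")
    return image.reshape(gy, ny // gy, gx, nx // gx).mean(axis=(1, 3))


def water_signal_from_spectrum(
    spectrum: np.ndarray,
    ppm_axis: np.ndarray,
    band: tuple[float, float] = (4.2, 5.2),
) -> float:
    """Unsuppressed-water amplitude: magnitude of the complex spectral sum
    over the water band, normalized to FID units. Phase-insensitive and
    robust on a broad singlet.

    The one-sided DFT of a decaying FID spreads half of the first point as a
    flat pedestal over all bins; it is subtracted (the standard first-point-
    halving convention) before integrating, otherwise the band captures only
    about half the resonance.
    """
    sel = (ppm_axis >= band[0]) & (ppm_axis <= band[1])
    if not np.any(sel):
        raise ValueError("water band outside the ppm axis")
    n = spectrum.size
    pedestal = spectrum.sum() / n / 2.0
    return float(2.0 * np.abs((spectrum[sel] - pedestal).sum()) / n)


def relaxation_correction(tr_ms: float, te_ms: float, t1_ms: float, t2_ms: float) -> float:
    """Mono-exponential steady-state signal attenuation factor."""
    if tr_ms <= 0 or te_ms < 0:
        raise ValueError("TR must be positive and TE non-negative")
    if t1_ms <= 0 or t2_ms <= 0:
        raise ValueError("relaxation times must be positive")
    return float(np.exp(-te_ms / t2_ms) * (1.0 - np.exp(-tr_ms / t1_ms)))


def quantify_internal_water(
    s_met: float,
    s_water: float,
    n_met: int,
    c_water_mM: float,
    n_water: int = N_WATER_PROTONS,
    relax_met: float = 1.0,
    relax_water: float = 1.0,
) -> float:
    """Internal-water-referenced concentration (mM).

    ``s_met`` is the metabolite signal (fit amplitude x proton count in the
    per-proton basis convention), ``s_water`` the water amplitude from the
    reference grid. Relaxation factors divide the respective signals;
    returns NaN when the water signal vanishes.
    """
    if s_met < 0 or s_water < 0:
        raise ValueError("signals must be non-negative")
    if s_water == 0:
        return float("nan")
    return (s_met / relax_met) / (s_water / relax_water) * n_water / n_met * c_water_mM


def quantify_contralateral_ref(
    s_met: float, s_met_clref: float, c_met_clref: float
) -> float:
    """Contralateral-referenced concentration: scale the voxel signal by the
    known concentration of the contralateral reference."""
    if s_met_clref <= 0:
        raise ValueError("contralateral reference signal must be positive")
    if not np.isfinite(c_met_clref):
        raise ValueError("contralateral reference concentration is undefined")
    return s_met / s_met_clref * c_met_clref
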