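"""HDF5 and NIfTI persistence for basis sets, scenes and MRSI grids."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .spin_sim import AcquisitionParams, BasisSet, SimulatedSpectrum
from .synthetic_data import GroundTruthScene, MRSIGrid

__all__ = [
    "save_basis", "load_basis",
    "save_grid", "load_grid",
    "save_scene", "load_scene",
    "save_nifti_map", "load_nifti_map",
    "export_basis_text",
]

_ACQ_ATTRS = ("larmor_freq", "spectral_width", "n_points", "ref_ppm")


def _write_acq(group: h5py.Group, acq: AcquisitionParams) -> None:
    for a in _ACQ_ATTRS:
        group.attrs[a] = getattr(acq, a)


def _read_acq(group: h5py.Group) -> AcquisitionParams:
    return AcquisitionParams(
        larmor_freq=float(group.attrs["larmor_freq"]),
        spectral_width=float(group.attrs["spectral_width"]),
        n_points=int(group.attrs["n_points"]),
        ref_ppm=float(group.attrs["ref_ppm"]),
    )


def save_basis(basis: BasisSet, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group(f"basis/{basis.te:g}")
        _write_acq(g, basis.acq)
        g.attrs["te"] = basis.te
        g.attrs["normalization"] = basis.normalization
        for met, spec in basis.entries.items():
            gm = g.create_group(met)
            gm.create_dataset("fid_re", data=spec.fid.real)
            gm.create_dataset("fid_im", data=spec.fid.imag)
            gm.attrs["n_protons"] = spec.n_protons


def load_basis(path) -> BasisSet:
    with h5py.File(path, "r") as f:
        root = f["basis"]
        te_key = next(iter(root))
        g = root[te_key]
        acq = _read_acq(g)
        te = float(g.attrs["te"])
        entries = {}
        for met in g:
            fid = g[met]["fid_re"][...] + 1j * g[met]["fid_im"][...]
            entries[met] = SimulatedSpectrum(
                fid=fid,
                spectrum=np.fft.fftshift(np.fft.fft(fid)),
                ppm_axis=acq.ppm_axis(),
                te=te,
                metabolite=met,
                n_protons=int(g[met].attrs["n_protons"]),
            )
        return BasisSet(te=te, entries=entries, acq=acq,
                        normalization=str(g.attrs["normalization"]))


def export_basis_text(basis: BasisSet, directory) -> None:
    """Per-metabolite plain-text spectra (ppm, real, imag) for inspection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ax = basis.ppm_axis
    for met, spec in basis.entries.items():
        arr = np.column_stack([ax, spec.spectrum.real, spec.spectrum.imag])
        header = (f"metabolite {met}  TE {basis.te} ms  protons {spec.n_protons}\n"
                  "ppm\treal\timag")
        np.savetxt(directory / f"{met}_te{basis.te:g}.tsv", arr,
                   delimiter="\t", header=header)


def save_scene(scene: GroundTruthScene, path_or_group) -> None:
    own = not isinstance(path_or_group, h5py.Group)
    f = h5py.File(path_or_group, "w") if own else path_or_group
    try:
        g = f.create_group("scene")
        g.attrs["grid_dims"] = scene.grid_dims
        g.attrs["voxel_size_mm"] = scene.voxel_size_mm
        g.create_dataset("labels", data=scene.labels)
        g.create_dataset("fractions", data=scene.tissue_fractions)
        g.create_dataset("voi_mask", data=scene.voi_mask)
        gc = g.create_group("conc")
        for m, c in scene.conc_maps.items():
            gc.create_dataset(m, data=c)
    finally:
        if own:
            f.close()


def load_scene(path_or_group) -> GroundTruthScene:
    own = not isinstance(path_or_group, h5py.Group)
    f = h5py.File(path_or_group, "r") if own else path_or_group
    try:
        g = f["scene"]
        return GroundTruthScene(
            grid_dims=tuple(int(x) for x in g.attrs["grid_dims"]),
            voxel_size_mm=tuple(float(x) for x in g.attrs["voxel_size_mm"]),
            labels=g["labels"][...],
            tissue_fractions=g["fractions"][...],
            conc_maps={m: g["conc"][m][...] for m in g["conc"]},
            voi_mask=g["voi_mask"][...].astype(bool),
        )
    finally:
        if own:
            f.close()


def save_grid(grid: MRSIGrid, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        _write_acq(g, grid.acq)
        g.attrs["te"] = grid.te
        g.attrs["noise_sd"] = grid.noise_sd
        g.attrs["seed"] = grid.seed
        g.create_dataset("spectra_re", data=grid.spectra.real)
        g.create_dataset("spectra_im", data=grid.spectra.imag)
        if grid.water_spectra is not None:
            g.create_dataset("water_re", data=grid.water_spectra.real)
            g.create_dataset("water_im", data=grid.water_spectra.imag)
            g.attrs["water_matrix"] = grid.water_matrix
        if grid.scene is not None:
            save_scene(grid.scene, f)


def load_grid(path) -> MRSIGrid:
    with h5py.File(path, "r") as f:
        g = f["grid"]
        water = None
        wm = None
        if "water_re" in g:
            water = g["water_re"][...] + 1j * g["water_im"][...]
            wm = tuple(int(x) for x in g.attrs["water_matrix"])
        scene = load_scene(f) if "scene" in f else None
        return MRSIGrid(
            spectra=g["spectra_re"][...] + 1j * g["spectra_im"][...],
            acq=_read_acq(g),
            te=float(g.attrs["te"]),
            noise_sd=float(g.attrs["noise_sd"]),
            seed=int(g.attrs["seed"]),
            water_spectra=water,
            water_matrix=wm,
            scene=scene,
        )


def save_nifti_map(map2d: np.ndarray, path, voxel_size_mm=(6.0, 6.0, 12.0)) -> None:
    """Write a per-voxel map as a single-slice NIfTI volume (mM, float32)."""
    import nibabel as nib

    data = np.asarray(map2d, dtype=np.float32)[:, :, None]
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti_map(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj).squeeze()
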