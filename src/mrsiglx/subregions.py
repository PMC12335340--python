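"""Tumor-subregion voxel assignment on the MRSI grid.

High-resolution segmentation labels (already registered to the MRSI space)
are reduced to per-voxel subregion fractions by exact cell counting. Voxels
at the edge of the VOI are excluded (imperfect slice profiles), voxels with
more than 50% of one subregion are assigned to it, and per subregion the
three voxels with the highest fraction enter the analysis -- extended
through exact ties with the third-ranked fraction, or reduced when fewer
candidates exist. A subregion with no candidate voxel is excluded from the
statistics for that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import binary_erosion

from .synthetic_data import SUBREGION_CLASSES

__all__ = [
    "SubregionSelection",
    "voxel_subregion_fractions",
    "exclude_voi_edge",
    "assign_subregion_voxels",
    "subregion_levels",
]


@dataclass
class SubregionSelection:
    """Selected voxels per subregion with their fractions."""

    selected: dict[str, list[tuple[tuple[int, int], float]]]
    excluded_subregions: dict[str, str]
    edge_mask: np.ndarray | None = None

    def voxels(self, subregion: str) -> list[tuple[int, int]]:
        return [v for v, _ in self.selected.get(subregion, [])]


def voxel_subregion_fractions(
    labels: np.ndarray,
    grid_dims: tuple[int, int],
    n_classes: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel class fractions from a high-resolution label image.

    ``labels`` must be an integer image whose dimensions are integer
    multiples of ``grid_dims`` (registration is upstream). Returns
    ``(fractions, counts)`` of shape (gy, gx, n_classes); fractions are
    exact ratios of the integer cell counts and sum to 1 per voxel.
    """
    labels = np.asarray(labels)
    gy, gx = grid_dims
    ny, nx = labels.shape
    if ny % gy or nx % gx:
        raise ValueError("label image dimensions must be integer multiples "
                         "of the MRSI grid")
    n_classes = n_classes or int(labels.max()) + 1
    by, bx = ny // gy, nx // gx
    blocks = labels.reshape(gy, by, gx, bx).transpose(0, 2, 1, 3).reshape(gy, gx, by * bx)
    counts = np.stack(
        [(blocks == c).sum(axis=-1) for c in range(n_classes)], axis=-1
    )
    return counts / (by * bx), counts


def exclude_voi_edge(voi_mask: np.ndarray) -> np.ndarray:
    """Interior of the VOI: drop voxels 8-adjacent to the mask boundary.

    A 12x12 VOI keeps 10x10 = 100 voxels. VOIs smaller than 3x3 yield an
    empty interior (with a warning).
    """
    voi_mask = np.asarray(voi_mask, dtype=bool)
    interior = binary_erosion(voi_mask, structure=np.ones((3, 3), dtype=bool))
    if voi_mask.any() and not interior.any():
        import warnings

        warnings.warn("VOI too small: edge exclusion leaves no interior voxels")
    return interior


def assign_subregion_voxels(
    fractions: np.ndarray,
    qc_mask: np.ndarray,
    counts: np.ndarray | None = None,
    classes: Sequence[str] = SUBREGION_CLASSES,
    min_fraction: float = 0.5,
    top_n: int = 3,
) -> SubregionSelection:
    """Select analysis voxels per subregion.

    Candidates are QC-accepted voxels with fraction strictly above
    ``min_fraction``; the ``top_n`` largest fractions are selected, extended
    through ties with the ``top_n``-th fraction (ties compared on the exact
    integer cell counts when provided, avoiding float ambiguity). Fewer than
    ``top_n`` candidates are used as-is; none marks the subregion excluded.
    """
    fractions = np.asarray(fractions, dtype=float)
    qc_mask = np.asarray(qc_mask, dtype=bool)
    if fractions.shape[:2] != qc_mask.shape:
        raise ValueError("fractions and QC mask shapes differ")
    key = counts if counts is not None else fractions
    selected: dict[str, list[tuple[tuple[int, int], float]]] = {}
    excluded: dict[str, str] = {}
    for c, name in enumerate(classes):
        cand = [
            ((i, j), fractions[i, j, c], key[i, j, c])
            for i in range(fractions.shape[0])
            for j in range(fractions.shape[1])
            if qc_mask[i, j] and fractions[i, j, c] > min_fraction
        ]
        if not cand:
            excluded[name] = f"no voxel with fraction > {min_fraction:g}"
            continue
        cand.sort(key=lambda t: (-t[2], t[0]))
        if len(cand) > top_n:
            cutoff = cand[top_n - 1][2]
            cand = [t for t in cand if t[2] >= cutoff]
        selected[name] = [(v, f) for v, f, _ in cand]
    return SubregionSelection(selected=selected, excluded_subregions=excluded)


def subregion_levels(
    selection: SubregionSelection,
    conc_maps: Mapping[str, np.ndarray],
) -> dict[str, dict[str, dict[str, float]]]:
    """Per-subregion, per-metabolite summary (mean, SD, n) over the selected
    voxels of one case. Empty selections are omitted (with the reason kept
    on the selection object)."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for name, pairs in selection.selected.items():
        vox = [v for v, _ in pairs]
        per_met: dict[str, dict[str, float]] = {}
        for met, cmap in conc_maps.items():
            vals = np.array([cmap[v] for v in vox], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            per_met[met] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        out[name] = per_met
    return out
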