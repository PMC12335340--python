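"""Reproducibility and group statistics, plus pipeline orchestration.

Scan-rescan agreement is summarized by Bland-Altman bias and ±1.96 SD
limits of agreement on voxelwise metabolite ratios. Subregion comparisons
follow a normality gate: Shapiro-Wilk per group; if every group is
compatible with normality (alpha 0.05) a one-way ANOVA with Tukey HSD
post hoc is used, otherwise Kruskal-Wallis followed by Dunn's test with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BlandAltmanResult",
    "GroupComparison",
    "bland_altman",
    "compare_subregions",
    "dunn_test",
    "scan_rescan_table",
    "significance_marker",
    "run_pipeline",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    normality_p: dict[str, float]
    test_used: str                     # "parametric" | "nonparametric" | "degenerate"
    omnibus_p: float
    pairwise: list[tuple[tuple[str, str], float, str]]
    dropped: dict[str, str] = field(default_factory=dict)


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bland-Altman analysis of paired session values (session1 - session2)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (session1, session2) pairs")
    d = arr[:, 0] - arr[:, 1]
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("fewer than two finite paired differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        sd_diff=sd, n=int(d.size),
    )


def dunn_test(groups: Mapping[str, np.ndarray]) -> list[tuple[tuple[str, str], float]]:
    """Dunn's rank-sum post hoc z-tests (two-sided, tie-corrected),
    unadjusted p-values per pair."""
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(data)
    n = all_vals.size
    ranks = sps.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1))
    splits = np.cumsum([d.size for d in data])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = {g: r.mean() for g, r in zip(names, group_ranks)}
    sizes = {g: d.size for g, d in zip(names, data)}
    out = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        if se == 0:
            out.append(((a, b), 1.0))
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out.append(((a, b), float(2 * sps.norm.sf(abs(z)))))
    return out


def compare_subregions(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> GroupComparison:
    """Compare case-level metabolite levels across subregions.

    Shapiro-Wilk per group gates the branch: ANOVA + Tukey HSD when all
    groups pass, Kruskal-Wallis + Dunn (Benjamini-Hochberg) otherwise.
    Groups with fewer than ``min_group_size`` values are dropped with a
    reason; degenerate (zero-variance) data is flagged, not crashed on.
    """
    groups: dict[str, np.ndarray] = {}
    dropped: dict[str, str] = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < min_group_size:
            dropped[name] = f"only {arr.size} values (need {min_group_size})"
        else:
            groups[name] = arr
    if len(groups) < 2:
        raise ValueError("need at least two groups with enough values")

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0 or all(np.ptp(g) == 0 for g in groups.values()):
        return GroupComparison(groups, {g: float("nan") for g in groups},
                               "degenerate", float("nan"), [], dropped)

    normality_p: dict[str, float] = {}
    for name, arr in groups.items():
        if np.ptp(arr) == 0:
            normality_p[name] = 0.0  # constant group: not normal
        else:
            normality_p[name] = float(sps.shapiro(arr).pvalue)
    parametric = all(p > alpha for p in normality_p.values())

    names = list(groups)
    if parametric:
        omnibus = float(sps.f_oneway(*groups.values()).pvalue)
        values = np.concatenate([groups[g] for g in names])
        labels = np.concatenate([[g] * groups[g].size for g in names])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairs = list(itertools.combinations([str(g) for g in tk.groupsunique], 2))
        pairwise = [((a, b), float(p), "tukey_hsd") for (a, b), p in zip(pairs, tk.pvalues)]
        branch = "parametric"
    else:
        omnibus = float(sps.kruskal(*groups.values()).pvalue)
        raw = dunn_test(groups)
        rej, adj, *_ = multipletests([p for _, p in raw], method="fdr_bh")
        pairwise = [(pair, float(p), "dunn_bh") for (pair, _), p in zip(raw, adj)]
        branch = "nonparametric"
    return GroupComparison(groups, normality_p, branch, omnibus, pairwise, dropped)


def significance_marker(p: float) -> str:
    """Figure convention: *p<0.05, **p<0.01, ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def scan_rescan_table(
    sessions: Mapping[str, Mapping[tuple[int, int], "FitResult"]],
    metabolites: Sequence[str] = ("Glu", "Gln", "tNAA", "tCr", "tCho", "mI"),
) -> pd.DataFrame:
    """Per-session mean ± SD of FWHM, SNR and metabolite CRLBs over the
    supplied (QC-accepted, interior) fits."""
    from .lcm_fit import COMPOSITE_SUMS, combined_crlb_percent

    rows = []
    for session, fits in sessions.items():
        if not fits:
            import warnings

            warnings.warn(f"session {session}: no accepted fits")
            continue
        rec: dict[str, float] = {"session": session, "n_voxels": len(fits)}
        fw = [f.fwhm_ppm for f in fits.values()]
        sn = [f.snr for f in fits.values()]
        rec["fwhm_ppm_mean"], rec["fwhm_ppm_sd"] = np.mean(fw), np.std(fw, ddof=1)
        rec["snr_mean"], rec["snr_sd"] = np.mean(sn), np.std(sn, ddof=1)
        for met in metabolites:
            if met in COMPOSITE_SUMS:
                vals = [combined_crlb_percent(f, COMPOSITE_SUMS[met]) for f in fits.values()]
            else:
                vals = [f.crlb_pct.get(met, np.nan) for f in fits.values()]
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            rec[f"crlb_{met}_mean"] = vals.mean() if vals.size else np.nan
            rec[f"crlb_{met}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: Mapping | str, out_dir=None, seed: int | None = None) -> dict:
    """Run the full synthetic pipeline from a YAML config or config mapping:
    basis simulation -> scene/grid generation -> fitting -> QC -> water
    quantification -> subregion assignment -> statistics. Writes CSV/JSON
    artifacts when ``out_dir`` is given and returns the result bundle."""
    from pathlib import Path

    from .config import load_config
    from .lcm_fit import FitConfig, cmc, fisher_information, fit_grid, quality_filter
    from .quantify import (
        WaterContentTable, quantify_internal_water, water_concentration_map,
        water_signal_from_spectrum,
    )
    from .spin_sim import AcquisitionParams, DEFAULT_BASIS_METABOLITES, make_basis_set
    from .subregions import (
        assign_subregion_voxels, exclude_voi_edge, subregion_levels,
        voxel_subregion_fractions,
    )
    from .synthetic_data import (
        NoiseModel, SUBREGION_CLASSES, SceneGeometry, generate_mrsi_grid,
        make_tumor_scene,
    )

    cfg = load_config(config)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    acq = AcquisitionParams(**cfg.get("acquisition", {}))
    te = float(cfg.get("te", 120.0))
    mets = tuple(cfg.get("metabolites") or DEFAULT_BASIS_METABOLITES)
    basis = make_basis_set(mets, te, acq)

    geom = SceneGeometry(**cfg.get("scene", {}))
    scene = make_tumor_scene(geom, seed=seed)
    noise = NoiseModel(**cfg.get("noise", {}))
    grid = generate_mrsi_grid(scene, basis, noise, seed=seed + 1,
                              target_snr=cfg.get("target_snr", 27.0))

    fit_cfg = FitConfig(**cfg.get("fit", {}))
    interior = exclude_voi_edge(scene.voi_mask)
    fits = fit_grid(grid, basis, fit_cfg, mask=interior)
    accepted, reasons = quality_filter(fits, fit_cfg)

    # water-referenced concentrations for the fitted voxels
    cw = water_concentration_map(scene.tissue_fractions, WaterContentTable())
    conc_maps = {m: np.full(scene.grid_dims, np.nan) for m in basis.entries}
    protons = basis.proton_counts()
    for (i, j), f in accepted.items():
        sw = water_signal_from_spectrum(grid.water_spectra[i, j], grid.ppm_axis)
        for m in basis.entries:
            conc_maps[m][i, j] = quantify_internal_water(
                f.concentrations[m] * protons[m], sw, protons[m], cw[i, j])
    cmc_map = np.full(scene.grid_dims, np.nan)
    for (i, j), f in fits.items():
        cmc_map[i, j] = cmc(fisher_information(f), list(f.metabolites), "Glu", "Gln")

    # subregion assignment from the scene's own labels (1x1 cells per voxel)
    fractions, counts = voxel_subregion_fractions(scene.labels, scene.grid_dims)
    qc_ok = np.zeros(scene.grid_dims, dtype=bool)
    for v in accepted:
        qc_ok[v] = True
    selection = assign_subregion_voxels(fractions, qc_ok & interior, counts)
    levels = subregion_levels(selection, {"Glu": conc_maps["Glu"], "Gln": conc_maps["Gln"]})

    bundle = {
        "seed": seed,
        "te": te,
        "n_fitted": len(fits),
        "n_accepted": len(accepted),
        "rejection_reasons": {f"{i},{j}": list(r) for (i, j), r in reasons.items() if r},
        "mean_cmc_glu_gln": float(np.nanmean(cmc_map)),
        "subregion_levels": levels,
        "conc_maps": conc_maps,
        "cmc_map": cmc_map,
        "selection": selection,
        "fits": fits,
        "grid": grid,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for (i, j), f in fits.items():
            for m, a in f.concentrations.items():
                rows.append({"voxel_i": i, "voxel_j": j, "metabolite": m,
                             "amplitude": a, "crlb_pct": f.crlb_pct.get(m),
                             "accepted": f.accepted,
                             "conc_mM": conc_maps[m][i, j] if m in conc_maps else np.nan})
        pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)
        summary = {k: bundle[k] for k in
                   ("seed", "te", "n_fitted", "n_accepted", "mean_cmc_glu_gln",
                    "subregion_levels", "rejection_reasons")}
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        try:
            from .io import save_nifti_map

            save_nifti_map(conc_maps["Glu"], out / "glu_mM.nii.gz")
            save_nifti_map(conc_maps["Gln"], out / "gln_mM.nii.gz")
            save_nifti_map(cmc_map, out / "cmc_glu_gln.nii.gz")
        except Exception:
            pass
    return bundle
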