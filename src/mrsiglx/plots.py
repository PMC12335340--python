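"""Figure helpers: spectra, metabolite maps, CMC distributions and
Bland-Altman plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .stats_report import BlandAltmanResult

__all__ = ["plot_spectrum_fit", "plot_map", "plot_cmc_box", "plot_bland_altman"]


def plot_spectrum_fit(fit, path=None, flip_axis=True):
    """Data window, fitted model and residual of one voxel fit."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = fit.window_ppm
    data = fit.model + fit.residual
    ax.plot(x, data.real, "k", lw=0.8, label="data")
    ax.plot(x, fit.model.real, "r", lw=1.0, label="fit")
    offset = 1.1 * np.abs(data.real).max()
    ax.plot(x, fit.residual.real + offset, "0.5", lw=0.6, label="residual")
    if flip_axis:
        ax.invert_xaxis()
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_yticks([])
    ax.legend(frameon=False)
    return _finish(fig, path)


def plot_map(map2d, title="", path=None, cmap="viridis", units="mM"):
    """Single metabolite or CMC map."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    im = ax.imshow(map2d, cmap=cmap, origin="upper")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label=units)
    return _finish(fig, path)


def plot_cmc_box(cmc_by_te: dict[float, np.ndarray], path=None):
    """Distribution of per-voxel CMC(Glu, Gln) per echo time."""
    fig, ax = plt.subplots(figsize=(4, 4))
    tes = sorted(cmc_by_te)
    data = [np.asarray(cmc_by_te[te]) for te in tes]
    ax.boxplot(data, tick_labels=[f"TE {te:g} ms" for te in tes])
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + 0.08 * rng.standard_normal(len(vals)), vals, ".",
                alpha=0.4, ms=3)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_ylabel("CMC(Glu, Gln)")
    return _finish(fig, path)


def plot_bland_altman(pairs, result: BlandAltmanResult, path=None, label=""):
    pairs = np.asarray(pairs, dtype=float)
    mean = pairs.mean(axis=1)
    diff = pairs[:, 0] - pairs[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(mean, diff, "o", ms=3, alpha=0.6)
    for y, style in ((result.bias, "-"), (result.loa_low, "--"),
                     (result.loa_high, "--")):
        ax.axhline(y, color="r", ls=style, lw=0.9)
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel("session difference")
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
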