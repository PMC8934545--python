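"""Rendering: probability-map overlays and G_cpRNFL histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .normative import ProbabilityMap

# green / yellow / red in the convention of commercial deviation maps
_CATEGORY_RGB = {
    0: (0.55, 0.85, 0.55),
    1: (1.00, 0.95, 0.30),
    2: (0.90, 0.15, 0.15),
}


def render_pmap(pmap: ProbabilityMap, path: str | Path | None = None):
    """Render a probability map with disc circle and vertical midline overlay."""
    rgb = np.zeros(pmap.shape + (3,))
    for code, color in _CATEGORY_RGB.items():
        rgb[pmap.category == code] = color
    h_mm, w_mm = pmap.extent_mm
    fig, ax = plt.subplots(figsize=(7, 7 * h_mm / w_mm))
    ax.imshow(rgb, extent=(0, w_mm, h_mm, 0))
    disc = pmap.disc_mm
    fovea = pmap.fovea_mm
    circle = plt.Circle(disc, pmap.anatomy.disc_radius, fill=False, color="k", lw=1.5)
    ax.add_patch(circle)
    ax.axvline(fovea[0], color="k", lw=1.2)
    ax.plot(*fovea, "k+", ms=10)
    ax.set_xlabel("mm (temporal → nasal field)")
    ax.set_ylabel("mm")
    ax.set_title(f"{pmap.layer} probability map (field view, OD frame)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return Path(path)
    return fig


def gcprnfl_histograms(g_by_group: dict, cutoff: float, path: str | Path | None = None):
    """Per-group histograms of G_cpRNFL with the reference 5th-percentile line."""
    groups = [g for g in ("HC_norm", "HC", "EG_VF", "MG", "AG") if g in g_by_group]
    fig, axes = plt.subplots(len(groups), 1, figsize=(6, 2.2 * len(groups)), sharex=True)
    if len(groups) == 1:
        axes = [axes]
    for ax, g in zip(axes, groups):
        vals = np.asarray(g_by_group[g])
        ax.hist(vals, bins=24, color="0.6", edgecolor="k")
        ax.axvline(cutoff, color="r", lw=1.5, label="reference 5th percentile")
        ax.axvline(vals.mean(), color="k", ls="--", lw=1.2, label="group mean")
        ax.set_ylabel(g)
    axes[0].legend(loc="upper right", fontsize=8)
    axes[-1].set_xlabel("G_cpRNFL (µm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig
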