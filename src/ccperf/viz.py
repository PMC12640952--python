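"""Polar-map rendering."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .mapping import PolarMap, segment_bin_map


def render_polar_png(polar: PolarMap, threshold: float, out_path,
                     title: str = "Stress MBF polar map",
                     vmax: float = 400.0) -> Path:
    """Bullseye PNG: segment boundaries, MBF colorbar in mL/min/100 g with a
    green dashed line at the abnormal-flow threshold; NaN bins neutral gray.
    Output bytes are deterministic for a fixed input and style."""
    out_path = Path(out_path)
    nr, na = polar.n_radius, polar.n_angle
    theta = np.linspace(0, 2 * np.pi, na + 1)
    r = np.linspace(0, 1, nr + 1)
    cmap = plt.get_cmap("turbo").copy()
    cmap.set_bad("0.6")

    fig = plt.figure(figsize=(5, 4.2), dpi=120)
    ax = fig.add_subplot(111, projection="polar")
    mesh = ax.pcolormesh(theta, r, np.ma.masked_invalid(polar.raster),
                         cmap=cmap, vmin=0.0, vmax=vmax, shading="flat")
    # ring boundaries (apical/mid/basal) and segment spokes
    for rr in (1 / 3, 2 / 3, 1.0):
        ax.plot(np.linspace(0, 2 * np.pi, 181), np.full(181, rr),
                color="k", lw=0.6)
    for a in range(0, 360, 60):
        ax.plot([np.radians(a)] * 2, [1 / 3, 1.0], color="k", lw=0.6)
    for a in range(15, 360, 90):
        ax.plot([np.radians(a)] * 2, [0.0, 1 / 3], color="k", lw=0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title, fontsize=10)
    cbar = fig.colorbar(mesh, ax=ax, pad=0.08)
    cbar.set_label("MBF (mL·min$^{-1}$·(100 g)$^{-1}$)", fontsize=8)
    if 0.0 < threshold < vmax:
        cbar.ax.axhline(threshold, color="green", linestyle="--", lw=1.5)
    fig.savefig(out_path, format="png")
    plt.close(fig)
    return out_path
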