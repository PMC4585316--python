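"""Figure rendering: architecture, activation and upstroke maps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["render_strand_maps", "render_sweep"]


def render_strand_maps(result, arch, path, isochrone_ms: float = 1.0):
    """Three-panel strand figure: cell types, activation map with 1-ms
    isochrones, and the dV/dt_max map."""
    geo = arch.geometry
    extent = [0, geo.length, 0, geo.width]
    fig, axes = plt.subplots(3, 1, figsize=(10, 4.5), constrained_layout=True)

    axes[0].imshow(
        arch.type_index_grid(), origin="lower", extent=extent, aspect="auto",
        cmap=matplotlib.colors.ListedColormap(["#c44", "#fd5", "#7c4"]),
        vmin=0, vmax=2, interpolation="nearest",
    )
    axes[0].set_title("cell types (red PCM, yellow LE-SCM, green HE-SCM)")

    eat = result.eat
    im = axes[1].imshow(eat, origin="lower", extent=extent, aspect="auto",
                        cmap="viridis")
    if np.isfinite(eat).any():
        tmax = np.nanmax(eat)
        levels = np.arange(0, tmax + isochrone_ms, isochrone_ms)
        if len(levels) > 1:
            axes[1].contour(
                np.nan_to_num(eat, nan=tmax + 10), levels=levels,
                colors="w", linewidths=0.5, extent=extent, origin="lower",
            )
    axes[1].set_title("activation map (isochrones every 1 ms)")
    fig.colorbar(im, ax=axes[1], label="EAT (ms)")

    dv = np.where(result.activated, result.dvdtmax, np.nan)
    im2 = axes[2].imshow(dv, origin="lower", extent=extent, aspect="auto",
                         cmap="magma")
    axes[2].set_title("dV/dt_max map")
    axes[2].set_xlabel("x (um)")
    fig.colorbar(im2, ax=axes[2], label="dV/dt_max (V/s)")
    fig.savefig(path, dpi=130)
    plt.close(fig)


def render_sweep(results: dict, path):
    """CV vs p_SCM for the sweep columns, with quadratic fits."""
    fig, ax = plt.subplots(figsize=(6, 4.5), constrained_layout=True)
    colors = {"HE": "C0", "LE": "C1", "mixed": "C2", "enhanced": "C3"}
    pp = np.linspace(0, 1, 101)
    for key, res in results.items():
        agg = res.aggregates()
        c = colors.get(key, "k")
        ax.errorbar(agg.p_scm, agg["mean"], yerr=agg["std"], fmt="o",
                    color=c, label=key, ms=4, capsize=2)
        q = res.quadratic
        ax.plot(pp, q.a2 * pp**2 + q.a1 * pp + q.a0, "-", color=c, lw=1)
    ax.set_xlabel("proportion of SCMs")
    ax.set_ylabel("CV (cm/s)")
    ax.legend()
    fig.savefig(path, dpi=130)
    plt.close(fig)
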