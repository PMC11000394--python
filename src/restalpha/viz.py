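"""Topographic scalp maps, per-subject spectrum plots, IAF strata plots.

Maps use thin-plate-spline interpolation of per-electrode scalars over the
unit-disc scalp projection; the surface is node-exact at electrode
positions.  Regions under electrodes excluded from a map (e.g. electrodes
not tested) are left blank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import RBFInterpolator

from .errors import ParameterError
from .montage import Montage, standard_montage
from .spectral import Spectrum

__all__ = ["TopoMap", "median_topomap", "pvalue_topomap", "iaf_strata_plot",
           "spectrum_plot", "plot_topomap"]

_GRID_N = 128


@dataclass
class TopoMap:
    """Interpolated scalp surface for a per-electrode scalar."""

    values: Mapping[str, float]
    positions: Mapping[str, tuple[float, float]]
    grid: np.ndarray           # (N, N), NaN outside the mask
    mask: np.ndarray           # (N, N) bool, inside-head
    extent: tuple[float, float, float, float]
    interpolator: object = None

    def value_at(self, pos: tuple[float, float]) -> float:
        """Exact interpolant value at an arbitrary 2D position."""
        return float(self.interpolator(np.asarray(pos, float)[None, :])[0])


def _make_topomap(values: Mapping[str, float], montage: Montage) -> TopoMap:
    names = list(values)
    if len(names) < 3:
        raise ParameterError("need at least 3 electrodes with values")
    pts = np.array([montage.lookup(n).pos2d for n in names], dtype=float)
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ParameterError("electrode positions are collinear")
    vals = np.array([values[n] for n in names], dtype=float)

    interp = RBFInterpolator(pts, vals, kernel="thin_plate_spline", degree=1)
    lim = 1.02
    axis = np.linspace(-lim, lim, _GRID_N)
    gx, gy = np.meshgrid(axis, axis)
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    surface = interp(flat).reshape(_GRID_N, _GRID_N)
    mask = gx ** 2 + gy ** 2 <= lim ** 2
    surface = np.where(mask, surface, np.nan)
    return TopoMap(values=dict(values),
                   positions={n: montage.lookup(n).pos2d for n in names},
                   grid=surface, mask=mask, extent=(-lim, lim, -lim, lim),
                   interpolator=interp)


def median_topomap(metric_table, group: str,
                   montage: Optional[Montage] = None,
                   electrodes: Optional[Sequence[str]] = None,
                   value_prefix: str = "alpha_psd_") -> TopoMap:
    """Per-electrode group medians interpolated over the scalp."""
    montage = montage if montage is not None else standard_montage()
    sub = metric_table[metric_table["group"] == group]
    if sub.empty:
        raise ParameterError(f"no rows for group {group!r}")
    if electrodes is None:
        electrodes = [c[len(value_prefix):] for c in metric_table.columns
                      if c.startswith(value_prefix)]
    values = {e: float(np.median(sub[f"{value_prefix}{e}"]))
              for e in electrodes}
    return _make_topomap(values, montage)


def pvalue_topomap(comparison, montage: Optional[Montage] = None) -> TopoMap:
    """Map of uncorrected post-hoc p-values over the tested electrodes only."""
    montage = montage if montage is not None else standard_montage()
    values = {e: float(comparison.table.loc[e, "p_raw"])
              for e in comparison.electrode_order}
    return _make_topomap(values, montage)


def plot_topomap(tm: TopoMap, ax=None, cmap: str = "viridis",
                 vmin: Optional[float] = None, vmax: Optional[float] = None,
                 title: str = "", montage: Optional[Montage] = None):
    """Render a TopoMap; electrodes without values are drawn as open circles."""
    montage = montage if montage is not None else standard_montage()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if vmin is None:
        vmin = float(np.nanpercentile(tm.grid, 2))
    if vmax is None:
        vmax = float(np.nanpercentile(tm.grid, 98))
    im = ax.imshow(tm.grid, origin="lower", extent=tm.extent, cmap=cmap,
                   vmin=vmin, vmax=vmax)
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1.5)
    ax.add_patch(circle)
    for e in montage:
        if e.name in tm.values:
            ax.plot(e.x, e.y, "k.", ms=4)
        else:
            ax.plot(e.x, e.y, "o", mfc="white", mec="grey", ms=5)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, shrink=0.75)
    return ax


def iaf_strata_plot(metric_table, electrode: str = "O1", path=None):
    """Two-panel IAF distribution plot, stratified by comorbid migraine."""
    col = f"iaf_{electrode}"
    if col not in metric_table.columns or "migraine" not in metric_table.columns:
        raise ParameterError("metric table needs iaf and migraine columns")
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, mig, label in zip(axes, (True, False),
                              ("migraine", "no migraine")):
        sub = metric_table[metric_table["migraine"] == mig]
        if sub.empty:
            ax.text(0.5, 0.5, "empty stratum", ha="center", va="center",
                    transform=ax.transAxes)
            ax.set_title(label)
            continue
        for i, group in enumerate(sorted(sub["group"].unique())):
            v = sub[sub["group"] == group][col].to_numpy(dtype=float)
            jitter = np.linspace(-0.12, 0.12, len(v)) if len(v) > 1 else [0.0]
            ax.plot(i + np.asarray(jitter), v, "o", alpha=0.7, label=group)
            if len(v):
                ax.hlines(np.median(v), i - 0.2, i + 0.2, color="k", lw=2)
        ax.set_xticks(range(len(sub["group"].unique())))
        ax.set_xticklabels(sorted(sub["group"].unique()))
        ax.set_title(label)
    axes[0].set_ylabel(f"IAF at {electrode} [Hz]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def spectrum_plot(spectrum: Spectrum, channel: str, iaf: float,
                  path=None, fmax: float = 30.0):
    """Single-channel PSD with the IAF ± 1 Hz window shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    sel = spectrum.freqs <= fmax
    ax.plot(spectrum.freqs[sel], spectrum.channel_psd(channel)[sel], lw=1.2)
    ax.axvspan(iaf - 1.0, iaf + 1.0, color="orange", alpha=0.3,
               label="IAF ± 1 Hz")
    ax.axvline(iaf, color="orange", lw=1)
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("PSD [µV²/Hz]")
    ax.set_title(channel)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
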