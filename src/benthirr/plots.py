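"""Plot helpers: station boxplots with significance letters and raster maps."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .raster import Raster
from .temporal import station_boxstats


def plot_station_boxes(
    values: Sequence[float],
    stations: Sequence[str],
    letters: Mapping[str, str] | None = None,
    order: Sequence[str] | None = None,
    ax=None,
    ylabel: str = "BIPc",
):
    """Boxplots of index values per station, annotated with Tukey letters.

    Stations appear in ``order`` (e.g. sorted by system then salinity) or in
    first-occurrence order.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    stats_df = station_boxstats(values, stations, order=order)
    names = list(stats_df["station"])
    values = np.asarray(values, dtype=float)
    grouped = [
        values[[i for i, s in enumerate(stations) if s == name]] for name in names
    ]
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(grouped, tick_labels=names)
    ax.set_ylabel(ylabel)
    if letters:
        top = max(v.max() for v in grouped)
        pad = 0.05 * (top - min(v.min() for v in grouped) or 1.0)
        for k, name in enumerate(names, start=1):
            ax.text(k, top + pad, letters.get(name, ""), ha="center")
    return ax


def plot_raster(raster: Raster, ax=None, cmap: str = "viridis", label: str = ""):
    """Image plot of a raster in its geographic frame (masked cells blank)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    nrow, ncol = raster.shape
    extent = (
        raster.x0 - raster.dx / 2,
        raster.x0 + (ncol - 0.5) * raster.dx,
        raster.y0 - (nrow - 0.5) * raster.dy,
        raster.y0 + raster.dy / 2,
    )
    im = ax.imshow(raster.data, extent=extent, origin="upper", cmap=cmap)
    if label:
        ax.figure.colorbar(im, ax=ax, label=label)
    return ax
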