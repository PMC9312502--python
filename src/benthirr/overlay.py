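"""Bivariate hotspot overlay of two index rasters.

Compares where two indices (e.g. bioirrigation vs bioturbation potential)
are *relatively* high.  Each raster is reduced to within-raster quantile
ranks, which makes the comparison invariant to any monotone rescaling
(log vs linear scale is irrelevant).  Cells are classed as:

- ``bipc_higher``  rank(A) − rank(B) >  delta_quantile
- ``bpc_higher``   rank(A) − rank(B) < −delta_quantile
- ``both_hot``     both ranks ≥ hot_quantile and |difference| ≤ delta_quantile
- ``neither``      everything else

The quantile thresholds are an explicit operationalisation of "relative
hotspot" — there is no canonical definition — and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster

CLASS_CODES = {"neither": 0, "bipc_higher": 1, "bpc_higher": 2, "both_hot": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class OverlayRaster:
    """Classified overlay grid (codes per :data:`CLASS_CODES`)."""

    classes: Raster
    hot_quantile: float
    delta_quantile: float

    def counts(self) -> dict[str, int]:
        out = {}
        data = self.classes.data
        for name, code in CLASS_CODES.items():
            out[name] = int(np.ma.sum(data == code))
        return out

    def legend(self) -> str:
        lines = [f"{code} = {name}" for name, code in CLASS_CODES.items()]
        lines.append(f"hot_quantile = {self.hot_quantile}")
        lines.append(f"delta_quantile = {self.delta_quantile}")
        return "\n".join(lines)


def _quantile_ranks(values: np.ndarray) -> np.ndarray:
    """Midrank-based quantile ranks in (0, 1] over the valid cells."""
    from scipy.stats import rankdata

    return rankdata(values) / values.size


def overlay(
    raster_a: Raster,
    raster_b: Raster,
    hot_quantile: float = 0.75,
    delta_quantile: float = 0.10,
) -> OverlayRaster:
    """Classify co-registered rasters into relative-hotspot classes.

    Cells masked in either input stay masked; unmasked cells always receive
    exactly one class.
    """
    if not raster_a.same_grid(raster_b):
        raise ValueError("rasters are not co-registered")
    if not 0 < hot_quantile < 1:
        raise ValueError("hot_quantile must be in (0, 1)")
    if not 0 <= delta_quantile < 1:
        raise ValueError("delta_quantile must be in [0, 1)")

    mask = np.ma.getmaskarray(raster_a.data) | np.ma.getmaskarray(raster_b.data)
    valid = ~mask
    a = np.asarray(raster_a.data.filled(0.0))[valid]
    b = np.asarray(raster_b.data.filled(0.0))[valid]
    ra = _quantile_ranks(a)
    rb = _quantile_ranks(b)
    diff = ra - rb

    cls = np.full(ra.shape, CLASS_CODES["neither"], dtype=float)
    cls[diff > delta_quantile] = CLASS_CODES["bipc_higher"]
    cls[diff < -delta_quantile] = CLASS_CODES["bpc_higher"]
    both = (ra >= hot_quantile) & (rb >= hot_quantile) & (np.abs(diff) <= delta_quantile)
    cls[both] = CLASS_CODES["both_hot"]

    grid = np.full(raster_a.shape, np.nan)
    grid[valid] = cls
    out = Raster(
        data=np.ma.masked_invalid(grid),
        x0=raster_a.x0, y0=raster_a.y0, dx=raster_a.dx, dy=raster_a.dy,
    )
    return OverlayRaster(
        classes=out, hot_quantile=hot_quantile, delta_quantile=delta_quantile
    )
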