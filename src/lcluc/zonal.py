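"""Zonal accounting of significant net changes (biome/region tables).

Overlays the trend raster with a zone map and accumulates, per zone and
class, the gains (sum of positive significant net areas), losses (sum of
negative significant net areas), their net, the combined one-standard-
deviation uncertainty assuming independent cells (root sum of squared cell
SDs), and the count of significant cells.  Gains and losses are accumulated
separately before netting, matching the dual-bar gain/loss presentation.

Zone maps are integer grids at big-grid (cell) resolution; pixel-resolution
maps are reduced by taking the zone of each cell's center pixel.  Zone code
0 (or ``nodata_zone``) marks cells outside any zone, which are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trend import TrendRaster

ZONE_TABLE_COLUMNS = (
    "zone", "class", "gain_km2", "loss_km2", "net_km2", "sd_km2", "n_cells_significant",
)


def reduce_zone_mask(pixel_zones: np.ndarray, block_size: int) -> np.ndarray:
    """Cell-level zone map: each cell takes the zone of its center pixel
    (offset block_size//2 within the block); trailing partial blocks drop."""
    pixel_zones = np.asarray(pixel_zones)
    rows, cols = pixel_zones.shape
    cr, cc = rows // block_size, cols // block_size
    off = block_size // 2
    return pixel_zones[off : cr * block_size : block_size, off : cc * block_size : block_size]


def zonal_net_change(
    trend: TrendRaster,
    zones: np.ndarray,
    zone_names: dict[int, str] | None = None,
    zone_ids: Sequence[int] | None = None,
    nodata_zone: int = 0,
) -> pd.DataFrame:
    """Per-zone, per-class gain/loss/net table over significant cells.

    Parameters
    ----------
    trend
        Fitted trend raster.
    zones
        Integer zone codes, either at cell resolution (same shape as the
        trend grids) or at pixel resolution (reduced via the center-pixel
        rule).
    zone_names
        Optional code -> display-name mapping for the ``zone`` column.
    zone_ids
        Zones to report; defaults to the codes present in ``zones``.  Zones
        listed here but absent from the map produce all-zero rows.

    Returns
    -------
    pandas.DataFrame
        Columns ``zone, class, gain_km2, loss_km2, net_km2, sd_km2,
        n_cells_significant``.
    """
    zones = np.asarray(zones)
    cell_shape = trend.cell_shape
    if zones.shape != cell_shape:
        reduced = reduce_zone_mask(zones, trend.block_size)
        if reduced.shape != cell_shape:
            raise ValueError(
                f"zone map shape {zones.shape} matches neither the cell grid "
                f"{cell_shape} nor a pixel grid reducible to it"
            )
        zones = reduced
    if zone_ids is None:
        zone_ids = sorted(int(z) for z in np.unique(zones) if z != nodata_zone)

    rows = []
    for zid in zone_ids:
        in_zone = zones == zid
        zname = zone_names.get(zid, zid) if zone_names else zid
        for cname in trend.class_names:
            net = trend.net_area[cname]
            sd = trend.sd_area[cname]
            sel = in_zone & trend.significant[cname] & ~np.isnan(net)
            vals = net[sel]
            rows.append(
                {
                    "zone": zname,
                    "class": cname,
                    "gain_km2": float(vals[vals > 0].sum()),
                    "loss_km2": float(vals[vals < 0].sum()),
                    "net_km2": float(vals.sum()),
                    "sd_km2": float(np.sqrt((sd[sel] ** 2).sum())),
                    "n_cells_significant": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows, columns=list(ZONE_TABLE_COLUMNS))


@dataclass(frozen=True)
class PairedChange:
    """Association between two classes' significant changes within a zone."""

    class_a: str
    class_b: str
    net_a_km2: float
    net_b_km2: float
    correlation: float  # NaN when undefined (<2 joint cells or zero variance)
    n_cells: int


def conversion_association(
    trend: TrendRaster,
    class_a: str,
    class_b: str,
    zone_mask: np.ndarray | None = None,
) -> PairedChange:
    """Paired gain/loss summary for two classes (e.g. cropland gain vs
    grassland loss) within a zone.

    ``net_a``/``net_b`` are the zone sums of significance-masked net areas;
    the correlation is Pearson's r over cells significant for *both* classes.
    A class paired with itself yields correlation 1 over its significant
    cells (when at least two with nonzero variance exist).
    """
    for name in (class_a, class_b):
        if name not in trend.class_names:
            raise ValueError(f"class {name!r} not in trend raster")
    if zone_mask is None:
        zone_mask = np.ones(trend.cell_shape, dtype=bool)
    zone_mask = np.asarray(zone_mask, dtype=bool)
    if zone_mask.shape != trend.cell_shape:
        zone_mask = reduce_zone_mask(zone_mask, trend.block_size)

    net_a = trend.net_area[class_a]
    net_b = trend.net_area[class_b]
    sig_a = trend.significant[class_a] & ~np.isnan(net_a) & zone_mask
    sig_b = trend.significant[class_b] & ~np.isnan(net_b) & zone_mask

    both = sig_a & sig_b
    corr = np.nan
    if both.sum() >= 2:
        a, b = net_a[both], net_b[both]
        if a.std() > 0 and b.std() > 0:
            corr = float(np.corrcoef(a, b)[0, 1])
    return PairedChange(
        class_a=class_a,
        class_b=class_b,
        net_a_km2=float(net_a[sig_a].sum()),
        net_b_km2=float(net_b[sig_b].sum()),
        correlation=corr,
        n_cells=int(both.sum()),
    )
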