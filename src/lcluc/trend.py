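"""Per-cell linear trend estimation, significance masking, and net change.

For every big-grid cell and analysis class, the annual fraction series is
regressed on the year index t = 0..n-1 by ordinary least squares.  The
trend slope (fraction/year) carries a two-sided t test (n-2 df) of slope=0;
cells with p below the significance threshold (default 0.1) are hotspots.
Net change over the study span is

    net_fraction = slope x interval          (interval = 13 for a 13-year span)
    net_area     = net_fraction x cell_area  (km²)
    sd_area      = se(slope) x interval x cell_area

with sd_area the one-standard-deviation uncertainty of the net change
(SD_LCC).  Non-significant cells report zero net area in hotspot layers but
retain the raw fit.  The endpoint-difference baseline (last year minus first
year) is provided for comparison; it has no significance concept and is
sensitive to anomalous start or end years.

Note the span convention: a 13-year annual series covers 12 inter-year
intervals, yet net change uses the multiplier 13 (the printed span length).
The multiplier is exposed as ``interval`` rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import FractionCube
from .io import Georeference

# residual sums below RSS_REL x Syy count as perfect fits (p = 0); total
# variation below VAR_ABS counts as a constant series (slope 0, p undefined)
_RSS_REL = 1e-12
_VAR_ABS = 1e-24

#: Edge length (m) of a nominal 250 m pixel on the MODIS sinusoidal grid.
MODIS_PIXEL_EDGE_M = 231.656


def min_detectable_area_ha(pixel_edge_m: float = MODIS_PIXEL_EDGE_M) -> float:
    """Detection floor of the change analysis: one map pixel, in hectares,
    truncated to one decimal (changes below a single pixel cannot register
    in any fraction series)."""
    ha = pixel_edge_m**2 / 1e4
    return np.floor(ha * 10.0) / 10.0


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of one fraction series on the year index."""

    slope: float
    intercept: float
    se_slope: float
    p_value: float  # NaN when undefined (constant series)
    n_years: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.p_value)


@dataclass(frozen=True)
class NetChange:
    """Significance-masked net change for one cell/class."""

    net_fraction: float
    net_area: float
    sd_area: float
    significant: bool
    alpha: float
    interval: float

    @property
    def masked_net_area(self) -> float:
        """Net area as reported in hotspot layers: zero unless significant."""
        return self.net_area if self.significant else 0.0


def _ols_arrays(y: np.ndarray, n: int) -> tuple[np.ndarray, ...]:
    """Vectorized OLS of y (..., n) on t = 0..n-1; returns slope, intercept,
    se_slope, p_value with NaN propagation and degenerate-series handling."""
    t = np.arange(n, dtype=np.float64)
    t_bar = t.mean()
    sxx = float(((t - t_bar) ** 2).sum())

    y_bar = y.mean(axis=-1)
    dev = y - y_bar[..., None]
    sxy = (dev * (t - t_bar)).sum(axis=-1)
    syy = (dev * dev).sum(axis=-1)

    slope = sxy / sxx
    intercept = y_bar - slope * t_bar
    rss = np.maximum(syy - slope * sxy, 0.0)

    constant = syy <= _VAR_ABS
    perfect = ~constant & (rss <= _RSS_REL * syy)

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    slope = np.where(constant, 0.0, slope)
    se = np.where(constant, 0.0, se)
    p = np.where(perfect, 0.0, p)
    p = np.where(constant, np.nan, p)

    bad = ~np.isfinite(y).all(axis=-1)
    for arr in (slope, intercept, se, p):
        arr[bad] = np.nan
    return slope, intercept, se, p


def ols_trend(fractions: Sequence[float], years: Sequence[int]) -> TrendFit:
    """Simple linear regression of one fraction series on the year index.

    Regression runs on t = 0..n-1 (the slope is invariant to regressing on
    calendar years; only the intercept differs).  Zero-residual fits with
    nonzero slope get p = 0; constant series get slope 0 with an undefined
    (NaN) p-value and are treated as non-significant downstream.

    Raises
    ------
    ValueError
        For fewer than 3 points, non-finite input, or non-increasing years.
    """
    y = np.asarray(fractions, dtype=np.float64)
    years = tuple(years)
    if y.ndim != 1 or y.size != len(years):
        raise ValueError(f"{y.size} values for {len(years)} years")
    if y.size < 3:
        raise ValueError(f"need at least 3 points for a trend, got {y.size}")
    if not np.isfinite(y).all():
        raise ValueError("fraction series contains non-finite values")
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("years must be strictly increasing")
    slope, intercept, se, p = _ols_arrays(y[None, :], y.size)
    return TrendFit(
        slope=float(slope[0]),
        intercept=float(intercept[0]),
        se_slope=float(se[0]),
        p_value=float(p[0]),
        n_years=y.size,
    )


def net_change(
    fit: TrendFit,
    interval: float = 13.0,
    alpha: float = 0.1,
    cell_area: float = 6.25,
) -> NetChange:
    """Net change and its one-standard-deviation uncertainty from a fit.

    ``interval`` is the span-length multiplier in years and ``cell_area`` the
    area of a fully valid cell in km².  A cell is significant iff its p-value
    is defined and below ``alpha``.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if cell_area <= 0:
        raise ValueError(f"cell_area must be positive, got {cell_area}")
    net_fraction = fit.slope * interval
    return NetChange(
        net_fraction=net_fraction,
        net_area=net_fraction * cell_area,
        sd_area=fit.se_slope * interval * cell_area,
        significant=bool(fit.defined and fit.p_value < alpha),
        alpha=alpha,
        interval=interval,
    )


@dataclass
class TrendRaster:
    """Per-class cell grids of slope, p-value, net area, SD and significance."""

    class_names: tuple[str, ...]
    slope: dict[str, np.ndarray]  # fraction / year
    p_value: dict[str, np.ndarray]
    net_area: dict[str, np.ndarray]  # km², unmasked
    sd_area: dict[str, np.ndarray]  # km² (SD of net change)
    significant: dict[str, np.ndarray]  # bool
    block_size: int
    interval: float
    alpha: float
    cell_area: float
    years: tuple[int, ...]
    georef: Georeference = field(default_factory=Georeference)

    @property
    def cell_shape(self) -> tuple[int, int]:
        return self.slope[self.class_names[0]].shape

    def masked_net_area(self, class_name: str) -> np.ndarray:
        """Hotspot layer: net area where significant, 0 elsewhere, NaN where
        the fit is undefined (no valid data)."""
        net = self.net_area[class_name]
        out = np.where(self.significant[class_name], net, 0.0)
        out[np.isnan(net)] = np.nan
        return out

    def net_fraction(self, class_name: str) -> np.ndarray:
        return self.slope[class_name] * self.interval


def trend_surface(
    cube: FractionCube,
    interval: float | None = None,
    alpha: float = 0.1,
    classes: Sequence[str] | None = None,
) -> TrendRaster:
    """OLS trend + net change for every (cell, class) fraction series.

    ``interval`` defaults to the number of years in the cube (the span-length
    convention).  Cells with any year lacking valid pixels, or with fewer
    than 3 valid years, carry NaN in every layer.
    """
    names = tuple(classes) if classes is not None else cube.class_names
    missing = [n for n in names if n not in cube.class_names]
    if missing:
        raise ValueError(f"classes not in cube: {missing}")
    n_years = len(cube.years)
    if n_years < 3:
        raise ValueError(f"need at least 3 years for trends, got {n_years}")
    if interval is None:
        interval = float(n_years)
    if interval <= 0 or cube.cell_area <= 0:
        raise ValueError("interval and cell_area must be positive")

    idx = [cube.class_index(n) for n in names]
    y = cube.fractions[..., idx]  # (R, C, Y, K)
    # a cell-year without valid pixels voids the whole cell
    invalid_cell = (cube.valid_count == 0).any(axis=-1)
    y = np.where(invalid_cell[..., None, None], np.nan, y)
    y = np.moveaxis(y, 2, -1)  # (R, C, K, Y)

    slope, _intercept, se, p = _ols_arrays(y, n_years)

    sig = p < alpha  # NaN compares False
    net = slope * interval * cube.cell_area
    sd = se * interval * cube.cell_area
    return TrendRaster(
        class_names=names,
        slope={n: slope[..., k] for k, n in enumerate(names)},
        p_value={n: p[..., k] for k, n in enumerate(names)},
        net_area={n: net[..., k] for k, n in enumerate(names)},
        sd_area={n: sd[..., k] for k, n in enumerate(names)},
        significant={n: sig[..., k] for k, n in enumerate(names)},
        block_size=cube.block_size,
        interval=interval,
        alpha=alpha,
        cell_area=cube.cell_area,
        years=cube.years,
        georef=cube.georef,
    )


def endpoint_change(cube: FractionCube, classes: Sequence[str] | None = None) -> np.ndarray:
    """Endpoint-difference baseline: fraction(last year) - fraction(first year).

    Returns a (cell_rows, cell_cols, n_classes) array.  No significance
    concept; anomalies in the first or last year feed straight into the
    estimate, which is what the regression approach avoids.
    """
    if len(cube.years) < 2:
        raise ValueError("endpoint change needs at least 2 years")
    names = tuple(classes) if classes is not None else cube.class_names
    idx = [cube.class_index(n) for n in names]
    return cube.fractions[:, :, -1, idx] - cube.fractions[:, :, 0, idx]


# ---------------------------------------------------------------------------
# model / results layer


class LandChangeTrendModel:
    """Hotspot trend model over a block-fraction cube.

    Parameters
    ----------
    cube : FractionCube
        Per-cell annual class fractions (see
        :func:`lcluc.aggregate.block_fractions`).
    interval : float, optional
        Span-length multiplier in years; defaults to the number of years.
    alpha : float
        Hotspot significance threshold on the slope's p-value (default 0.1).
    classes : sequence of str, optional
        Classes to fit; defaults to every class in the cube.

    Examples
    --------
    >>> model = LandChangeTrendModel.from_series(series)   # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        cube: FractionCube,
        interval: float | None = None,
        alpha: float = 0.1,
        classes: Sequence[str] | None = None,
    ) -> None:
        self.cube = cube
        self.interval = float(interval) if interval is not None else float(len(cube.years))
        self.alpha = float(alpha)
        self.classes = tuple(classes) if classes is not None else cube.class_names

    @classmethod
    def from_series(
        cls,
        series,
        block_size: int = 10,
        merge_forest: bool = True,
        analysis_only: bool = True,
        interval: float | None = None,
        alpha: float = 0.1,
    ) -> "LandChangeTrendModel":
        """Build the model straight from a label series: forest merge ->
        block fractions -> model over the analysis classes."""
        from .aggregate import block_fractions, merge_classes

        if merge_forest and series.legend.forest_merge:
            series = merge_classes(series)
        cube = block_fractions(series, block_size=block_size)
        classes = series.legend.analysis_set if analysis_only and series.legend.analysis_set else None
        return cls(cube, interval=interval, alpha=alpha, classes=classes)

    def fit(self) -> "LandChangeTrendResults":
        trend = trend_surface(self.cube, interval=self.interval, alpha=self.alpha,
                              classes=self.classes)
        return LandChangeTrendResults(self, trend)


class LandChangeTrendResults:
    """Fitted per-cell trends with net-change layers and summaries."""

    def __init__(self, model: LandChangeTrendModel, trend: TrendRaster) -> None:
        self.model = model
        self.trend = trend

    # convenience accessors -------------------------------------------------

    def slope(self, class_name: str) -> np.ndarray:
        return self.trend.slope[class_name]

    def p_value(self, class_name: str) -> np.ndarray:
        return self.trend.p_value[class_name]

    def net_area(self, class_name: str, masked: bool = True) -> np.ndarray:
        return self.trend.masked_net_area(class_name) if masked else self.trend.net_area[class_name]

    def sd_area(self, class_name: str) -> np.ndarray:
        return self.trend.sd_area[class_name]

    def significant(self, class_name: str) -> np.ndarray:
        return self.trend.significant[class_name]

    def endpoint_change(self) -> np.ndarray:
        """Endpoint-difference baseline on the same cube and classes."""
        return endpoint_change(self.model.cube, self.trend.class_names)

    # summaries --------------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Domain-wide per-class accounting of significant net changes."""
        rows = []
        for name in self.trend.class_names:
            net = self.trend.net_area[name]
            sd = self.trend.sd_area[name]
            sig = self.trend.significant[name]
            fitted = ~np.isnan(net)
            signet = net[sig & fitted]
            rows.append(
                {
                    "class": name,
                    "n_cells": int(fitted.sum()),
                    "n_significant": int((sig & fitted).sum()),
                    "gain_km2": float(signet[signet > 0].sum()),
                    "loss_km2": float(signet[signet < 0].sum()),
                    "net_km2": float(signet.sum()),
                    "sd_km2": float(np.sqrt((sd[sig & fitted] ** 2).sum())),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        t = self.trend
        head = (
            "Land-cover change trend summary\n"
            f"years {t.years[0]}-{t.years[-1]} (n={len(t.years)}), "
            f"interval x{t.interval:g}, alpha={t.alpha:g}, "
            f"cell {t.block_size}x{t.block_size} px = {t.cell_area:g} km2\n"
            f"cells {t.cell_shape[0]}x{t.cell_shape[1]}\n"
        )
        return head + df.to_string(index=False, float_format=lambda v: f"{v:.3f}")

    # downstream stages -------------------------------------------------------

    def zonal(self, zones: np.ndarray, zone_names: dict[int, str] | None = None,
              zone_ids: Sequence[int] | None = None) -> pd.DataFrame:
        from .zonal import zonal_net_change

        return zonal_net_change(self.trend, zones, zone_names=zone_names, zone_ids=zone_ids)

    def conversion_association(self, class_a: str, class_b: str,
                               zone_mask: np.ndarray | None = None):
        from .zonal import conversion_association

        return conversion_association(self.trend, class_a, class_b, zone_mask=zone_mask)

    def save(self, out_dir, stem: str = "trend") -> None:
        from .io import write_trend_raster

        write_trend_raster(self.trend, out_dir, stem=stem)
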