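"""On-disk artifacts: annual label rasters, legends, trend layers, tables.

Rasters are written as multi-band TIFF via :mod:`tifffile`, with a JSON
sidecar (``<name>.json`` next to ``<name>.tif``) carrying the affine
transform, CRS identifier, nodata code and band semantics.  The sidecar
keeps the raster self-describing without a GIS stack; transforms follow the
GDAL convention ``(a, b, c, d, e, f)`` mapping pixel ``(col, row)`` to
``(x, y) = (a*col + b*row + c, d*col + e*row + f)``.

Pixel indexing is 0-based with half-open block intervals: aggregation cell
``(i, j)`` covers input pixels ``[B*i, B*i+B) x [B*j, B*j+B)`` in row-major
order for block size ``B``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .legend import ClassLegend

#: Identity georeference for synthetic data: unit pixels anchored at origin.
IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)


@dataclass(frozen=True)
class Georeference:
    """Affine transform + CRS identifier for a pixel grid."""

    transform: tuple[float, float, float, float, float, float] = IDENTITY_TRANSFORM
    crs: str | None = None

    def scaled(self, block_size: int) -> "Georeference":
        """Georeference of the block grid: pixel size scaled by ``block_size``,
        origin unchanged."""
        a, b, c, d, e, f = self.transform
        k = float(block_size)
        return Georeference((a * k, b * k, c, d * k, e * k, f), self.crs)


@dataclass
class LandCoverSeries:
    """Co-registered stack of annual integer label grids.

    Attributes
    ----------
    years : tuple[int, ...]
        Strictly increasing acquisition years, one per grid.
    labels : numpy.ndarray
        ``(n_years, rows, cols)`` integer class codes.
    legend : ClassLegend
        Code/name mapping; every non-nodata label must be a legend code.
    georef : Georeference
        Shared georeference (identity transform for synthetic data).
    pixel_size : float
        Pixel edge length in metres (used for cell areas downstream).
    """

    years: tuple[int, ...]
    labels: np.ndarray
    legend: ClassLegend
    georef: Georeference = field(default_factory=Georeference)
    pixel_size: float = 250.0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (years, rows, cols) array")
        if len(self.years) != self.labels.shape[0]:
            raise ValueError(
                f"{len(self.years)} years but {self.labels.shape[0]} label grids"
            )
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError(f"years not strictly increasing: {self.years}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        known = set(self.legend.codes) | {self.legend.nodata_code}
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - known)
        if unknown:
            raise ValueError(f"labels contain codes absent from the legend: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape[1:]

    @property
    def n_years(self) -> int:
        return len(self.years)

    def with_labels(self, labels: np.ndarray, legend: ClassLegend | None = None) -> "LandCoverSeries":
        return replace(self, labels=labels, legend=legend or self.legend)


# ---------------------------------------------------------------------------
# label series


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_series(series: LandCoverSeries, out_dir: str | Path, stem: str = "landcover") -> list[Path]:
    """Write one single-band TIFF per year plus a shared sidecar.

    Returns the raster paths in year order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, year in enumerate(series.years):
        p = out_dir / f"{stem}_{year}.tif"
        tifffile.imwrite(p, series.labels[i].astype(np.int16))
        paths.append(p)
    meta = {
        "years": list(series.years),
        "files": [p.name for p in paths],
        "transform": list(series.georef.transform),
        "crs": series.georef.crs,
        "nodata_code": series.legend.nodata_code,
        "pixel_size": series.pixel_size,
    }
    _sidecar(out_dir / f"{stem}_series.tif").write_text(json.dumps(meta, indent=2))
    series.legend.to_json(out_dir / f"{stem}_legend.json")
    return paths


def read_series(
    paths: Sequence[str | Path] | str | Path,
    legend_path: str | Path,
    years: Sequence[int] | None = None,
    pixel_size: float = 250.0,
) -> LandCoverSeries:
    """Read an annual label stack from per-year rasters or one multi-band raster.

    Parameters
    ----------
    paths
        One raster per year (list, year order) or a single multi-band raster
        whose band order is year order.
    legend_path
        JSON legend written by :meth:`ClassLegend.to_json`.
    years
        Acquisition years; defaults to the sidecar's ``years`` or, failing
        that, ``0..n-1``.

    Raises
    ------
    ValueError
        On shape or georeference mismatch between files (naming the file) or
        on codes absent from the legend (listing the codes).
    """
    legend = ClassLegend.from_json(legend_path)
    if isinstance(paths, (str, Path)):
        paths = [Path(paths)]
    else:
        paths = [Path(p) for p in paths]

    grids: list[np.ndarray] = []
    for p in paths:
        try:
            arr = tifffile.imread(p)
        except (OSError, ValueError) as exc:
            raise ValueError(f"unreadable raster {p}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        for band in arr:
            if grids and band.shape != grids[0].shape:
                raise ValueError(
                    f"raster {p} has shape {band.shape}, expected {grids[0].shape}"
                )
            grids.append(band)
    labels = np.stack(grids).astype(np.int64)

    georef = Georeference()
    meta_pixel_size = None
    # sidecar is optional: look next to the first raster
    for cand in (paths[0].parent.glob("*_series.json")):
        meta = json.loads(cand.read_text())
        georef = Georeference(tuple(meta["transform"]), meta.get("crs"))
        if years is None and len(meta.get("years", ())) == len(grids):
            years = meta["years"]
        meta_pixel_size = meta.get("pixel_size")
        break
    if years is None:
        years = range(len(grids))

    return LandCoverSeries(
        years=tuple(int(y) for y in years),
        labels=labels,
        legend=legend,
        georef=georef,
        pixel_size=float(meta_pixel_size or pixel_size),
    )


# ---------------------------------------------------------------------------
# trend rasters

TREND_BANDS = ("slope", "p_value", "net_area", "sd_area", "significant")


def write_trend_raster(trend, out_dir: str | Path, stem: str = "trend") -> dict[str, Path]:
    """Serialize a :class:`~lcluc.trend.TrendRaster` as one multi-band TIFF
    per analysis class (bands: slope, p_value, net_area, sd_area,
    significant) plus a provenance sidecar.

    Cells without a defined fit carry NaN in every float band and -1 in the
    significance band.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in trend.class_names:
        stack = np.stack(
            [
                trend.slope[name],
                trend.p_value[name],
                trend.net_area[name],
                trend.sd_area[name],
                np.where(
                    np.isnan(trend.p_value[name]), -1.0, trend.significant[name].astype(float)
                ),
            ]
        ).astype(np.float64)
        p = out_dir / f"{stem}_{name}.tif"
        tifffile.imwrite(p, stack, photometric="minisblack")
        paths[name] = p
    meta = {
        "classes": list(trend.class_names),
        "bands": list(TREND_BANDS),
        "files": {n: p.name for n, p in paths.items()},
        "block_size": trend.block_size,
        "interval": trend.interval,
        "alpha": trend.alpha,
        "cell_area": trend.cell_area,
        "years": list(trend.years),
        "transform": list(trend.georef.transform),
        "crs": trend.georef.crs,
    }
    (out_dir / f"{stem}_provenance.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_trend_raster(out_dir: str | Path, stem: str = "trend"):
    """Round-trip counterpart of :func:`write_trend_raster`."""
    from .trend import TrendRaster  # local import to avoid a cycle

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}_provenance.json").read_text())
    slope, p_value, net_area, sd_area, significant = {}, {}, {}, {}, {}
    for name in meta["classes"]:
        stack = tifffile.imread(out_dir / meta["files"][name])
        slope[name] = stack[0]
        p_value[name] = stack[1]
        net_area[name] = stack[2]
        sd_area[name] = stack[3]
        significant[name] = stack[4] > 0.5
    return TrendRaster(
        class_names=tuple(meta["classes"]),
        slope=slope,
        p_value=p_value,
        net_area=net_area,
        sd_area=sd_area,
        significant=significant,
        block_size=int(meta["block_size"]),
        interval=float(meta["interval"]),
        alpha=float(meta["alpha"]),
        cell_area=float(meta["cell_area"]),
        years=tuple(meta["years"]),
        georef=Georeference(tuple(meta["transform"]), meta.get("crs")),
    )


# ---------------------------------------------------------------------------
# probability stacks (fusion inputs/outputs)


def write_probability_stack(probs: np.ndarray, path: str | Path, class_codes: Sequence[int]) -> None:
    """Write a per-class probability stack, band order = legend order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(probs, dtype=np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"class_codes": [int(c) for c in class_codes]}))


def read_probability_stack(path: str | Path) -> tuple[np.ndarray, list[int]]:
    path = Path(path)
    probs = tifffile.imread(path).astype(np.float64)
    codes = json.loads(_sidecar(path).read_text())["class_codes"]
    return probs, [int(c) for c in codes]


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)
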