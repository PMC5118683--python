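"""Block aggregation: label series -> per-cell class-fraction time series.

The analysis unit is the "big grid cell": a block of ``block_size`` x
``block_size`` pixels (default 10 x 10, i.e. 2.5 x 2.5 km at the nominal
250 m pixel) within which the fraction of each land-cover class is tracked
annually.  Trend regression then runs on each cell's fraction series.

Fraction denominators count all valid (non-nodata) pixels of every legend
class, including classes outside the analysis set, so fractions over the
full legend sum to exactly 1 in fully valid cells and per-cell trend slopes
cancel exactly across the full legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Georeference, LandCoverSeries
from .legend import ClassLegend


@dataclass
class FractionCube:
    """Per-cell x year x class fraction array with validity counts.

    Attributes
    ----------
    fractions : numpy.ndarray
        ``(cell_rows, cell_cols, n_years, n_classes)`` array; fraction of the
        cell's *valid* pixels carrying each class.
    valid_count : numpy.ndarray
        ``(cell_rows, cell_cols, n_years)`` count of non-nodata pixels.
    years : tuple[int, ...]
    class_names : tuple[str, ...]
        Class order of the last axis.
    block_size : int
        Pixels per cell edge.
    cell_area : float
        Area of a fully valid cell in km² (6.25 for 10x10 blocks of 250 m
        pixels).
    covers_legend : bool
        True when ``class_names`` span the full legend, so fractions sum to 1
        in fully valid cells.
    """

    fractions: np.ndarray
    valid_count: np.ndarray
    years: tuple[int, ...]
    class_names: tuple[str, ...]
    block_size: int = 10
    cell_area: float = 6.25
    georef: Georeference = field(default_factory=Georeference)
    covers_legend: bool = True
    n_dropped_edge_cells: int = 0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.valid_count = np.asarray(self.valid_count)
        self.years = tuple(int(y) for y in self.years)
        self.class_names = tuple(self.class_names)
        if self.fractions.ndim != 4:
            raise ValueError("fractions must be (cell_rows, cell_cols, years, classes)")
        r, c, y, k = self.fractions.shape
        if self.valid_count.shape != (r, c, y):
            raise ValueError("valid_count shape does not match fractions")
        if y != len(self.years):
            raise ValueError(f"{len(self.years)} years but {y} fraction layers")
        if k != len(self.class_names):
            raise ValueError(f"{len(self.class_names)} classes but {k} fraction layers")

    @property
    def cell_shape(self) -> tuple[int, int]:
        return self.fractions.shape[:2]

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in cube (has {self.class_names})") from None

    def select(self, class_names: Sequence[str]) -> "FractionCube":
        """Restrict to a subset of classes (fractions unchanged)."""
        idx = [self.class_index(n) for n in class_names]
        return FractionCube(
            fractions=self.fractions[..., idx],
            valid_count=self.valid_count,
            years=self.years,
            class_names=tuple(class_names),
            block_size=self.block_size,
            cell_area=self.cell_area,
            georef=self.georef,
            covers_legend=False,
            n_dropped_edge_cells=self.n_dropped_edge_cells,
        )

    # -- tabular round trip ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        r, c, y, k = self.fractions.shape
        rows, cols, yrs, cls = np.meshgrid(
            np.arange(r), np.arange(c), np.array(self.years), np.arange(k), indexing="ij"
        )
        return pd.DataFrame(
            {
                "cell_row": rows.ravel(),
                "cell_col": cols.ravel(),
                "year": yrs.ravel(),
                "class": np.array(self.class_names)[cls.ravel()],
                "fraction": self.fractions.ravel(),
                "valid_count": np.repeat(self.valid_count.ravel(), k),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, block_size: int = 10, cell_area: float = 6.25
    ) -> "FractionCube":
        years = tuple(sorted(df["year"].unique().tolist()))
        names = tuple(dict.fromkeys(df["class"].tolist()))
        r = int(df["cell_row"].max()) + 1
        c = int(df["cell_col"].max()) + 1
        fr = np.full((r, c, len(years), len(names)), np.nan)
        vc = np.zeros((r, c, len(years)), dtype=np.int64)
        yi = {y: i for i, y in enumerate(years)}
        ki = {n: i for i, n in enumerate(names)}
        fr[
            df["cell_row"].to_numpy(),
            df["cell_col"].to_numpy(),
            df["year"].map(yi).to_numpy(),
            df["class"].map(ki).to_numpy(),
        ] = df["fraction"].to_numpy()
        vc[
            df["cell_row"].to_numpy(),
            df["cell_col"].to_numpy(),
            df["year"].map(yi).to_numpy(),
        ] = df["valid_count"].to_numpy()
        return cls(fr, vc, years, names, block_size=block_size, cell_area=cell_area,
                   covers_legend=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "FractionCube":
        return cls.from_frame(pd.read_csv(path), **kwargs)


def merge_classes(series: LandCoverSeries, legend: ClassLegend | None = None) -> LandCoverSeries:
    """Collapse all forest types into the merged forest super-class (FORE).

    Codes in ``legend.forest_merge`` are relabelled to
    ``legend.merge_target``; all other codes pass through unchanged.
    """
    legend = legend or series.legend
    if not legend.forest_merge:
        raise ValueError("legend defines no forest_merge set")
    target = legend.merge_target_code
    labels = series.labels.copy()
    mask = np.isin(labels, legend.forest_merge_codes)
    labels[mask] = target
    return series.with_labels(labels, legend)


def block_fractions(
    series: LandCoverSeries,
    block_size: int = 10,
    classes: Sequence[str] | None = None,
) -> FractionCube:
    """Per big-grid-cell class fractions for every year.

    fraction = (valid pixels of the class in the cell) / (valid pixels in the
    cell).  Cells with some nodata pixels keep the reduced denominator; cells
    with zero valid pixels get NaN fractions.  Trailing partial edge blocks
    (grid not divisible by ``block_size``) are dropped and counted in
    ``n_dropped_edge_cells``.
    """
    if block_size <= 0:
        raise ValueError(f"block_size must be positive, got {block_size}")
    legend = series.legend
    names = tuple(classes) if classes is not None else tuple(legend.entries.values())
    if not names:
        raise ValueError("empty class list")
    unknown = [n for n in names if n not in legend.entries.values()]
    if unknown:
        raise ValueError(f"classes not in legend: {unknown}")
    codes = [legend.code(n) for n in names]

    n_years, rows, cols = series.labels.shape
    cr, cc = rows // block_size, cols // block_size
    if cr == 0 or cc == 0:
        raise ValueError(
            f"grid {rows}x{cols} smaller than one {block_size}x{block_size} block"
        )
    n_dropped = (rows // block_size + (1 if rows % block_size else 0)) * (
        cols // block_size + (1 if cols % block_size else 0)
    ) - cr * cc

    trimmed = series.labels[:, : cr * block_size, : cc * block_size]
    # (years, cr, B, cc, B) -> (cr, cc, years, B*B)
    blocks = (
        trimmed.reshape(n_years, cr, block_size, cc, block_size)
        .transpose(1, 3, 0, 2, 4)
        .reshape(cr, cc, n_years, block_size * block_size)
    )
    valid = blocks != legend.nodata_code
    valid_count = valid.sum(axis=-1)

    counts = np.empty((cr, cc, n_years, len(codes)), dtype=np.int64)
    for k, code in enumerate(codes):
        counts[..., k] = (blocks == code).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = counts / valid_count[..., None]
    fractions[valid_count == 0] = np.nan

    full_legend = set(names) == set(legend.entries.values())
    pixel_km = series.pixel_size / 1000.0
    return FractionCube(
        fractions=fractions,
        valid_count=valid_count,
        years=series.years,
        class_names=names,
        block_size=block_size,
        cell_area=(pixel_km * block_size) ** 2,
        georef=series.georef.scaled(block_size),
        covers_legend=full_legend,
        n_dropped_edge_cells=int(n_dropped),
    )
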