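"""Synthetic annual land-cover scenarios with known conversion trends.

Generates categorical label stacks that emulate the data regime of a
13-year annual land-cover map series: regionally localized, constant-rate
class conversions (urban rings expanding into cropland, cropland reclaimed
from grassland, shrubland succeeding to forest), per-pixel misclassification
noise drawn from a confusion table, and optional anomaly years with elevated
noise (the extreme-climate failure mode that endpoint differencing is
vulnerable to).  Every scenario carries an analytically derived ground
truth, so downstream trend estimates can be scored against designed slopes
rather than against another realization.

Conversion demand is converted from fractional rates to integer pixel
counts by rounding the *cumulative* target each year (largest-remainder with
the running remainder carried), so the expected fraction trajectory of each
class is exactly affine in the year index.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .aggregate import FractionCube
from .io import Georeference, LandCoverSeries
from .legend import ClassLegend, default_legend

DEFAULT_YEARS = tuple(range(2001, 2014))


@dataclass(frozen=True)
class Transition:
    """One constant-rate conversion within a named region.

    annual_rate is the fraction of the region's area converted per year.
    ``clustered`` mode accretes conversions around existing to-class patches
    (contiguous hotspots); ``random`` converts uniformly chosen eligible
    pixels.
    """

    region: str
    from_class: str
    to_class: str
    annual_rate: float
    spatial_mode: Literal["clustered", "random"] = "clustered"


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic landscape experiment.

    Attributes
    ----------
    grid_shape : (rows, cols) in pixels.
    pixel_size : pixel edge length in metres.
    years : strictly increasing acquisition years.
    legend : class legend shared by all grids.
    regions : named boolean pixel masks (each ``grid_shape``).
    region_initial : per-region initial class-fraction composition
        (name -> {class: fraction}); pixels outside all regions use
        ``background``.
    background : initial class fractions outside all regions.
    transitions : constant-rate conversions.
    noise_rate : per-pixel per-year misclassification probability.
    confusion : row-stochastic (K, K) table over ``legend.codes`` order used
        to draw replacement labels for flipped pixels; None = uniform over
        the other classes.
    anomaly_years : years whose noise rate is replaced by
        ``anomaly_noise_rate`` (a one-year perturbation, not a level shift).
    block_size : big-grid cell edge (pixels) used for the analytic ground
        truth.
    seed : RNG seed; identical config + seed -> bit-identical series.
    """

    grid_shape: tuple[int, int]
    years: Sequence[int] = DEFAULT_YEARS
    pixel_size: float = 250.0
    legend: ClassLegend = field(default_factory=default_legend)
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    region_initial: dict[str, dict[str, float]] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=lambda: {"GRAS": 1.0})
    transitions: list[Transition] = field(default_factory=list)
    noise_rate: float = 0.0
    confusion: np.ndarray | None = None
    anomaly_years: tuple[int, ...] = ()
    anomaly_noise_rate: float | None = None
    block_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.validate()

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"invalid grid_shape {self.grid_shape}")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        names = set(self.legend.entries.values())
        for rname, mask in self.regions.items():
            if np.asarray(mask).shape != (rows, cols):
                raise ValueError(f"region {rname!r} mask does not fit grid {self.grid_shape}")
        for comp_name, comp in [("background", self.background)] + [
            (f"region_initial[{r!r}]", c) for r, c in self.region_initial.items()
        ]:
            unknown = set(comp) - names
            if unknown:
                raise ValueError(f"{comp_name} uses unknown classes {sorted(unknown)}")
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{comp_name} fractions sum to {total}, expected 1")
        for t in self.transitions:
            if t.region not in self.regions:
                raise ValueError(f"transition references unknown region {t.region!r}")
            for cname in (t.from_class, t.to_class):
                if cname not in names:
                    raise ValueError(f"transition uses unknown class {cname!r}")
            if t.annual_rate < 0:
                raise ValueError(f"negative annual_rate in transition {t}")
            if t.spatial_mode not in ("clustered", "random"):
                raise ValueError(f"unknown spatial_mode {t.spatial_mode!r}")
        # total outflow over the full span must not exceed initial stock
        n_steps = len(self.years) - 1
        outflow: dict[tuple[str, str], float] = {}
        for t in self.transitions:
            key = (t.region, t.from_class)
            outflow[key] = outflow.get(key, 0.0) + t.annual_rate * n_steps
        for (rname, cname), demand in outflow.items():
            comp = self.region_initial.get(rname, self.background)
            avail = comp.get(cname, 0.0)
            if demand > avail + 1e-9:
                raise ValueError(
                    f"transitions demand {demand:.4f} of region {rname!r} from class "
                    f"{cname!r} over {n_steps} steps but only {avail:.4f} is available"
                )
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate {self.noise_rate} outside [0, 1]")
        if self.anomaly_noise_rate is not None and not 0.0 <= self.anomaly_noise_rate <= 1.0:
            raise ValueError(f"anomaly_noise_rate {self.anomaly_noise_rate} outside [0, 1]")
        if self.confusion is not None:
            _check_confusion(self.confusion, len(self.legend.codes))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a scenario from a TOML or JSON document.

        Regions are given as inclusive-exclusive rectangles
        ``[row0, row1, col0, col1]``; transitions as tables with keys
        region/from/to/rate/mode.
        """
        path = Path(path)
        if path.suffix == ".toml":
            doc = tomllib.loads(path.read_text())
        else:
            doc = json.loads(path.read_text())
        known = {
            "grid_shape", "years", "pixel_size", "regions", "region_initial",
            "background", "transitions", "noise_rate", "anomaly_years",
            "anomaly_noise_rate", "block_size", "seed",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
        shape = tuple(doc["grid_shape"])
        regions = {
            name: rect_mask(shape, *rect) for name, rect in doc.get("regions", {}).items()
        }
        transitions = [
            Transition(
                region=t["region"],
                from_class=t["from"],
                to_class=t["to"],
                annual_rate=float(t["rate"]),
                spatial_mode=t.get("mode", "clustered"),
            )
            for t in doc.get("transitions", [])
        ]
        return cls(
            grid_shape=shape,
            years=tuple(doc.get("years", DEFAULT_YEARS)),
            pixel_size=float(doc.get("pixel_size", 250.0)),
            regions=regions,
            region_initial=doc.get("region_initial", {}),
            background=doc.get("background", {"GRAS": 1.0}),
            transitions=transitions,
            noise_rate=float(doc.get("noise_rate", 0.0)),
            anomaly_years=tuple(doc.get("anomaly_years", ())),
            anomaly_noise_rate=doc.get("anomaly_noise_rate"),
            block_size=int(doc.get("block_size", 10)),
            seed=int(doc.get("seed", 0)),
        )


def rect_mask(shape: tuple[int, int], row0: int, row1: int, col0: int, col1: int) -> np.ndarray:
    """Boolean mask for the half-open pixel rectangle [row0,row1) x [col0,col1)."""
    m = np.zeros(shape, dtype=bool)
    m[row0:row1, col0:col1] = True
    return m


@dataclass
class GroundTruth:
    """Analytic truth for a scenario, derived from the config (never from the
    realization).

    ``designed_slope`` holds, per big-grid cell and class, the expected
    fraction change per year.  Per-cell slopes are exact in expectation for
    ``random``-mode transitions with spatially uniform initial from-class
    cover; for ``clustered`` mode only the region-level net areas are exact
    (the conversion front sweeps cells sequentially).  Slopes across all
    classes sum to zero per cell by construction.
    """

    class_names: tuple[str, ...]
    designed_slope: np.ndarray  # (cell_rows, cell_cols, n_classes), fraction/yr
    interval: float  # net-change multiplier (printed span length in years)
    cell_area: float  # km² per fully valid cell
    region_net_area: dict[tuple[str, str], float]  # (region, class) -> km²

    @property
    def designed_net_fraction(self) -> np.ndarray:
        return self.designed_slope * self.interval

    def slope_for(self, class_name: str) -> np.ndarray:
        return self.designed_slope[..., self.class_names.index(class_name)]

    def to_csv(self, path: str | Path) -> None:
        r, c, k = self.designed_slope.shape
        rows, cols, cls = np.meshgrid(
            np.arange(r), np.arange(c), np.arange(k), indexing="ij"
        )
        pd.DataFrame(
            {
                "cell_row": rows.ravel(),
                "cell_col": cols.ravel(),
                "class": np.array(self.class_names)[cls.ravel()],
                "designed_slope": self.designed_slope.ravel(),
                "designed_net_fraction": self.designed_net_fraction.ravel(),
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generation


def _initial_map(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Year-0 mosaic: exact class counts per region via largest-remainder,
    placed by a seeded permutation."""
    rows, cols = config.grid_shape
    legend = config.legend
    labels = np.empty((rows, cols), dtype=np.int64)

    covered = np.zeros((rows, cols), dtype=bool)
    zones: list[tuple[np.ndarray, dict[str, float]]] = []
    for rname, mask in config.regions.items():
        mask = np.asarray(mask, dtype=bool) & ~covered  # first region wins overlaps
        zones.append((mask, config.region_initial.get(rname, config.background)))
        covered |= mask
    zones.append((~covered, config.background))

    for mask, comp in zones:
        n = int(mask.sum())
        if n == 0:
            continue
        names = list(comp)
        counts = _largest_remainder([comp[c] * n for c in names], n)
        pool = np.repeat([legend.code(c) for c in names], counts)
        labels[mask] = rng.permutation(pool)
    return labels


def _largest_remainder(targets: Sequence[float], total: int) -> np.ndarray:
    """Integer apportionment of ``total`` matching fractional targets."""
    t = np.asarray(targets, dtype=np.float64)
    base = np.floor(t).astype(np.int64)
    short = total - int(base.sum())
    order = np.argsort(-(t - base), kind="stable")
    base[order[:short]] += 1
    return base


def _convert_clustered(
    labels: np.ndarray, region: np.ndarray, from_code: int, to_code: int, demand: int
) -> np.ndarray:
    """Indices (flat) of the ``demand`` eligible pixels nearest to existing
    to-class cover, ties broken row-major.  Seeds at the first eligible pixel
    when the region holds no to-class pixel yet."""
    eligible = region & (labels == from_code)
    flat = np.flatnonzero(eligible)
    if flat.size < demand:
        raise ValueError("insufficient eligible pixels")  # caller adds context
    seeds = region & (labels == to_code)
    if not seeds.any():
        first = np.zeros_like(seeds)
        first.flat[flat[0]] = True
        seeds = first
    dist = ndimage.distance_transform_edt(~seeds)
    keys = dist.flat[flat]
    order = np.lexsort((flat, keys))  # distance first, then row-major
    return flat[order[:demand]]


def generate_series(config: ScenarioConfig) -> tuple[LandCoverSeries, GroundTruth]:
    """Realize a scenario: one label grid per year plus analytic ground truth.

    Year 0 carries the initial mosaic; each subsequent year converts pixels
    per transition, with cumulative demand rounded so expected fraction
    trajectories are affine in the year index.  Noise (if configured) is a
    separate observation layer applied by :func:`apply_noise`; the returned
    series here is noise-free truth.

    Raises
    ------
    ValueError
        When a transition demands more pixels than are eligible, naming the
        region, class and year.
    """
    rng = np.random.default_rng(config.seed)
    legend = config.legend
    labels0 = _initial_map(config, rng)
    n_years = len(config.years)
    grids = [labels0]

    region_px = {name: int(np.asarray(m, bool).sum()) for name, m in config.regions.items()}
    converted = {i: 0 for i in range(len(config.transitions))}

    current = labels0
    for step in range(1, n_years):
        current = current.copy()
        for ti, t in enumerate(config.transitions):
            target = int(np.floor(step * t.annual_rate * region_px[t.region] + 0.5))
            demand = target - converted[ti]
            if demand <= 0:
                continue
            region = np.asarray(config.regions[t.region], dtype=bool)
            from_code, to_code = legend.code(t.from_class), legend.code(t.to_class)
            if t.spatial_mode == "clustered":
                try:
                    chosen = _convert_clustered(current, region, from_code, to_code, demand)
                except ValueError:
                    chosen = None
            else:
                flat = np.flatnonzero(region & (current == from_code))
                chosen = (
                    rng.choice(flat, size=demand, replace=False) if flat.size >= demand else None
                )
            if chosen is None:
                raise ValueError(
                    f"transition {t.from_class}->{t.to_class} in region {t.region!r} "
                    f"needs {demand} pixels in year {config.years[step]} but fewer are eligible"
                )
            current.flat[chosen] = to_code
            converted[ti] = target
        grids.append(current)

    series = LandCoverSeries(
        years=config.years,
        labels=np.stack(grids),
        legend=legend,
        georef=Georeference(),
        pixel_size=config.pixel_size,
    )
    return series, _ground_truth(config, region_px)


def _ground_truth(config: ScenarioConfig, region_px: dict[str, int]) -> GroundTruth:
    legend = config.legend
    names = tuple(legend.entries.values())
    b = config.block_size
    rows, cols = config.grid_shape
    cr, cc = rows // b, cols // b
    slope = np.zeros((cr, cc, len(names)), dtype=np.float64)
    interval = float(len(config.years))
    pixel_km2 = (config.pixel_size / 1000.0) ** 2
    region_net: dict[tuple[str, str], float] = {}

    for t in config.transitions:
        mask = np.asarray(config.regions[t.region], dtype=bool)[: cr * b, : cc * b]
        overlap = mask.reshape(cr, b, cc, b).sum(axis=(1, 3))  # pixels of cell in region
        per_cell = t.annual_rate * overlap / (b * b)  # fraction/yr of the cell
        ki_from, ki_to = names.index(t.from_class), names.index(t.to_class)
        slope[..., ki_to] += per_cell
        slope[..., ki_from] -= per_cell
        net = t.annual_rate * region_px[t.region] * interval * pixel_km2
        for cname, sign in ((t.to_class, 1.0), (t.from_class, -1.0)):
            key = (t.region, cname)
            region_net[key] = region_net.get(key, 0.0) + sign * net

    return GroundTruth(
        class_names=names,
        designed_slope=slope,
        interval=interval,
        cell_area=(config.pixel_size / 1000.0 * b) ** 2,
        region_net_area=region_net,
    )


# ---------------------------------------------------------------------------
# observation noise


def _check_confusion(confusion: np.ndarray, n_classes: int) -> None:
    confusion = np.asarray(confusion, dtype=np.float64)
    if confusion.shape != (n_classes, n_classes):
        raise ValueError(
            f"confusion must be ({n_classes}, {n_classes}) in legend-code order"
        )
    if (confusion < 0).any():
        raise ValueError("confusion entries must be non-negative")
    bad = np.flatnonzero(np.abs(confusion.sum(axis=1) - 1.0) > 1e-9)
    if bad.size:
        raise ValueError(f"confusion rows {bad.tolist()} do not sum to 1")


def uniform_confusion(n_classes: int) -> np.ndarray:
    """Confusion table that relabels uniformly among the *other* classes."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    c = np.full((n_classes, n_classes), 1.0 / (n_classes - 1))
    np.fill_diagonal(c, 0.0)
    return c


def apply_noise(
    series: LandCoverSeries,
    noise_rate: float,
    confusion: np.ndarray | None = None,
    anomaly_years: Sequence[int] = (),
    anomaly_noise_rate: float | None = None,
    seed: int = 0,
) -> LandCoverSeries:
    """Per-pixel, per-year misclassification noise.

    Each pixel-year is independently relabelled with probability
    ``noise_rate`` (``anomaly_noise_rate`` in anomaly years); the replacement
    is drawn from the confusion row of the current label.  Nodata pixels are
    untouched.  Deterministic under a fixed seed.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError(f"noise_rate {noise_rate} outside [0, 1]")
    if anomaly_noise_rate is not None and not 0.0 <= anomaly_noise_rate <= 1.0:
        raise ValueError(f"anomaly_noise_rate {anomaly_noise_rate} outside [0, 1]")
    codes = np.array(series.legend.codes)
    if confusion is None:
        confusion = uniform_confusion(len(codes))
    _check_confusion(confusion, len(codes))
    cum = np.cumsum(np.asarray(confusion, dtype=np.float64), axis=1)
    code_to_idx = np.full(codes.max() + 1, -1, dtype=np.int64)
    code_to_idx[codes] = np.arange(len(codes))

    rng = np.random.default_rng(seed)
    anomaly = set(int(y) for y in anomaly_years)
    out = series.labels.copy()
    for yi, year in enumerate(series.years):
        rate = anomaly_noise_rate if (year in anomaly and anomaly_noise_rate is not None) else noise_rate
        grid = out[yi]
        flip = (rng.random(grid.shape) < rate) & (grid != series.legend.nodata_code)
        if not flip.any():
            continue
        rows_idx = code_to_idx[grid[flip]]
        u = rng.random(rows_idx.shape)
        # inverse-CDF draw from each pixel's confusion row
        new_idx = (u[:, None] >= cum[rows_idx]).sum(axis=1)
        grid[flip] = codes[new_idx]
    return series.with_labels(out)


# ---------------------------------------------------------------------------
# classifier-output fixtures for fusion


def generate_classifier_outputs(
    series: LandCoverSeries,
    n_models: int,
    reliability: float | Sequence[float],
    seed: int = 0,
    year_index: int = 0,
    concentration: float = 100.0,
):
    """Simulate per-model label grids + class-membership probability stacks.

    Each model assigns the true label with probability equal to its
    reliability and a uniformly drawn wrong label otherwise; the pixel's
    probability vector is a Dirichlet draw concentrated on the assigned
    label (mean mass = reliability on the assigned class, symmetric over the
    rest), and the reported label is the argmax of that vector.  At the
    default concentration the argmax coincides with the assigned label, so
    per-model label accuracy equals the reliability in expectation.
    """
    from .fusion import ClassifierOutput

    if n_models < 2:
        raise ValueError("need at least 2 models")
    rels = [reliability] * n_models if np.isscalar(reliability) else list(reliability)
    if len(rels) != n_models:
        raise ValueError(f"{len(rels)} reliabilities for {n_models} models")
    if any(not 0.0 < r <= 1.0 for r in rels):
        raise ValueError("reliability must lie in (0, 1]")

    codes = np.array(series.legend.codes)
    k = len(codes)
    truth = series.labels[year_index]
    code_to_idx = np.full(codes.max() + 1, -1, dtype=np.int64)
    code_to_idx[codes] = np.arange(k)
    truth_idx = code_to_idx[truth]

    rng = np.random.default_rng(seed)
    outputs = []
    for m, r in enumerate(rels):
        correct = rng.random(truth.shape) < r
        offset = rng.integers(1, k, size=truth.shape)  # uniform over wrong classes
        assigned = np.where(correct, truth_idx, (truth_idx + offset) % k)
        if r == 1.0:
            probs = np.zeros((k,) + truth.shape)
            np.put_along_axis(probs, assigned[None], 1.0, axis=0)
        else:
            alpha_hi = concentration * r
            alpha_lo = concentration * (1.0 - r) / (k - 1)
            g = rng.gamma(alpha_lo, size=(k,) + truth.shape)
            hi = rng.gamma(alpha_hi, size=truth.shape)
            np.put_along_axis(g, assigned[None], hi[None], axis=0)
            probs = g / g.sum(axis=0, keepdims=True)
        labels = codes[np.argmax(probs, axis=0)]
        outputs.append(
            ClassifierOutput(labels=labels, probabilities=probs, class_codes=tuple(codes),
                             model_id=f"model_{m}")
        )
    return outputs


# ---------------------------------------------------------------------------
# direct fraction-series scenarios (Gaussian observation noise)


def linear_fraction_cube(
    n_cells: int,
    slope: float,
    intercept: float = 0.3,
    noise_sd: float = 0.03,
    years: Sequence[int] = DEFAULT_YEARS,
    class_name: str = "AGRI",
    complement_class: str = "GRAS",
    seed: int = 0,
    block_size: int = 10,
    cell_area: float = 6.25,
) -> tuple[FractionCube, float]:
    """Fraction cube with a designed linear trend plus iid Gaussian noise.

    Emulates the regression stage's input directly: every cell's fraction of
    ``class_name`` follows ``intercept + slope * t + N(0, noise_sd²)`` on the
    year index t, with a complementary class absorbing the remainder so the
    two-class total stays at 1 before noise.  Returns the cube and the
    designed net fraction (slope x span length).  Values are not clipped, so
    the slope estimator's t statistics keep their exact null distribution.
    """
    years = tuple(int(y) for y in years)
    n_years = len(years)
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=np.float64)
    clean = intercept + slope * t
    noisy = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_cells, n_years))
    fractions = np.stack([noisy, 1.0 - noisy], axis=-1)[:, None, :, :]
    fractions = fractions.reshape(n_cells, 1, n_years, 2)
    valid = np.full((n_cells, 1, n_years), block_size * block_size, dtype=np.int64)
    cube = FractionCube(
        fractions=fractions,
        valid_count=valid,
        years=years,
        class_names=(class_name, complement_class),
        block_size=block_size,
        cell_area=cell_area,
        covers_legend=False,
    )
    return cube, slope * n_years
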