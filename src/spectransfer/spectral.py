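"""NDRE1 computation and plot-level zonal statistics.

The red-edge index NDRE1 = (rho_780 - rho_700) / (rho_780 + rho_700) is
computed per pixel from a NIR / red-edge band pair.  Plot polygons are
buffered inward (default 20 cm) to drop boundary pixels, and 23 statistics
are extracted per plot and date: the 21 quantiles at 5% steps (including
minimum, median and maximum), the mean and the standard deviation.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape as shapely_shape

from .raster import RasterLayer

logger = logging.getLogger(__name__)

#: Quantile probabilities: 0%, 5%, ..., 100%.
QUANTILE_LEVELS: np.ndarray = np.round(np.arange(0, 101, 5) / 100.0, 2)

#: The 23 per-plot predictor names, in canonical order.
STAT_NAMES: list[str] = [f"q{int(p * 100):03d}" for p in QUANTILE_LEVELS] + ["mean", "sd"]

DEFAULT_BUFFER_M = 0.20
DEFAULT_MIN_PIXELS = 10


@dataclass(frozen=True)
class MeasurementDate:
    """One UAV measurement date with its day of year and growth stage."""

    date: _dt.date
    doy: int
    zadoks_stage: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy {self.doy} outside 1..366")
        if self.zadoks_stage is not None and not 0 <= self.zadoks_stage <= 99:
            raise ValueError(f"Zadoks stage {self.zadoks_stage} outside 0..99")

    @classmethod
    def from_iso(cls, iso: str, zadoks_stage: int | None = None) -> "MeasurementDate":
        d = _dt.date.fromisoformat(iso)
        return cls(d, d.timetuple().tm_yday, zadoks_stage)


@dataclass
class PlotGeometry:
    """A breeding plot: polygon boundary plus trial-design attributes."""

    plot_id: str
    polygon: Polygon
    row: int
    genotype: str
    is_reference: bool = False

    @property
    def is_empty(self) -> bool:
        return self.polygon.is_empty


@dataclass
class PlotSpectralRecord:
    """The 23 NDRE1 statistics for one plot on one measurement date."""

    trial_id: str
    plot_id: str
    date: MeasurementDate
    quantiles: np.ndarray  # 21 values, non-decreasing
    mean: float
    sd: float
    n_pixels: int

    def as_series(self) -> pd.Series:
        vals = np.concatenate([self.quantiles, [self.mean, self.sd]])
        return pd.Series(vals, index=STAT_NAMES, name=self.plot_id)


def ndre1(nir: RasterLayer, red_edge: RasterLayer) -> RasterLayer:
    """Per-pixel normalized difference red edge index.

    Nodata pixels in either band propagate; pixels where NIR + RE == 0 are
    set to nodata (the ratio is undefined there).
    """
    if not nir.same_grid(red_edge):
        raise ValueError("NIR and red-edge rasters differ in shape or transform")
    valid = nir.valid_mask() & red_edge.valid_mask()
    denom = nir.values + red_edge.values
    valid &= denom != 0
    out = np.full(nir.shape, nir.nodata, dtype=float)
    np.divide(nir.values - red_edge.values, denom, out=out, where=valid)
    return RasterLayer(out, nir.transform, band_center_nm=None, nodata=nir.nodata)


def buffer_inward(plot: PlotGeometry, distance_m: float = DEFAULT_BUFFER_M) -> PlotGeometry:
    """Shrink a plot polygon inward to exclude boundary pixels.

    A buffer that swallows the whole plot yields an empty geometry (flagged
    via ``PlotGeometry.is_empty``), not an exception.  Mitred joins keep
    rectangles rectangular.
    """
    if distance_m < 0:
        raise ValueError("buffer distance must be >= 0")
    if distance_m == 0:
        return plot
    shrunk = plot.polygon.buffer(-distance_m, join_style="mitre")
    if shrunk.is_empty or shrunk.area <= 0:
        shrunk = Polygon()
    return PlotGeometry(plot.plot_id, shrunk, plot.row, plot.genotype, plot.is_reference)


def pixel_values_in_polygon(index: RasterLayer, polygon: Polygon) -> np.ndarray:
    """Valid pixel values whose centers fall inside ``polygon``.

    Membership is pixel-center-in-polygon; only the polygon's bounding box
    is scanned.
    """
    if polygon.is_empty:
        return np.empty(0)
    minx, miny, maxx, maxy = polygon.bounds
    t = index.transform
    nrow, ncol = index.shape
    # candidate index window from the bounding box (y0 is the top edge, dy < 0)
    col_lo = max(int(np.floor((minx - t.x0) / t.dx - 0.5)), 0)
    col_hi = min(int(np.ceil((maxx - t.x0) / t.dx - 0.5)) + 1, ncol)
    row_lo = max(int(np.floor((maxy - t.y0) / t.dy - 0.5)), 0)
    row_hi = min(int(np.ceil((miny - t.y0) / t.dy - 0.5)) + 1, nrow)
    if col_lo >= col_hi or row_lo >= row_hi:
        return np.empty(0)
    rows, cols = np.mgrid[row_lo:row_hi, col_lo:col_hi]
    x, y = t.pixel_center(rows, cols)
    inside = shapely.contains_xy(polygon, x.ravel(), y.ravel()).reshape(rows.shape)
    window = index.values[row_lo:row_hi, col_lo:col_hi]
    valid = np.isfinite(window) & (window != index.nodata)
    return window[inside & valid]


def stats_from_pixels(values: np.ndarray) -> pd.Series:
    """The 23 NDRE1 statistics from a 1-D pixel sample.

    Quantiles use linear interpolation between order statistics; the
    standard deviation is the sample formula (denominator n - 1).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no pixel values")
    q = np.quantile(values, QUANTILE_LEVELS, method="linear")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return pd.Series(
        np.concatenate([q, [float(values.mean()), sd]]), index=STAT_NAMES
    )


def stats_from_pixel_matrix(values: np.ndarray, index=None) -> pd.DataFrame:
    """Vectorized :func:`stats_from_pixels` for a (n_plots, n_pixels) block."""
    values = np.asarray(values, dtype=float)
    q = np.quantile(values, QUANTILE_LEVELS, axis=1).T
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(values))
    return pd.DataFrame(
        np.column_stack([q, mean, sd]), columns=STAT_NAMES, index=index
    )


def extract_plot_stats(
    index: RasterLayer,
    plots: list[PlotGeometry],
    date: MeasurementDate,
    trial_id: str = "",
    buffer_m: float = DEFAULT_BUFFER_M,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> list[PlotSpectralRecord]:
    """Zonal NDRE1 statistics for every plot on one date.

    The inward buffer is applied here so callers cannot forget it.  Plots
    whose buffered polygon covers fewer than ``min_pixels`` valid pixel
    centers are omitted (and logged), not erred on.
    """
    records: list[PlotSpectralRecord] = []
    for plot in plots:
        buffered = buffer_inward(plot, buffer_m)
        vals = pixel_values_in_polygon(index, buffered.polygon)
        if vals.size < min_pixels:
            logger.info(
                "plot %s omitted: %d valid pixels < min_pixels=%d",
                plot.plot_id, vals.size, min_pixels,
            )
            continue
        s = stats_from_pixels(vals)
        records.append(
            PlotSpectralRecord(
                trial_id=trial_id,
                plot_id=plot.plot_id,
                date=date,
                quantiles=s.iloc[:21].to_numpy(),
                mean=float(s["mean"]),
                sd=float(s["sd"]),
                n_pixels=int(vals.size),
            )
        )
    return records


def records_to_wide(records: list[PlotSpectralRecord]) -> pd.DataFrame:
    """Wide table: one row per plot, one column per statistic."""
    if not records:
        return pd.DataFrame(columns=STAT_NAMES)
    df = pd.DataFrame([r.as_series() for r in records])
    df.index.name = "plot_id"
    return df


def records_to_long(records: list[PlotSpectralRecord]) -> pd.DataFrame:
    """Long table: (trial_id, plot_id, date, stat_name, value)."""
    rows = []
    for r in records:
        s = r.as_series()
        for stat, val in s.items():
            rows.append(
                {
                    "trial_id": r.trial_id,
                    "plot_id": r.plot_id,
                    "date": r.date.date.isoformat(),
                    "stat_name": stat,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def write_plots_geojson(path, plots: list[PlotGeometry]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {
                "plot_id": p.plot_id,
                "row": p.row,
                "genotype": p.genotype,
                "is_reference": bool(p.is_reference),
            },
        }
        for p in plots
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_plots_geojson(path) -> list[PlotGeometry]:
    with open(path) as fh:
        fc = json.load(fh)
    plots = []
    for feat in fc["features"]:
        props = feat["properties"]
        plots.append(
            PlotGeometry(
                plot_id=str(props["plot_id"]),
                polygon=shapely_shape(feat["geometry"]),
                row=int(props.get("row", -1)),
                genotype=str(props.get("genotype", "")),
                is_reference=bool(props.get("is_reference", False)),
            )
        )
    return plots
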