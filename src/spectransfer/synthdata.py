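"""Synthetic multi-trial phenotyping campaigns with known ground truth.

Each trial emulates one winter-wheat breeding yard in one year at one
location: a regular grid of unreplicated plots with every fifth row sown
to a reference cultivar, plot grain yield (GY, dt/ha) as a genotype effect
plus residual noise, and per-date plot-level NDRE1 built so that its
correlation with GY tracks a prescribed seasonal signal curve rho_d.  The
construction is a linear mix on standardized variables,

    z_NDRE = rho_d * z_GY + sqrt(1 - rho_d^2) * eta,   eta ~ N(0, 1),

so corr(NDRE1, GY) = rho_d in expectation; trial-level level differences
enter through per-trial GY means and an additive NDRE1 offset.  Within-plot
pixel values are the plot mean plus i.i.d. Gaussian pixel noise.

A fraction of plots is flagged unharvested at random.  The real trials'
unharvested plots were non-random (pathogens, lodging, weak growth); that
selection process is deliberately not modelled.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .raster import DEFAULT_NODATA, GridTransform, RasterLayer
from .spectral import (
    MeasurementDate,
    PlotGeometry,
    STAT_NAMES,
    extract_plot_stats,
    ndre1,
    stats_from_pixels,
)

#: Piecewise-linear seasonal correlation between plot NDRE1 and grain yield
#: as a function of Zadoks stage: weak during tillering/stem elongation,
#: peaking at anthesis / early milk ripeness (GS 65-75), declining through
#: dough ripeness.
SIGNAL_CURVE_BY_STAGE: list[tuple[float, float]] = [
    (15, 0.10), (25, 0.20), (33, 0.35), (45, 0.55), (60, 0.80),
    (65, 0.85), (75, 0.85), (80, 0.65), (85, 0.45), (90, 0.35),
]

#: Seasonal canopy NDRE1 level: rises with canopy closure, falls with
#: senescence.
NDRE_LEVEL_BY_STAGE: list[tuple[float, float]] = [
    (15, 0.15), (25, 0.30), (33, 0.45), (45, 0.55), (60, 0.60),
    (70, 0.55), (80, 0.40), (85, 0.30), (90, 0.25),
]


def _interp_by_stage(stages, curve) -> np.ndarray:
    xs, ys = zip(*curve)
    return np.interp(np.asarray(stages, dtype=float), xs, ys)


def signal_curve_from_stages(stages, peak: float = 0.85) -> list[float]:
    """Seasonal rho_d values for a list of Zadoks stages, rescaled so the
    curve's maximum equals ``peak``."""
    rho = _interp_by_stage(stages, SIGNAL_CURVE_BY_STAGE)
    return list(rho * (peak / max(SIGNAL_CURVE_BY_STAGE, key=lambda t: t[1])[1]))


@dataclass
class TrialConfig:
    """Generating parameters for one year x location trial."""

    location_code: str
    year: int
    n_rows: int
    n_plots_per_row: int
    date_doys: list[int]
    stage_by_date: list[int]
    signal_curve: list[float]
    gy_mean: float = 85.0          # dt/ha
    gy_genotype_sd: float = 6.0    # genotypic SD, dt/ha
    gy_residual_sd: float = 4.0    # plot residual SD, dt/ha
    ndre_level_offset: float = 0.0
    ndre_sd: float = 0.06          # between-plot SD of plot-mean NDRE1
    ndre_mean_by_date: list[float] | None = None
    pixel_noise_sd: float = 0.05
    missing_harvest_frac: float = 0.0
    pixels_per_plot: int = 64
    rasterize: bool = False
    plot_width_m: float = 1.5
    plot_length_m: float = 8.0
    pixel_size_m: float = 0.05
    year_doys: list[int] | None = None  # unused; reserved
    dates_iso: list[str] | None = None  # optional calendar dates
    seed: int = 0

    def __post_init__(self) -> None:
        doys = list(self.date_doys)
        if len(set(doys)) != len(doys):
            raise ValueError("measurement-date DOYs must be unique")
        if any(b <= a for a, b in zip(doys, doys[1:])):
            raise ValueError("date_doys must be strictly increasing")
        if len(self.stage_by_date) != len(doys):
            raise ValueError("stage_by_date length must match date_doys")
        if len(self.signal_curve) != len(doys):
            raise ValueError("signal_curve length must match date_doys")
        if any(abs(r) > 1 for r in self.signal_curve):
            raise ValueError("signal correlations must lie in [-1, 1]")
        if not 0 <= self.missing_harvest_frac < 1:
            raise ValueError("missing_harvest_frac must be in [0, 1)")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if self.ndre_mean_by_date is not None and len(self.ndre_mean_by_date) != len(doys):
            raise ValueError("ndre_mean_by_date length must match date_doys")

    @property
    def trial_id(self) -> str:
        return f"{self.location_code}_{self.year % 100:02d}"

    @property
    def n_dates(self) -> int:
        return len(self.date_doys)

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.n_plots_per_row

    def dates(self) -> list[MeasurementDate]:
        out = []
        for i, doy in enumerate(self.date_doys):
            if self.dates_iso is not None:
                d = _dt.date.fromisoformat(self.dates_iso[i])
            else:
                d = _dt.date(self.year, 1, 1) + _dt.timedelta(days=int(doy) - 1)
            out.append(MeasurementDate(d, int(doy), int(self.stage_by_date[i])))
        return out


@dataclass
class TrialDataset:
    """One generated trial: geometry, yields and per-date NDRE1 pixels."""

    trial_id: str
    location_code: str
    year: int
    plots: list[PlotGeometry]
    dates: list[MeasurementDate]
    yield_table: pd.DataFrame  # plot_id, gy_dt_ha, harvested
    plot_ndre_mean: np.ndarray  # (n_dates, n_plots) true plot means
    pixel_values: list[np.ndarray]  # per date, (n_plots, pixels_per_plot)
    rasters: list[tuple[RasterLayer, RasterLayer]] | None = None
    truth: dict = field(default_factory=dict)

    @property
    def plot_ids(self) -> list[str]:
        return [p.plot_id for p in self.plots]

    def stats_wide(self, date_index: int, **extract_kw) -> pd.DataFrame:
        """23 NDRE1 statistics per plot for one date.

        Uses the raster extraction path when rasters were rendered,
        otherwise computes the statistics from the stored pixel samples.
        """
        if self.rasters is not None:
            nir, re = self.rasters[date_index]
            recs = extract_plot_stats(
                ndre1(nir, re), self.plots, self.dates[date_index],
                trial_id=self.trial_id, **extract_kw,
            )
            from .spectral import records_to_wide

            return records_to_wide(recs)
        from .spectral import stats_from_pixel_matrix

        return stats_from_pixel_matrix(
            self.pixel_values[date_index],
            index=pd.Index(self.plot_ids, name="plot_id"),
        )


def _plot_grid(config: TrialConfig) -> list[PlotGeometry]:
    """Axis-aligned rectangular plots on a regular grid; reference-cultivar
    rows are 1-based rows 1, 6, 11, ... ("every fifth trial row")."""
    plots = []
    w, L = config.plot_width_m, config.plot_length_m
    ref_counter = 0
    for r in range(1, config.n_rows + 1):
        is_ref_row = (r - 1) % 5 == 0
        if is_ref_row:
            ref_genotype = f"REF_{'AB'[ref_counter % 2]}"
            ref_counter += 1
        for c in range(config.n_plots_per_row):
            x0, y0 = c * w, (r - 1) * L
            poly = Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + L), (x0, y0 + L)])
            genotype = ref_genotype if is_ref_row else f"G_r{r:03d}c{c:03d}"
            plots.append(
                PlotGeometry(
                    plot_id=f"{config.trial_id}_r{r:03d}c{c:03d}",
                    polygon=poly,
                    row=r,
                    genotype=genotype,
                    is_reference=is_ref_row,
                )
            )
    return plots


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent stream for (seed, key): fixed offsets so adding dates
    does not perturb earlier dates."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _render_rasters(config: TrialConfig, plots, plot_means, seed) -> list[tuple[RasterLayer, RasterLayer]]:
    """Full two-band rasters: per-pixel NDRE1 = plot mean + noise, mapped to
    a (NIR, RE) pair of constant total reflectance 0.8."""
    px = config.pixel_size_m
    width = config.n_plots_per_row * config.plot_width_m
    height = config.n_rows * config.plot_length_m
    ncol = int(round(width / px))
    nrow = int(round(height / px))
    transform = GridTransform(0.0, height, px, -px)
    xs, ys = transform.center_grids((nrow, ncol))
    rasters = []
    total = 0.8  # NIR + RE reflectance per pixel
    for d in range(config.n_dates):
        rng = _rng(seed, 3, d)
        v = np.full((nrow, ncol), DEFAULT_NODATA)
        for i, plot in enumerate(plots):
            minx, miny, maxx, maxy = plot.polygon.bounds
            sel = (xs >= minx) & (xs < maxx) & (ys >= miny) & (ys < maxy)
            n_px = int(sel.sum())
            vals = plot_means[d, i] + rng.normal(0.0, config.pixel_noise_sd, n_px)
            v[sel] = np.clip(vals, -1.0, 1.0)
        valid = v != DEFAULT_NODATA
        nir_v = np.full_like(v, DEFAULT_NODATA)
        re_v = np.full_like(v, DEFAULT_NODATA)
        nir_v[valid] = total * (1 + v[valid]) / 2
        re_v[valid] = total * (1 - v[valid]) / 2
        rasters.append(
            (
                RasterLayer(nir_v, transform, 780),
                RasterLayer(re_v, transform, 700),
            )
        )
    return rasters


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Generate one trial; identical config (incl. seed) => identical data."""
    plots = _plot_grid(config)
    n = len(plots)
    dates = config.dates()

    # genotype effects: one draw per genotype (references shared across rows)
    genotypes = [p.genotype for p in plots]
    uniq = list(dict.fromkeys(genotypes))
    g_draw = _rng(config.seed, 0).normal(0.0, config.gy_genotype_sd, len(uniq))
    g_by_geno = dict(zip(uniq, g_draw))
    eps = _rng(config.seed, 1).normal(0.0, config.gy_residual_sd, n)
    gy = config.gy_mean + np.array([g_by_geno[g] for g in genotypes]) + eps
    z_gy = (gy - gy.mean()) / gy.std()

    if config.ndre_mean_by_date is not None:
        mu_d = np.asarray(config.ndre_mean_by_date, dtype=float)
    else:
        mu_d = _interp_by_stage(config.stage_by_date, NDRE_LEVEL_BY_STAGE)

    plot_means = np.empty((config.n_dates, n))
    n_clip_risky = 0
    for d in range(config.n_dates):
        rho = float(config.signal_curve[d])
        eta = _rng(config.seed, 2, d).standard_normal(n)
        z = rho * z_gy + np.sqrt(1.0 - rho**2) * eta
        m = mu_d[d] + config.ndre_sd * z + config.ndre_level_offset
        n_clip_risky += int(np.sum(np.abs(m) + 3 * config.pixel_noise_sd > 1))
        plot_means[d] = np.clip(m, -1.0, 1.0)
    if n_clip_risky > 0.01 * n * config.n_dates:
        warnings.warn(
            "NDRE1 clipping risk: >1% of plot means within 3 pixel-noise SDs "
            "of the [-1, 1] bounds; target correlations may be attenuated",
            stacklevel=2,
        )

    pixel_values = []
    for d in range(config.n_dates):
        noise = _rng(config.seed, 4, d).normal(
            0.0, config.pixel_noise_sd, (n, config.pixels_per_plot)
        )
        pixel_values.append(np.clip(plot_means[d][:, None] + noise, -1.0, 1.0))

    harvested = _rng(config.seed, 5).random(n) >= config.missing_harvest_frac
    yield_table = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "gy_dt_ha": gy,
            "harvested": harvested,
        }
    )

    rasters = _render_rasters(config, plots, plot_means, config.seed) if config.rasterize else None
    return TrialDataset(
        trial_id=config.trial_id,
        location_code=config.location_code,
        year=config.year,
        plots=plots,
        dates=dates,
        yield_table=yield_table,
        plot_ndre_mean=plot_means,
        pixel_values=pixel_values,
        rasters=rasters,
        truth={"config": config, "gy": gy, "genotype_effects": g_by_geno},
    )


def generate_campaign(configs: list[TrialConfig]) -> list[TrialDataset]:
    """Generate independent trials; duplicate trial ids are an error."""
    ids = [c.trial_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate trial ids in campaign: {sorted(ids)}")
    return [generate_trial(c) for c in configs]


# ---------------------------------------------------------------------------
# The six-trial study layout: 2 locations x 3 years, with the printed UAV
# measurement dates and growth stages, harvested-plot fractions from the
# reported plot counts, and trial-level GY / NDRE1 level differences
# (drought years 2020/2022 lower-yielding than the favourable 2021; the MR
# site out-yielding HZ).
# ---------------------------------------------------------------------------

STUDY_TRIALS: dict[str, dict] = {
    "MR_20": {
        "location": "MR", "year": 2020,
        "dates": [("2020-04-01", 25), ("2020-04-23", 30), ("2020-05-08", 33),
                  ("2020-05-19", 43), ("2020-05-27", 65), ("2020-06-08", 72),
                  ("2020-06-24", 75), ("2020-07-09", 83)],
        "missing_frac": 0.103, "gy_mean": 86.0, "ndre_level_offset": 0.03,
    },
    "HZ_20": {
        "location": "HZ", "year": 2020,
        "dates": [("2020-03-26", 25), ("2020-04-09", 30), ("2020-05-06", 33),
                  ("2020-05-20", 43), ("2020-05-29", 65), ("2020-06-08", 75),
                  ("2020-06-19", 81), ("2020-06-26", 84), ("2020-07-26", 85)],
        "missing_frac": 0.117, "gy_mean": 78.0, "ndre_level_offset": 0.0,
    },
    "MR_21": {
        "location": "MR", "year": 2021,
        "dates": [("2021-03-24", 24), ("2021-04-20", 30), ("2021-04-28", 31),
                  ("2021-06-03", 63), ("2021-06-17", 72), ("2021-07-06", 79),
                  ("2021-07-20", 85)],
        "missing_frac": 0.233, "gy_mean": 101.0, "ndre_level_offset": 0.04,
    },
    "HZ_21": {
        "location": "HZ", "year": 2021,
        "dates": [("2021-03-25", 22), ("2021-04-15", 27), ("2021-04-30", 33),
                  ("2021-05-14", 37), ("2021-06-08", 57), ("2021-07-13", 85)],
        "missing_frac": 0.244, "gy_mean": 92.0, "ndre_level_offset": -0.02,
    },
    "MR_22": {
        "location": "MR", "year": 2022,
        "dates": [("2022-03-03", 21), ("2022-03-18", 22), ("2022-03-30", 25),
                  ("2022-04-12", 27), ("2022-04-26", 29), ("2022-05-05", 33),
                  ("2022-05-19", 37), ("2022-06-09", 67)],
        "missing_frac": 0.355, "gy_mean": 84.0, "ndre_level_offset": 0.02,
    },
    "HZ_22": {
        "location": "HZ", "year": 2022,
        "dates": [("2022-03-03", 21), ("2022-03-23", 22), ("2022-03-31", 25),
                  ("2022-04-13", 27), ("2022-04-22", 31), ("2022-05-03", 33),
                  ("2022-05-12", 35), ("2022-05-25", 37), ("2022-06-02", 63),
                  ("2022-06-09", 67), ("2022-06-15", 71), ("2022-06-28", 79),
                  ("2022-07-18", 85)],
        "missing_frac": 0.324, "gy_mean": 74.0, "ndre_level_offset": -0.04,
    },
}


def study_campaign_configs(
    seed: int = 1,
    n_rows: int = 12,
    n_plots_per_row: int = 16,
    peak_rho: float = 0.85,
    **overrides,
) -> list[TrialConfig]:
    """TrialConfigs for the six-trial 2-location x 3-year study layout.

    Plot counts default to a desk-scale 12 x 16 grid per trial; per-trial
    seeds are derived deterministically from ``seed``.
    """
    configs = []
    for i, (trial_id, spec) in enumerate(STUDY_TRIALS.items()):
        iso_dates = [d for d, _ in spec["dates"]]
        stages = [s for _, s in spec["dates"]]
        doys = [_dt.date.fromisoformat(d).timetuple().tm_yday for d in iso_dates]
        trial_seed = int(
            np.random.SeedSequence((int(seed), i)).generate_state(1, np.uint32)[0] % (2**31)
        )
        configs.append(
            TrialConfig(
                location_code=spec["location"],
                year=spec["year"],
                n_rows=n_rows,
                n_plots_per_row=n_plots_per_row,
                date_doys=doys,
                stage_by_date=stages,
                signal_curve=signal_curve_from_stages(stages, peak=peak_rho),
                gy_mean=spec["gy_mean"],
                ndre_level_offset=spec["ndre_level_offset"],
                missing_harvest_frac=spec["missing_frac"],
                dates_iso=iso_dates,
                seed=trial_seed,
                **overrides,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Config file and on-disk writers
# ---------------------------------------------------------------------------

def load_campaign_config(path) -> list[TrialConfig]:
    """Read a YAML file holding a list of TrialConfig blocks under `trials`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = doc["trials"] if isinstance(doc, dict) else doc
    return [TrialConfig(**b) for b in blocks]


def write_trial(dataset: TrialDataset, out_dir) -> None:
    """Write a trial's plot polygons, yields, dates (and rasters if present)."""
    from pathlib import Path

    from .raster import write_raster_pair
    from .spectral import write_plots_geojson

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_plots_geojson(out / f"{dataset.trial_id}_plots.geojson", dataset.plots)
    yt = dataset.yield_table.copy()
    yt.loc[~yt["harvested"], "gy_dt_ha"] = np.nan
    yt.to_csv(out / f"{dataset.trial_id}_yield.csv", index=False)
    pd.DataFrame(
        {
            "trial_id": dataset.trial_id,
            "date": [d.date.isoformat() for d in dataset.dates],
            "doy": [d.doy for d in dataset.dates],
            "zadoks_stage": [d.zadoks_stage for d in dataset.dates],
        }
    ).to_csv(out / f"{dataset.trial_id}_dates.csv", index=False)
    if dataset.rasters is not None:
        for date, (nir, re) in zip(dataset.dates, dataset.rasters):
            write_raster_pair(
                out / f"{dataset.trial_id}_{date.date.isoformat()}.tif", nir, re
            )
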