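"""Synthetic study area with known latent structure.

Generates every input the pipeline consumes — commune polygons, daily
surface-temperature rasters, a CORINE-coded land-cover raster, the
four-component socioeconomic table, air-conditioning equipment rates,
and emergency visit records — from a small set of latent quantities
(an urban-heat-island gradient, a one-factor deprivation model, Poisson
visit counts rising with true vulnerability).  The latents are returned
alongside the data so downstream stages can be tested against ground
truth; columns marked ``true_`` or ``latent_`` are test-only and exist
in no real data source.

Every generator draws from its own stream seeded by (seed,
generator-name), so adding a generator never perturbs the others and a
fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import datetime
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .core import (
    AdminUnit,
    AdminUnitSet,
    DEFAULT_WORKING_CRS,
    IndicatorColumn,
    RasterGrid,
    VisitRecord,
    write_raster,
    write_units,
)
from .errors import ConfigError, ResolutionError
from .icanicule import VisitRecordSet
from .zonal import assign_pixels

#: Mean commune area in metropolitan France is 14.9 km²; a square of
#: side √14.9 km reproduces it exactly.
NATIONAL_MEAN_AREA_KM2 = 14.9
DEFAULT_CELL_KM = math.sqrt(NATIONAL_MEAN_AREA_KM2)

DEFAULT_CAUSE_CODES = ("T67.0", "T67.9", "E86.0", "E87.1")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study area.

    Defaults describe a plausible southern-France summer: a 10×10 grid
    of mean-area communes, a ~5 °C urban-heat-island amplitude on a
    24 °C June–August baseline, one-factor deprivation with loadings
    (+, +, −, −) for unemployment / blue-collar / graduates / income,
    AC uptake rising with local temperature, and a baseline of 20
    heat-related emergency visits per 10 000 residents per season.
    """

    n_side: int = 10
    cell_km: float = DEFAULT_CELL_KM
    uhi_coeff: float = 5.0          # °C per unit artificial fraction
    base_temp_c: float = 24.0       # seasonal baseline, °C
    noise_sd_c: float = 0.5         # per-pixel temperature noise, °C
    n_days: int = 3                 # daily rasters to emit
    day_sd_c: float = 1.5           # day-to-day offset SD, °C
    pixel_m: float = 200.0          # raster resolution, metres
    artificial_jitter: float = 0.02  # uniform jitter on urban fractions
    fdep_loadings: tuple[float, float, float, float] = (1.0, 1.0, -1.0, -1.0)
    socio_noise_sd: float = 0.5     # component noise on the latent scale
    ac_intercept: float = 15.0      # % equipped at baseline temperature
    ac_slope: float = 4.0           # % per °C above baseline
    ac_noise_sd: float = 2.0        # % noise on AC rates
    visit_base_rate: float = 20.0   # expected visits per 10 000 per season
    visit_effect: float = 0.5       # log-rate increase per vulnerability SD
    cause_codes: tuple[str, ...] = DEFAULT_CAUSE_CODES
    season_start: datetime.date = datetime.date(2022, 6, 1)
    season_end: datetime.date = datetime.date(2022, 8, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_side < 2:
            raise ConfigError("n_side must be >= 2")
        if self.cell_km <= 0:
            raise ConfigError("cell_km must be > 0")
        if self.noise_sd_c < 0:
            raise ConfigError("noise_sd_c must be >= 0")
        if self.visit_base_rate < 0:
            raise ConfigError("visit_base_rate must be >= 0")


def _rng(cfg: SynthConfig, name: str) -> np.random.Generator:
    """Stream seeded by (seed, generator-name); stable across versions."""
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFF_FFFF
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


# origin of the synthetic grid in the working projection (metres);
# near the Lambert-93 false origin so coordinates look like real ones
GRID_ORIGIN_X = 700_000.0
GRID_ORIGIN_Y = 6_600_000.0


def make_commune_grid(cfg: SynthConfig) -> AdminUnitSet:
    """Square communes tiling an n_side × n_side block.

    Departments are assigned in quadrant blocks; populations are
    log-normal (median 2 000), mimicking the long right tail of French
    commune sizes.  unit_id carries leading zeros, like real commune
    codes.
    """
    rng = _rng(cfg, "commune_grid")
    cell_m = cfg.cell_km * 1000.0
    block = max(1, math.ceil(cfg.n_side / 2))
    n_blocks_per_row = math.ceil(cfg.n_side / block)
    units = []
    populations = rng.lognormal(mean=math.log(2000.0), sigma=1.0,
                                size=cfg.n_side * cfg.n_side)
    for r in range(cfg.n_side):
        for c in range(cfg.n_side):
            dept_num = (r // block) * n_blocks_per_row + (c // block) + 1
            serial = r * cfg.n_side + c + 1
            x0 = GRID_ORIGIN_X + c * cell_m
            y1 = GRID_ORIGIN_Y - r * cell_m
            geom = shapely.box(x0, y1 - cell_m, x0 + cell_m, y1)
            units.append(
                AdminUnit(
                    unit_id=f"{dept_num:02d}{serial:03d}",
                    name=f"Commune {serial}",
                    department_id=f"D{dept_num:02d}",
                    geometry=geom,
                    population=float(round(populations[serial - 1])),
                    area_km2=geom.area / 1e6,
                )
            )
    return AdminUnitSet(units, DEFAULT_WORKING_CRS)


def make_true_artificial(
    cfg: SynthConfig, units: AdminUnitSet
) -> dict[str, float]:
    """Radially decreasing urban fraction: ≈0.9 at the grid centre,
    ≈0.05 at the corners, with small seeded jitter, clipped to [0, 1]."""
    rng = _rng(cfg, "true_artificial")
    cell_m = cfg.cell_km * 1000.0
    cx = GRID_ORIGIN_X + cfg.n_side * cell_m / 2.0
    cy = GRID_ORIGIN_Y - cfg.n_side * cell_m / 2.0
    dmax = math.hypot(cfg.n_side * cell_m / 2.0, cfg.n_side * cell_m / 2.0)
    out = {}
    for u in units:
        p = u.geometry.centroid
        d = math.hypot(p.x - cx, p.y - cy)
        base = 0.05 + (0.9 - 0.05) * max(0.0, 1.0 - d / dmax)
        jitter = rng.uniform(-cfg.artificial_jitter, cfg.artificial_jitter)
        out[u.unit_id] = float(np.clip(base + jitter, 0.0, 1.0))
    return out


def _grid_raster_shape(cfg: SynthConfig) -> tuple[int, int]:
    side_m = cfg.n_side * cfg.cell_km * 1000.0
    n = math.ceil(side_m / cfg.pixel_m - 1e-9)
    return n, n


def _empty_grid(cfg: SynthConfig, semantics: str, nodata: float,
                dtype) -> RasterGrid:
    n_rows, n_cols = _grid_raster_shape(cfg)
    return RasterGrid(
        origin_x=GRID_ORIGIN_X,
        origin_y=GRID_ORIGIN_Y,
        pixel_size=cfg.pixel_m,
        values=np.full((n_rows, n_cols), nodata, dtype=dtype),
        nodata=nodata,
        crs_id=DEFAULT_WORKING_CRS,
        semantics=semantics,  # type: ignore[arg-type]
    )


ARTIFICIAL_CODE = 112  # discontinuous urban fabric
VEGETATED_CODE = 311   # broad-leaved forest


def make_landcover_raster(
    cfg: SynthConfig,
    units: AdminUnitSet,
    true_artificial: dict[str, float],
) -> RasterGrid:
    """Land-cover raster realising each commune's artificial fraction.

    Within each commune, round(fraction × n_pixels) pixels get an
    artificial code and the rest a vegetated code, so the realised
    fraction matches the target within one pixel's worth.
    """
    if cfg.pixel_m > cfg.cell_km * 1000.0:
        raise ResolutionError(
            f"pixel size {cfg.pixel_m} m exceeds commune side "
            f"{cfg.cell_km * 1000.0} m"
        )
    rng = _rng(cfg, "landcover")
    grid = _empty_grid(cfg, "landcover_code", nodata=-1, dtype=np.int64)
    assignment = assign_pixels(grid, units)
    flat = np.full(grid.n_rows * grid.n_cols, grid.nodata, dtype=np.int64)
    idx = assignment.unit_index.ravel()
    for i, uid in enumerate(assignment.unit_ids):
        pix = np.flatnonzero(idx == i)
        if pix.size == 0:
            continue
        n_art = int(round(true_artificial[uid] * pix.size))
        chosen = rng.permutation(pix)[:n_art]
        flat[pix] = VEGETATED_CODE
        flat[chosen] = ARTIFICIAL_CODE
    grid.values = flat.reshape(grid.n_rows, grid.n_cols)
    return grid


def true_zonal_temperature(
    cfg: SynthConfig, true_artificial: dict[str, float]
) -> dict[str, float]:
    """Noise-free expected commune temperature: base + uhi × fraction."""
    return {
        uid: cfg.base_temp_c + cfg.uhi_coeff * f
        for uid, f in true_artificial.items()
    }


def make_temperature_raster(
    cfg: SynthConfig,
    units: AdminUnitSet,
    true_artificial: dict[str, float],
    day_offset_c: float = 0.0,
    stream: str = "temperature",
) -> RasterGrid:
    """One temperature raster: base + UHI term + Gaussian pixel noise."""
    rng = _rng(cfg, stream)
    grid = _empty_grid(cfg, "temperature_celsius", nodata=-9999.0,
                       dtype=np.float64)
    assignment = assign_pixels(grid, units)
    idx = assignment.unit_index.ravel()
    frac = np.array(
        [true_artificial[uid] for uid in assignment.unit_ids]
    )
    flat = np.full(idx.shape, grid.nodata)
    inside = idx >= 0
    flat[inside] = (
        cfg.base_temp_c
        + day_offset_c
        + cfg.uhi_coeff * frac[idx[inside]]
    )
    if cfg.noise_sd_c > 0:
        flat[inside] += rng.normal(0.0, cfg.noise_sd_c, size=int(inside.sum()))
    grid.values = flat.reshape(grid.n_rows, grid.n_cols)
    return grid


def make_daily_temperature_rasters(
    cfg: SynthConfig,
    units: AdminUnitSet,
    true_artificial: dict[str, float],
) -> list[RasterGrid]:
    """n_days rasters sharing the UHI field, with day-to-day offsets."""
    rng = _rng(cfg, "day_offsets")
    offsets = rng.normal(0.0, cfg.day_sd_c, size=cfg.n_days)
    return [
        make_temperature_raster(
            cfg, units, true_artificial,
            day_offset_c=float(offsets[d]), stream=f"temperature_day{d}",
        )
        for d in range(cfg.n_days)
    ]


def make_socioeconomic_table(
    cfg: SynthConfig, units: AdminUnitSet
) -> pd.DataFrame:
    """One-factor socioeconomic table.

    A latent deprivation factor d_i ~ N(0, 1) drives all four
    components through the configured loadings plus N(0, socio_noise_sd)
    noise; the standardised components are then mapped affinely onto
    realistic scales (percentages, euros) so correlations with the
    latent are untouched.  The latent is returned in column
    ``latent_deprivation`` — test-only, present in no real source.
    """
    rng = _rng(cfg, "socio")
    ids = units.unit_ids
    n = len(ids)
    d = rng.standard_normal(n)
    lu, lb, lg, li = cfg.fdep_loadings
    noise = rng.normal(0.0, cfg.socio_noise_sd, size=(n, 4))
    raw = np.column_stack([lu * d, lb * d, lg * d, li * d]) + noise
    # affine maps to realistic scales (correlation-preserving); slopes are
    # small enough that clipping is never reached in practice
    unemployment = np.clip(10.0 + 1.5 * raw[:, 0], 0.0, 100.0)
    blue_collar = np.clip(25.0 + 4.0 * raw[:, 1], 0.0, 100.0)
    graduates = np.clip(45.0 + 6.0 * raw[:, 2], 0.0, 100.0)
    income = np.maximum(21_000.0 + 2_500.0 * raw[:, 3], 1_000.0)
    return pd.DataFrame(
        {
            "unemployment_rate": unemployment,
            "blue_collar_pct": blue_collar,
            "graduates_pct": graduates,
            "median_income": income,
            "latent_deprivation": d,
        },
        index=pd.Index(ids, name="unit_id"),
    )


def make_ac_rates(
    cfg: SynthConfig,
    units: AdminUnitSet,
    zonal_temp: dict[str, float],
) -> dict[str, float]:
    """AC equipment rate (% of primary residences), rising with local
    temperature: clip(intercept + slope × (T − base), 0, 100) + noise,
    re-clipped to [0, 100]."""
    rng = _rng(cfg, "ac_rates")
    out = {}
    for uid in units.unit_ids:
        rate = np.clip(
            cfg.ac_intercept + cfg.ac_slope * (zonal_temp[uid] - cfg.base_temp_c),
            0.0,
            100.0,
        )
        if cfg.ac_noise_sd > 0:
            rate = np.clip(rate + rng.normal(0.0, cfg.ac_noise_sd), 0.0, 100.0)
        out[uid] = float(rate)
    return out


def _standardise(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    return (values - values.mean()) / sd if sd > 0 else values - values.mean()


def make_true_vulnerability(
    cfg: SynthConfig,
    units: AdminUnitSet,
    true_artificial: dict[str, float],
    latent_deprivation: pd.Series,
) -> dict[str, float]:
    """Ground-truth vulnerability from the noise-free latents.

    Mirrors the index formula on the latent scale: standardised
    (temperature, deprivation, artificial fraction, −AC rate)/4.
    """
    ids = units.unit_ids
    temp = np.array([true_zonal_temperature(cfg, true_artificial)[u] for u in ids])
    frac = np.array([true_artificial[u] for u in ids])
    dep = latent_deprivation.loc[ids].to_numpy(dtype=float)
    ac = np.clip(
        cfg.ac_intercept + cfg.ac_slope * (temp - cfg.base_temp_c), 0.0, 100.0
    )
    v = (
        _standardise(temp) + _standardise(dep) + _standardise(frac)
        - _standardise(ac)
    ) / 4.0
    v = _standardise(v)
    return dict(zip(ids, v.astype(float)))


def make_visit_records(
    cfg: SynthConfig,
    units: AdminUnitSet,
    true_vulnerability: dict[str, float],
) -> VisitRecordSet:
    """Poisson visit counts rising with true vulnerability.

    Per unit: count ~ Poisson(pop/10 000 × base_rate ×
    exp(effect × vulnerability)).  Each visit gets a cause code drawn
    uniformly from the configured heat-cause set, source ED/GP with
    probability 0.7/0.3, and a date uniform over the summer window.
    """
    rng = _rng(cfg, "visits")
    n_days = (cfg.season_end - cfg.season_start).days + 1
    records: list[VisitRecord] = []
    for u in units:
        lam = (
            u.population / 10_000.0
            * cfg.visit_base_rate
            * math.exp(cfg.visit_effect * true_vulnerability[u.unit_id])
        )
        count = int(rng.poisson(lam)) if lam > 0 else 0
        if count == 0:
            continue
        days = rng.integers(0, n_days, size=count)
        codes = rng.choice(len(cfg.cause_codes), size=count)
        is_ed = rng.random(count) < 0.7
        for k in range(count):
            records.append(
                VisitRecord(
                    unit_id=u.unit_id,
                    date=cfg.season_start + datetime.timedelta(days=int(days[k])),
                    source="emergency_department" if is_ed[k] else "emergency_gp",
                    cause_code=cfg.cause_codes[int(codes[k])],
                )
            )
    return VisitRecordSet(records)


@dataclass
class SynthBundle:
    """Everything the pipeline needs, plus the test-only ground truth."""

    config: SynthConfig
    units: AdminUnitSet
    true_artificial: dict[str, float]
    landcover: RasterGrid
    daily_temperature: list[RasterGrid]
    socio: pd.DataFrame                  # includes latent_deprivation (test-only)
    ac_rates: dict[str, float]
    true_vulnerability: dict[str, float]
    visits: VisitRecordSet

    def ac_column(self) -> IndicatorColumn:
        return IndicatorColumn(
            name="ac_rate",
            values=dict(self.ac_rates),
            orientation="protective",
            units_label="%",
        )


def generate(cfg: SynthConfig) -> SynthBundle:
    """Run every generator in a fixed order under one config."""
    units = make_commune_grid(cfg)
    frac = make_true_artificial(cfg, units)
    landcover = make_landcover_raster(cfg, units, frac)
    daily = make_daily_temperature_rasters(cfg, units, frac)
    socio = make_socioeconomic_table(cfg, units)
    zonal_true = true_zonal_temperature(cfg, frac)
    ac = make_ac_rates(cfg, units, zonal_true)
    vuln = make_true_vulnerability(cfg, units, frac, socio["latent_deprivation"])
    visits = make_visit_records(cfg, units, vuln)
    return SynthBundle(
        config=cfg,
        units=units,
        true_artificial=frac,
        landcover=landcover,
        daily_temperature=daily,
        socio=socio,
        ac_rates=ac,
        true_vulnerability=vuln,
        visits=visits,
    )


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the formats the pipeline reads.

    The socioeconomic CSV keeps only the four real-world columns; the
    latents go to a separate, clearly test-only file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["units"] = outdir / "units.geojson"
    write_units(bundle.units, paths["units"])

    paths["landcover"] = outdir / "landcover.tif"
    write_raster(bundle.landcover, paths["landcover"])

    temp_paths = []
    for d, raster in enumerate(bundle.daily_temperature):
        p = outdir / f"temperature_day{d:02d}.tif"
        write_raster(raster, p)
        temp_paths.append(p)
    paths["temperature"] = temp_paths  # type: ignore[assignment]

    paths["socio"] = outdir / "socio.csv"
    bundle.socio.drop(columns=["latent_deprivation"]).to_csv(paths["socio"])

    paths["ac"] = outdir / "ac_rates.csv"
    pd.DataFrame(
        {"unit_id": list(bundle.ac_rates), "ac_rate_pct": list(bundle.ac_rates.values())}
    ).to_csv(paths["ac"], index=False)

    paths["visits"] = outdir / "visits.csv"
    bundle.visits.to_csv(paths["visits"])

    paths["truth"] = outdir / "synthetic_truth.csv"
    truth = pd.DataFrame(
        {
            "unit_id": bundle.units.unit_ids,
            "true_artificial": [
                bundle.true_artificial[u] for u in bundle.units.unit_ids
            ],
            "latent_deprivation": bundle.socio["latent_deprivation"].loc[
                bundle.units.unit_ids
            ].to_numpy(),
            "true_vulnerability": [
                bundle.true_vulnerability[u] for u in bundle.units.unit_ids
            ],
        }
    )
    truth.to_csv(paths["truth"], index=False)
    return paths
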