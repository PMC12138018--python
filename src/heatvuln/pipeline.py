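"""One-command orchestration: raw layers (or synthetic fixtures) to the
scored, classed geodata product, with a run manifest.

Stage order: temporal mean of daily rasters → zonal temperature,
land-cover exposed fraction, deprivation score, AC ingest → z-scores →
imputation → composite index → quantile classes → heat-morbidity
aggregation.  Every run emits a manifest (config echo, per-stage
counts, warnings, output checksums) whether it succeeds or fails.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    AdminUnitSet,
    IndicatorColumn,
    read_raster,
    read_units,
    validate_alignment,
)
from .deprivation import fdep_score, read_socio_table
from .errors import ConfigError, HeatvulnError, SchemaError
from .icanicule import (
    CauseMap,
    VisitRecordSet,
    aggregate_indicator,
    filter_heat_visits,
    indicator_frame,
    read_cause_map,
)
from .landcover import default_grouping, read_grouping, unit_exposed_fraction
from .vindex import (
    ImputationPolicy,
    composite_index,
    quantile_classes,
    scores_frame,
    zscore,
)
from .zonal import assign_pixels, temporal_mean, zonal_mean_temperature

log = logging.getLogger("heatvuln")


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    units_path: Path
    temperature_paths: list[Path]
    landcover_path: Path
    socio_path: Path
    ac_path: Path
    outdir: Path
    grouping_path: Path | None = None
    causes_path: Path | None = None
    impute_mode: str = "department_median"
    k_classes: int = 5
    window: tuple[datetime.date, datetime.date] = (
        datetime.date(2022, 6, 1),
        datetime.date(2022, 8, 31),
    )
    visits_path: Path | None = None
    working_crs: str = "EPSG:2154"

    def validate(self) -> None:
        if self.k_classes < 2:
            raise ConfigError("k_classes must be >= 2")
        named = {
            "units": self.units_path,
            "landcover": self.landcover_path,
            "socio": self.socio_path,
            "ac": self.ac_path,
        }
        for label, p in named.items():
            if p is None:
                raise ConfigError(f"missing input layer: {label}")
            if not Path(p).exists():
                raise ConfigError(f"{label} input does not exist: {p}")
        if not self.temperature_paths:
            raise ConfigError("missing input layer: temperature rasters")
        for p in self.temperature_paths:
            if not Path(p).exists():
                raise ConfigError(f"temperature raster does not exist: {p}")
        if self.visits_path is not None and not Path(self.visits_path).exists():
            raise ConfigError(f"visits input does not exist: {self.visits_path}")


@dataclass
class RunManifest:
    """Accounting record of one run, emitted on success or failure."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts
        log.info("stage %s: %s", stage, counts)

    def checksum(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.checksums[Path(path).name] = digest

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def read_ac_rates(path: str | Path) -> IndicatorColumn:
    """Read the per-unit AC equipment CSV (% of primary residences)."""
    df = pd.read_csv(path, dtype={"unit_id": str})
    for col in ("unit_id", "ac_rate_pct"):
        if col not in df.columns:
            raise SchemaError(f"AC table missing column {col!r}")
    vals = df.set_index("unit_id")["ac_rate_pct"]
    present = vals.dropna()
    if ((present < 0) | (present > 100)).any():
        raise SchemaError("ac_rate_pct must lie in [0, 100]")
    return IndicatorColumn(
        name="ac_rate",
        values={u: float(v) for u, v in present.items()},
        orientation="protective",
        missing=set(vals.index[vals.isna()]),
        units_label="%",
    )


@dataclass
class RunResult:
    units: AdminUnitSet
    scores: pd.DataFrame
    morbidity: pd.DataFrame | None
    manifest: RunManifest
    outputs: dict[str, Path]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float format keeps re-runs byte-identical
    df.to_csv(path, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the output bundle.

    Outputs: ``scores.csv``, ``scores.geojson`` (index + morbidity
    attributes on the unit polygons), ``icanicule.csv`` when visit data
    is configured, and ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            k: str(v) for k, v in dataclasses.asdict(config).items()
        }
    )
    stage = "read_units"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = _run_stages(config, manifest, outdir)
        manifest.warnings.extend(str(w.message) for w in caught)
        manifest.write(outdir / "manifest.json")
        return result
    except HeatvulnError as exc:
        manifest.failed_stage = manifest.stages.get("_current", {}).get(
            "name", stage
        )
        manifest.error = str(exc)
        manifest.write(outdir / "manifest.json")
        raise


def _run_stages(
    config: RunConfig, manifest: RunManifest, outdir: Path
) -> RunResult:
    def current(name: str) -> None:
        manifest.stages["_current"] = {"name": name}

    current("read_units")
    units = read_units(config.units_path, working_crs=config.working_crs)
    manifest.record("read_units", n_units=len(units))

    current("temporal_mean")
    dailies = [read_raster(p, "temperature_celsius") for p in config.temperature_paths]
    mean_raster = temporal_mean(dailies)
    manifest.record("temporal_mean", n_days=len(dailies))

    current("alignment")
    report = validate_alignment(mean_raster, units)
    if not report.ok:
        raise SchemaError(
            f"raster covers only {report.coverage_fraction:.1%} of unit area; "
            f"uncovered: {report.uncovered_unit_ids[:10]}"
        )
    manifest.record("alignment", coverage=report.coverage_fraction)

    current("zonal_temperature")
    assignment = assign_pixels(mean_raster, units)
    temp = zonal_mean_temperature(mean_raster, units, assignment)
    manifest.record(
        "zonal_temperature",
        n_scored=len(temp.values),
        n_missing=len(temp.missing),
        n_unassigned_pixels=assignment.n_unassigned,
    )

    current("landcover")
    lc_raster = read_raster(config.landcover_path, "landcover_code")
    grouping = (
        read_grouping(config.grouping_path)
        if config.grouping_path
        else default_grouping()
    )
    lc_assignment = (
        assignment
        if mean_raster.same_grid(lc_raster)
        else assign_pixels(lc_raster, units)
    )
    artif = unit_exposed_fraction(lc_raster, units, grouping, lc_assignment)
    manifest.record(
        "landcover", n_scored=len(artif.values), n_missing=len(artif.missing)
    )

    current("deprivation")
    socio = read_socio_table(config.socio_path)
    fdep = fdep_score(socio)
    manifest.record(
        "deprivation", n_scored=len(fdep.values), n_missing=len(fdep.missing)
    )

    current("ac_ingest")
    ac = read_ac_rates(config.ac_path)
    manifest.record("ac_ingest", n_scored=len(ac.values), n_missing=len(ac.missing))

    current("zscore_impute")
    policy = ImputationPolicy(mode=config.impute_mode)
    z_cols = {}
    for col in (temp, fdep, artif, ac):
        z = zscore(col)
        z = impute_or_log(z, units, policy, manifest)
        z_cols[col.name] = z
    manifest.record(
        "zscore_impute",
        imputed={name: sorted(c.imputed) for name, c in z_cols.items() if c.imputed},
    )

    current("composite_index")
    scores = composite_index(
        z_cols["temperature"],
        z_cols["fdep"],
        z_cols["artificial_fraction"],
        z_cols["ac_rate"],
    )
    n_missing = sum(s.missing for s in scores)
    manifest.record(
        "composite_index", n_scored=len(scores) - n_missing, n_missing=n_missing
    )

    current("quantile_classes")
    quantile_classes(scores, k=config.k_classes)
    scores_df = scores_frame(scores)
    manifest.record("quantile_classes", k=config.k_classes)

    morbidity_df = None
    if config.visits_path is not None:
        current("icanicule")
        causes = (
            read_cause_map(config.causes_path) if config.causes_path else CauseMap()
        )
        visits = VisitRecordSet.from_csv(config.visits_path)
        kept, dropped = filter_heat_visits(visits, causes, config.window)
        indicators, orphans = aggregate_indicator(
            kept, units, causes, period=config.window
        )
        morbidity_df = indicator_frame(indicators)
        manifest.record(
            "icanicule",
            n_input=len(visits),
            n_kept=len(kept),
            n_dropped=dropped,
            n_orphans=len(orphans),
        )

    manifest.stages.pop("_current", None)

    outputs: dict[str, Path] = {}
    outputs["scores_csv"] = outdir / "scores.csv"
    _write_csv(scores_df, outputs["scores_csv"])
    if morbidity_df is not None:
        outputs["icanicule_csv"] = outdir / "icanicule.csv"
        _write_csv(morbidity_df, outputs["icanicule_csv"])

    outputs["geojson"] = outdir / "scores.geojson"
    joined = scores_df.join(morbidity_df) if morbidity_df is not None else scores_df
    _write_scored_geojson(units, joined, outputs["geojson"])
    for p in outputs.values():
        manifest.checksum(p)
    return RunResult(
        units=units,
        scores=scores_df,
        morbidity=morbidity_df,
        manifest=manifest,
        outputs=outputs,
    )


def run_synth_pipeline(
    synth_cfg,
    outdir: str | Path,
    k_classes: int = 5,
    impute_mode: str = "department_median",
) -> RunResult:
    """Synth mode: generate the full input bundle, then run the pipeline.

    Inputs land in ``outdir/inputs`` and products in ``outdir/outputs``;
    the run is deterministic for a given synth seed.
    """
    from .synth import generate, write_bundle

    outdir = Path(outdir)
    bundle = generate(synth_cfg)
    paths = write_bundle(bundle, outdir / "inputs")
    cfg = RunConfig(
        units_path=paths["units"],
        temperature_paths=list(paths["temperature"]),
        landcover_path=paths["landcover"],
        socio_path=paths["socio"],
        ac_path=paths["ac"],
        visits_path=paths["visits"],
        window=(synth_cfg.season_start, synth_cfg.season_end),
        k_classes=k_classes,
        impute_mode=impute_mode,
        outdir=outdir / "outputs",
    )
    return run_pipeline(cfg)


def impute_or_log(
    column: IndicatorColumn,
    units: AdminUnitSet,
    policy: ImputationPolicy,
    manifest: RunManifest,
) -> IndicatorColumn:
    from .vindex import impute

    before = set(column.missing)
    out = impute(column, units, policy)
    for uid in sorted(before - out.missing):
        msg = f"imputed {column.name} for unit {uid} ({policy.mode})"
        log.warning(msg)
        manifest.warnings.append(msg)
    return out


def _write_scored_geojson(
    units: AdminUnitSet, attributes: pd.DataFrame, path: Path
) -> None:
    from shapely.geometry import mapping

    features = []
    for u in units:
        props = {"unit_id": u.unit_id, "name": u.name,
                 "department_id": u.department_id, "population": u.population}
        if u.unit_id in attributes.index:
            row = attributes.loc[u.unit_id]
            for key, val in row.items():
                if isinstance(val, float) and pd.isna(val):
                    props[key] = None
                elif hasattr(val, "item"):
                    props[key] = val.item()
                else:
                    props[key] = val
        features.append(
            {"type": "Feature", "geometry": mapping(u.geometry), "properties": props}
        )
    obj = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": units.crs_id}},
        "features": features,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)


def export_choropleth(
    scores: pd.DataFrame,
    units: AdminUnitSet,
    attr: str,
    out_geojson: str | Path,
    out_image: str | Path | None = None,
) -> None:
    """Write a classed GeoJSON plus a static choropleth image.

    Sequential colour ramp, one bin per class; units with no value are
    hatched grey ("no data").
    """
    if attr not in scores.columns:
        raise SchemaError(f"attribute {attr!r} not in score table")
    _write_scored_geojson(units, scores[[attr]], Path(out_geojson))
    if out_image is None:
        return

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon
    import numpy as np

    vals = scores[attr]
    classes = sorted(vals.dropna().unique())
    cmap = plt.get_cmap("YlOrRd", max(len(classes), 2))
    fig, ax = plt.subplots(figsize=(7, 7))
    for u in units:
        val = vals.get(u.unit_id)
        geoms = getattr(u.geometry, "geoms", [u.geometry])
        for g in geoms:
            xy = np.asarray(g.exterior.coords)
            if val is None or pd.isna(val):
                patch = MplPolygon(xy, facecolor="0.8", hatch="//",
                                   edgecolor="0.4", linewidth=0.3)
            else:
                patch = MplPolygon(
                    xy,
                    facecolor=cmap(classes.index(val)),
                    edgecolor="0.3",
                    linewidth=0.3,
                )
            ax.add_patch(patch)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"Heatwave vulnerability — {attr}")
    fig.savefig(out_image, dpi=150, bbox_inches="tight")
    plt.close(fig)
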