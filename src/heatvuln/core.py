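"""Domain types, georeferenced I/O and cross-layer validation.

All geometry lives in one projected, metre-unit reference system
(``crs_id`` such as ``"EPSG:2154"``).  Raster origin is the upper-left
pixel *corner*; row index increases southward.  ``unit_id`` is opaque
text — French commune codes carry leading zeros and must never be
coerced to numbers.

Vector I/O is GeoJSON (``json`` + shapely); raster I/O is single-band
GeoTIFF through :mod:`tifffile`, reading and writing the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL_NODATA).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import (
    AlignmentError,
    EmptyInputError,
    GeoreferenceError,
    SchemaError,
    UnsupportedFormatError,
)
from .projection import PROJECTIONS, is_geographic

DEFAULT_WORKING_CRS = "EPSG:2154"

Orientation = Literal["risk", "protective"]
RasterSemantics = Literal["temperature_celsius", "landcover_code"]

TEMP_MIN_C, TEMP_MAX_C = -60.0, 70.0


# ---------------------------------------------------------------------------
# vector side
# ---------------------------------------------------------------------------

@dataclass
class AdminUnit:
    """One administrative unit (commune) with its scoring attributes."""

    unit_id: str
    name: str
    department_id: str
    geometry: BaseGeometry
    population: float
    area_km2: float

    def validate(self) -> None:
        if not self.unit_id:
            raise SchemaError("unit_id must be non-empty")
        if self.population < 0:
            raise SchemaError(f"unit {self.unit_id!r}: population must be >= 0")
        if self.area_km2 <= 0:
            raise SchemaError(f"unit {self.unit_id!r}: area_km2 must be > 0")
        geom_km2 = self.geometry.area / 1e6
        if abs(geom_km2 - self.area_km2) > 0.005 * self.area_km2:
            raise SchemaError(
                f"unit {self.unit_id!r}: stored area {self.area_km2:.4f} km² "
                f"differs from geometry area {geom_km2:.4f} km² by more than 0.5%"
            )


@dataclass
class AdminUnitSet:
    """Ordered collection of units sharing one projected reference system."""

    units: list[AdminUnit]
    crs_id: str

    def __post_init__(self) -> None:
        if not self.units:
            raise EmptyInputError("administrative layer contains no units")
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate unit_id values: {dup}")
        for u in self.units:
            u.validate()

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[AdminUnit]:
        return iter(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def get(self, unit_id: str) -> AdminUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def total_area_km2(self) -> float:
        return float(sum(u.area_km2 for u in self.units))

    def reordered(self, unit_ids: list[str]) -> "AdminUnitSet":
        by_id = {u.unit_id: u for u in self.units}
        return AdminUnitSet([by_id[i] for i in unit_ids], self.crs_id)


def _repair(geom: BaseGeometry) -> BaseGeometry:
    return geom if geom.is_valid else shapely.make_valid(geom)


def _parse_geojson_crs(obj: dict) -> str:
    """Legacy GeoJSON ``crs`` member; RFC 7946 files default to WGS84."""
    crs = obj.get("crs")
    if crs is None:
        return "EPSG:4326"
    name = str(crs.get("properties", {}).get("name", ""))
    if name.upper().startswith("EPSG:"):
        return name.upper()
    if "EPSG" in name:  # e.g. urn:ogc:def:crs:EPSG::2154
        code = name.rsplit(":", 1)[-1]
        return f"EPSG:{code}"
    if name.upper().endswith("CRS84"):
        return "EPSG:4326"
    raise GeoreferenceError(f"unrecognised CRS name {name!r}")


def _reproject_geom(geom: BaseGeometry, proj) -> BaseGeometry:
    return shapely.transform(
        geom,
        lambda pts: np.array([proj.forward(x, y) for x, y in pts]),
    )


def read_units(
    path: str | Path,
    working_crs: str = DEFAULT_WORKING_CRS,
) -> AdminUnitSet:
    """Read an administrative layer from GeoJSON.

    Mandatory feature properties: ``unit_id``, ``department_id``,
    ``population`` (``name`` is optional).  Geographic input is
    reprojected to ``working_crs``; projected input is taken as-is with
    its declared system.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpkg":
        raise UnsupportedFormatError(
            "GeoPackage input is not supported by this build; convert to GeoJSON"
        )
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    features = obj.get("features", [])
    if not features:
        raise EmptyInputError(f"{path}: empty layer")

    src_crs = _parse_geojson_crs(obj)
    proj = None
    if is_geographic(src_crs):
        proj = PROJECTIONS.get(working_crs)
        if proj is None:
            raise GeoreferenceError(
                f"no projection registered for working CRS {working_crs!r}"
            )
        crs_id = working_crs
    else:
        crs_id = src_crs

    units: list[AdminUnit] = []
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        for fieldname in ("unit_id", "department_id", "population"):
            if fieldname not in props or props[fieldname] is None:
                raise SchemaError(
                    f"feature {i}: missing mandatory attribute {fieldname!r}"
                )
        geom = _repair(shape(feat["geometry"]))
        if proj is not None:
            geom = _reproject_geom(geom, proj)
        units.append(
            AdminUnit(
                unit_id=str(props["unit_id"]),
                name=str(props.get("name", "")),
                department_id=str(props["department_id"]),
                geometry=geom,
                population=float(props["population"]),
                area_km2=geom.area / 1e6,
            )
        )
    return AdminUnitSet(units, crs_id)


def write_units(units: AdminUnitSet, path: str | Path) -> None:
    """Write GeoJSON with a legacy ``crs`` member naming the projected system."""
    features = []
    for u in units:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(u.geometry),
                "properties": {
                    "unit_id": u.unit_id,
                    "name": u.name,
                    "department_id": u.department_id,
                    "population": u.population,
                    "area_km2": u.area_km2,
                },
            }
        )
    obj = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": units.crs_id}},
        "features": features,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)


# ---------------------------------------------------------------------------
# raster side
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """Single-band georeferenced grid with square, metre-unit pixels."""

    origin_x: float
    origin_y: float
    pixel_size: float
    values: np.ndarray
    nodata: float
    crs_id: str
    semantics: RasterSemantics

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.pixel_size <= 0:
            raise GeoreferenceError("pixel_size must be > 0")
        if self.values.ndim != 2:
            raise UnsupportedFormatError("raster values must be a 2-D array")
        if self.semantics == "temperature_celsius":
            v = self.values
            bad = (v != self.nodata) & ((v < TEMP_MIN_C) | (v > TEMP_MAX_C))
            if np.any(bad):
                raise SchemaError(
                    f"{int(bad.sum())} temperature pixels outside "
                    f"[{TEMP_MIN_C}, {TEMP_MAX_C}] °C and not nodata"
                )
        elif self.semantics == "landcover_code":
            if not np.issubdtype(self.values.dtype, np.integer):
                raise SchemaError("land-cover raster must carry integer codes")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer pixel edges."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) centre coordinates in row-major pixel order."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.pixel_size
        ys = self.origin_y - (rows + 0.5) * self.pixel_size
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.crs_id == other.crs_id
            and self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) < 1e-6
            and abs(self.origin_y - other.origin_y) < 1e-6
            and abs(self.pixel_size - other.pixel_size) < 1e-9
        )

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata


# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113
_KEY_MODEL_TYPE = 1024     # 1 projected, 2 geographic
_KEY_RASTER_TYPE = 1025    # 1 PixelIsArea
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


def _crs_to_geokeys(crs_id: str) -> list[int]:
    try:
        code = int(crs_id.split(":")[1])
    except (IndexError, ValueError) as exc:
        raise GeoreferenceError(f"cannot encode CRS {crs_id!r} in GeoTIFF") from exc
    if is_geographic(crs_id):
        keys = [(_KEY_MODEL_TYPE, 2), (_KEY_RASTER_TYPE, 1), (_KEY_GEOGRAPHIC_CS, code)]
    else:
        keys = [(_KEY_MODEL_TYPE, 1), (_KEY_RASTER_TYPE, 1), (_KEY_PROJECTED_CS, code)]
    directory = [1, 1, 0, len(keys)]
    for key, value in keys:
        directory += [key, 0, 1, value]
    return directory


def _geokeys_to_crs(directory: Iterable[int]) -> str:
    vals = list(directory)
    entries = {}
    for i in range(4, len(vals), 4):
        key, location, _count, value = vals[i : i + 4]
        if location == 0:
            entries[key] = value
    if _KEY_PROJECTED_CS in entries:
        return f"EPSG:{entries[_KEY_PROJECTED_CS]}"
    if _KEY_GEOGRAPHIC_CS in entries:
        return f"EPSG:{entries[_KEY_GEOGRAPHIC_CS]}"
    raise GeoreferenceError("GeoTIFF carries no recognisable CRS geokey")


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a single-band GeoTIFF with georeferencing tags."""
    px = float(grid.pixel_size)
    geokeys = _crs_to_geokeys(grid.crs_id)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0),
        ),
        (_TAG_GEOKEYS, "H", len(geokeys), tuple(geokeys)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    values = grid.values
    if grid.semantics == "landcover_code":
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float64)
    tifffile.imwrite(path, values, extratags=extratags)


def read_raster(path: str | Path, semantics: RasterSemantics) -> RasterGrid:
    """Read a single-band georeferenced GeoTIFF.

    Class-code rasters are cast to integers exactly; a lossy cast is a
    schema error.  Missing georeferencing tags raise
    :class:`GeoreferenceError`; multi-band files are rejected.
    """
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise UnsupportedFormatError(
                f"{path}: expected a single-band raster, found {len(tif.pages)} pages"
            )
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(
                f"{path}: expected 1 sample per pixel, found {page.samplesperpixel}"
            )
        tags = {t.code: t.value for t in page.tags.values()}
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GeoreferenceError(f"{path}: missing GeoTIFF georeferencing tags")
        if _TAG_GEOKEYS not in tags:
            raise GeoreferenceError(f"{path}: missing CRS (GeoKeyDirectory tag)")
        sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
        if abs(sx - sy) > 1e-9:
            raise UnsupportedFormatError(f"{path}: non-square pixels ({sx} × {sy})")
        tie = tags[_TAG_TIEPOINT]
        if tie[0] != 0 or tie[1] != 0:
            raise GeoreferenceError(f"{path}: tiepoint must anchor pixel (0, 0)")
        crs_id = _geokeys_to_crs(tags[_TAG_GEOKEYS])
        nodata_raw = tags.get(_TAG_GDAL_NODATA, "nan")
        if isinstance(nodata_raw, bytes):
            nodata_raw = nodata_raw.decode()
        nodata = float(str(nodata_raw).strip().strip("\x00") or "nan")
        values = page.asarray()

    if semantics == "landcover_code":
        as_int = values.astype(np.int64)
        if not np.array_equal(as_int.astype(values.dtype), values):
            raise SchemaError(f"{path}: land-cover codes are not integral")
        values = as_int
        if not np.isnan(nodata) and nodata == int(nodata):
            nodata = int(nodata)
    else:
        values = values.astype(np.float64)
    return RasterGrid(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        pixel_size=float(sx),
        values=values,
        nodata=nodata,
        crs_id=crs_id,
        semantics=semantics,
    )


# ---------------------------------------------------------------------------
# indicator & visit containers
# ---------------------------------------------------------------------------

@dataclass
class IndicatorColumn:
    """One per-unit indicator with orientation and missingness flags."""

    name: str
    values: dict[str, float]
    orientation: Orientation
    missing: set[str] = field(default_factory=set)
    units_label: str = ""
    imputed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.missing & set(self.values)
        if overlap:
            raise SchemaError(
                f"indicator {self.name!r}: units {sorted(overlap)} are flagged "
                "missing but carry a value"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise SchemaError(
                f"indicator {self.name!r}: non-finite values for {sorted(bad)}"
            )

    @property
    def unit_ids(self) -> set[str]:
        return set(self.values) | self.missing

    def value_array(self, unit_ids: list[str]) -> np.ndarray:
        """Values aligned to ``unit_ids`` with NaN where missing."""
        return np.array([self.values.get(u, np.nan) for u in unit_ids])

    def with_values(self, values: dict[str, float], missing: set[str],
                    imputed: set[str] | None = None) -> "IndicatorColumn":
        return IndicatorColumn(
            name=self.name,
            values=values,
            orientation=self.orientation,
            missing=missing,
            units_label=self.units_label,
            imputed=self.imputed if imputed is None else imputed,
        )


@dataclass(frozen=True)
class VisitRecord:
    """One emergency visit event feeding the heat-morbidity indicator."""

    unit_id: str
    date: datetime.date
    source: str  # emergency_department | emergency_gp
    cause_code: str

    def __post_init__(self) -> None:
        if self.source not in ("emergency_department", "emergency_gp"):
            raise SchemaError(f"invalid visit source {self.source!r}")


# ---------------------------------------------------------------------------
# cross-layer validation
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReport:
    crs_ok: bool
    coverage_fraction: float
    uncovered_unit_ids: list[str]

    @property
    def ok(self) -> bool:
        return self.crs_ok and self.coverage_fraction >= 0.99


def validate_alignment(raster: RasterGrid, units: AdminUnitSet) -> AlignmentReport:
    """Check that a raster can serve the unit layer without reprojection.

    A CRS mismatch is an error (rasters are never silently reprojected or
    resampled).  Coverage below 99% of total unit area fails the report;
    uncovered units are listed individually.
    """
    if raster.crs_id != units.crs_id:
        raise AlignmentError(
            f"raster CRS {raster.crs_id!r} != unit CRS {units.crs_id!r}; "
            "reproject the vector layer, never the raster"
        )
    xmin, ymin, xmax, ymax = raster.extent
    extent_poly = shapely.box(xmin, ymin, xmax, ymax)
    covered = 0.0
    total = 0.0
    uncovered: list[str] = []
    for u in units:
        a = u.geometry.area
        inter = u.geometry.intersection(extent_poly).area
        covered += inter
        total += a
        if inter < a * (1 - 1e-9):
            uncovered.append(u.unit_id)
    return AlignmentReport(
        crs_ok=True,
        coverage_fraction=covered / total if total else 0.0,
        uncovered_unit_ids=uncovered,
    )
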