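"""Shared fixtures: small synthetic study areas and brute-force oracles."""

from __future__ import annotations

import pytest
from hypothesis import settings

from heatvuln.synth import SynthConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """4×4 communes at national mean area, default noise, seed 7."""
    return generate(SynthConfig(n_side=4, seed=7))


@pytest.fixture(scope="session")
def medium_bundle():
    """6×6 communes, 1 km cells, 100 m pixels — fast but non-trivial."""
    return generate(SynthConfig(n_side=6, cell_km=1.0, pixel_m=100.0, seed=11))


def brute_force_assignment(raster, units):
    """Independent pixel-centre-in-polygon oracle.

    Unit-major traversal: for each unit, every pixel whose centre falls
    inside the unit's bounding box is coverage-tested with a fresh
    shapely Point (coverage implies bbox containment, so the restriction
    is exact).  Boundary ties are resolved afterwards by lexicographic
    unit_id.  Returns a dict (row, col) -> unit_id.
    """
    import math

    from shapely.geometry import Point

    ox, oy, px = raster.origin_x, raster.origin_y, raster.pixel_size
    hits: dict[tuple[int, int], list[str]] = {}
    for u in units:
        xmin, ymin, xmax, ymax = u.geometry.bounds
        c_lo = max(0, math.ceil((xmin - ox) / px - 0.5))
        c_hi = min(raster.n_cols - 1, math.floor((xmax - ox) / px - 0.5))
        r_lo = max(0, math.ceil((oy - ymax) / px - 0.5))
        r_hi = min(raster.n_rows - 1, math.floor((oy - ymin) / px - 0.5))
        for r in range(r_lo, r_hi + 1):
            y = oy - (r + 0.5) * px
            for c in range(c_lo, c_hi + 1):
                x = ox + (c + 0.5) * px
                if u.geometry.covers(Point(x, y)):
                    hits.setdefault((r, c), []).append(u.unit_id)
    return {pixel: min(ids) for pixel, ids in hits.items()}


def brute_force_zonal_mean(raster, units):
    """Pixel-loop zonal mean oracle: sum/count per unit, nodata skipped."""
    assign = brute_force_assignment(raster, units)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for (r, c), uid in assign.items():
        v = raster.values[r, c]
        if v == raster.nodata:
            continue
        sums[uid] = sums.get(uid, 0.0) + float(v)
        counts[uid] = counts.get(uid, 0) + 1
    return {uid: sums[uid] / counts[uid] for uid in sums}, counts
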