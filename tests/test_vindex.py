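"""Z-scores, imputation, the equal-weight composite and quantile classing."""

import numpy as np
import pytest
import shapely
from hypothesis import given, strategies as st

from heatvuln.core import AdminUnit, AdminUnitSet, IndicatorColumn
from heatvuln.errors import DegenerateVarianceError, OrientationError, SchemaError
from heatvuln.vindex import (
    ImputationPolicy,
    composite_index,
    impute,
    quantile_classes,
    scores_frame,
    zscore,
)


def _col(values, name="temperature", orientation="risk", missing=()):
    return IndicatorColumn(
        name=name,
        values=dict(values),
        orientation=orientation,
        missing=set(missing),
    )


def _grid_units(n_side=3, dept_split=None):
    units = []
    for r in range(n_side):
        for c in range(n_side):
            geom = shapely.box(c * 1000, -r * 1000, (c + 1) * 1000, (1 - r) * 1000)
            dept = "D01" if dept_split is None or c < dept_split else "D02"
            units.append(
                AdminUnit(
                    f"{r}{c}", "", dept, geom, 100.0, geom.area / 1e6
                )
            )
    return AdminUnitSet(units, "EPSG:2154")


class TestZscore:
    def test_three_values_match_closed_form(self):
        z = zscore(_col({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert z.values["a"] == pytest.approx(-1.2247448714, abs=1e-9)
        assert z.values["b"] == pytest.approx(0.0, abs=1e-12)
        assert z.values["c"] == pytest.approx(1.2247448714, abs=1e-9)

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = zscore(_col({f"u{i}": v for i, v in enumerate(rng.uniform(0, 50, 40))}))
        arr = np.array(list(z.values.values()))
        assert arr.mean() == pytest.approx(0.0, abs=1e-9)
        assert arr.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    @given(
        a=st.floats(0.1, 100.0),
        b=st.floats(-1000.0, 1000.0),
    )
    def test_affine_invariance(self, a, b):
        vals = {"u1": 1.0, "u2": 4.0, "u3": 9.0, "u4": 16.0}
        z1 = zscore(_col(vals))
        z2 = zscore(_col({k: a * v + b for k, v in vals.items()}))
        for k in vals:
            assert z2.values[k] == pytest.approx(z1.values[k], abs=1e-9)

    def test_missing_entries_stay_missing(self):
        z = zscore(_col({"a": 1.0, "b": 2.0, "c": 3.0}, missing={"d"}))
        assert z.missing == {"d"}
        assert "d" not in z.values

    def test_zero_dispersion_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            zscore(_col({"a": 5.0, "b": 5.0, "c": 5.0}))


class TestImpute:
    def test_no_missing_is_identity(self):
        units = _grid_units(2)
        col = _col({u: 1.0 * i for i, u in enumerate(units.unit_ids)}, name="fdep")
        out = impute(col, units, ImputationPolicy("department_median"))
        assert out.values == col.values
        assert not out.imputed

    def test_department_median_fills_with_median(self):
        units = _grid_units(2)  # all D01
        ids = units.unit_ids
        col = _col(
            {ids[0]: 1.0, ids[1]: 2.0, ids[2]: 3.0},
            name="fdep",
            missing={ids[3]},
        )
        out = impute(col, units, ImputationPolicy("department_median"))
        assert out.values[ids[3]] == pytest.approx(2.0)
        assert out.imputed == {ids[3]}
        assert ids[3] not in out.missing

    def test_whole_department_missing_stays_missing(self):
        units = _grid_units(2, dept_split=1)  # col 0 = D01, col 1 = D02
        d2 = [u.unit_id for u in units if u.department_id == "D02"]
        d1 = [u.unit_id for u in units if u.department_id == "D01"]
        col = _col({u: 1.0 + i for i, u in enumerate(d1)}, name="fdep",
                   missing=set(d2))
        out = impute(col, units, ImputationPolicy("department_median"))
        assert set(d2) <= out.missing

    def test_drop_mode_changes_nothing(self):
        units = _grid_units(2)
        col = _col({units.unit_ids[0]: 1.0, units.unit_ids[1]: 3.0},
                   name="fdep", missing={units.unit_ids[2]})
        out = impute(col, units, ImputationPolicy("drop"))
        assert out.missing == col.missing

    def test_neighbour_mean_uses_adjacent_units(self):
        units = _grid_units(3)
        ids = units.unit_ids  # row-major "rc"
        vals = {u: float(i) for i, u in enumerate(ids) if u != "11"}
        col = _col(vals, name="fdep", missing={"11"})
        out = impute(col, units, ImputationPolicy("neighbour_mean", frozenset({"fdep"})))
        # centre cell touches all 8 others
        expected = np.mean([v for k, v in vals.items()])
        assert out.values["11"] == pytest.approx(expected)

    def test_policy_ignores_columns_outside_applies_to(self):
        units = _grid_units(2)
        col = _col({units.unit_ids[0]: 20.0, units.unit_ids[1]: 22.0},
                   name="temperature", missing={units.unit_ids[2]})
        out = impute(col, units, ImputationPolicy("department_median"))
        assert units.unit_ids[2] in out.missing


class TestCompositeIndex:
    def _zs(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"u{i}" for i in range(n)]
        cols = []
        for name, orient in [
            ("temperature", "risk"),
            ("fdep", "risk"),
            ("artificial_fraction", "risk"),
            ("ac_rate", "protective"),
        ]:
            cols.append(
                zscore(_col(dict(zip(ids, rng.uniform(0, 10, n))),
                            name=name, orientation=orient))
            )
        return cols

    def test_all_zero_z_scores_give_zero_index(self):
        ids = ["a", "b"]
        cols = []
        for name, orient in [
            ("temperature", "risk"), ("fdep", "risk"),
            ("artificial_fraction", "risk"), ("ac_rate", "protective"),
        ]:
            cols.append(_col({i: 0.0 for i in ids}, name=name, orientation=orient))
        scores = composite_index(*cols)
        assert all(s.index == 0.0 for s in scores)

    def test_single_unit_z_of_one_weighs_quarter(self):
        ids = ["a"]
        make = lambda name, orient, v: _col({"a": v}, name=name, orientation=orient)
        scores = composite_index(
            make("temperature", "risk", 1.0),
            make("fdep", "risk", 0.0),
            make("artificial_fraction", "risk", 0.0),
            make("ac_rate", "protective", 0.0),
        )
        assert scores[0].index == pytest.approx(0.25)

    def test_matches_direct_formula_oracle(self):
        zt, zf, za, zac = self._zs(n=30, seed=1)
        scores = {s.unit_id: s.index for s in composite_index(zt, zf, za, zac)}
        for uid in zt.values:
            direct = (
                zt.values[uid] + zf.values[uid] + za.values[uid] - zac.values[uid]
            ) / 4.0
            assert scores[uid] == pytest.approx(direct, abs=1e-12)

    def test_protective_sign_flips_ac(self):
        ids = ["a"]
        make = lambda name, orient, v: _col({"a": v}, name=name, orientation=orient)
        scores = composite_index(
            make("temperature", "risk", 0.0),
            make("fdep", "risk", 0.0),
            make("artificial_fraction", "risk", 0.0),
            make("ac_rate", "protective", 2.0),
        )
        assert scores[0].index == pytest.approx(-0.5)

    def test_wrong_orientation_metadata_rejected(self):
        zt, zf, za, zac = self._zs()
        bad_ac = _col(dict(zac.values), name="ac_rate", orientation="risk")
        with pytest.raises(OrientationError):
            composite_index(zt, zf, za, bad_ac)

    def test_unit_missing_an_indicator_is_missing(self):
        zt, zf, za, zac = self._zs(n=6)
        vals = dict(zt.values)
        gone = sorted(vals)[0]
        del vals[gone]
        zt2 = zt.with_values(vals, {gone})
        scores = {s.unit_id: s for s in composite_index(zt2, zf, za, zac)}
        assert scores[gone].missing
        assert not scores[sorted(vals)[0]].missing

    def test_permuting_units_permutes_outputs(self):
        zt, zf, za, zac = self._zs(n=12, seed=2)
        base = {s.unit_id: s.index for s in composite_index(zt, zf, za, zac)}

        def rev(col):
            items = list(col.values.items())[::-1]
            return col.with_values(dict(items), set(col.missing))

        permuted = {
            s.unit_id: s.index
            for s in composite_index(rev(zt), rev(zf), rev(za), rev(zac))
        }
        assert base == permuted


class TestAffineInvarianceOfIndex:
    def test_raw_indicator_rescaling_leaves_index_unchanged(self):
        rng = np.random.default_rng(4)
        ids = [f"u{i}" for i in range(25)]
        raw = {
            "temperature": dict(zip(ids, rng.uniform(18, 32, 25))),
            "fdep": dict(zip(ids, rng.standard_normal(25))),
            "artificial_fraction": dict(zip(ids, rng.uniform(0, 1, 25))),
            "ac_rate": dict(zip(ids, rng.uniform(0, 60, 25))),
        }
        orients = {"temperature": "risk", "fdep": "risk",
                   "artificial_fraction": "risk", "ac_rate": "protective"}

        def build(transform):
            cols = []
            for name in ("temperature", "fdep", "artificial_fraction", "ac_rate"):
                a, b = transform[name]
                vals = {k: a * v + b for k, v in raw[name].items()}
                cols.append(zscore(_col(vals, name=name, orientation=orients[name])))
            return {s.unit_id: s.index for s in composite_index(*cols)}

        identity = {n: (1.0, 0.0) for n in raw}
        scaled = {"temperature": (1.8, 32.0), "fdep": (3.0, -1.0),
                  "artificial_fraction": (100.0, 0.0), "ac_rate": (0.01, 0.5)}
        base = build(identity)
        other = build(scaled)
        for uid in base:
            assert other[uid] == pytest.approx(base[uid], abs=1e-9)


class TestOrientationMonotonicity:
    def _rank(self, scores, uid):
        ordered = sorted(
            (s for s in scores if not s.missing), key=lambda s: s.index
        )
        return [s.unit_id for s in ordered].index(uid)

    @pytest.mark.parametrize("indicator", ["temperature", "fdep",
                                           "artificial_fraction"])
    def test_raising_risk_indicator_never_lowers_rank(self, indicator):
        rng = np.random.default_rng(5)
        ids = [f"u{i}" for i in range(15)]
        raw = {
            "temperature": dict(zip(ids, rng.uniform(18, 32, 15))),
            "fdep": dict(zip(ids, rng.standard_normal(15))),
            "artificial_fraction": dict(zip(ids, rng.uniform(0, 1, 15))),
            "ac_rate": dict(zip(ids, rng.uniform(0, 60, 15))),
        }
        orients = {"temperature": "risk", "fdep": "risk",
                   "artificial_fraction": "risk", "ac_rate": "protective"}

        def score(raw_vals):
            cols = [
                zscore(_col(raw_vals[n], name=n, orientation=orients[n]))
                for n in ("temperature", "fdep", "artificial_fraction", "ac_rate")
            ]
            return composite_index(*cols)

        target = ids[3]
        before = self._rank(score(raw), target)
        bumped = {n: dict(v) for n, v in raw.items()}
        bumped[indicator][target] += 5.0
        after = self._rank(score(bumped), target)
        assert after >= before

    def test_raising_ac_never_raises_rank(self):
        rng = np.random.default_rng(6)
        ids = [f"u{i}" for i in range(15)]
        raw = {
            "temperature": dict(zip(ids, rng.uniform(18, 32, 15))),
            "fdep": dict(zip(ids, rng.standard_normal(15))),
            "artificial_fraction": dict(zip(ids, rng.uniform(0, 1, 15))),
            "ac_rate": dict(zip(ids, rng.uniform(0, 60, 15))),
        }
        orients = {"temperature": "risk", "fdep": "risk",
                   "artificial_fraction": "risk", "ac_rate": "protective"}

        def score(raw_vals):
            cols = [
                zscore(_col(raw_vals[n], name=n, orientation=orients[n]))
                for n in ("temperature", "fdep", "artificial_fraction", "ac_rate")
            ]
            return composite_index(*cols)

        target = ids[7]
        before = self._rank(score(raw), target)
        bumped = {n: dict(v) for n, v in raw.items()}
        bumped["ac_rate"][target] += 20.0
        after = self._rank(score(bumped), target)
        assert after <= before


def _scored(values):
    from heatvuln.vindex import VulnerabilityScore

    return [
        VulnerabilityScore(
            unit_id=f"u{i:04d}", z_temperature=0, z_fdep=0, z_artificial=0,
            z_ac=0, index=float(v),
        )
        for i, v in enumerate(values)
    ]


class TestQuantileClasses:
    def test_ten_values_five_classes_split_in_pairs(self):
        scores = _scored(range(1, 11))
        quantile_classes(scores, k=5)
        assert [s.quantile_class for s in scores] == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_equal_collapses_with_warning(self):
        scores = _scored([2.0] * 10)
        with pytest.warns(UserWarning, match="distinct"):
            quantile_classes(scores, k=5)
        assert {s.quantile_class for s in scores} == {1}

    def test_thousand_uniform_scores_split_exactly(self):
        rng = np.random.default_rng(7)
        scores = _scored(rng.uniform(0, 1, 1000))
        quantile_classes(scores, k=5)
        counts = np.bincount([s.quantile_class for s in scores])[1:]
        assert list(counts) == [200] * 5

    def test_too_few_scores_rejected(self):
        with pytest.raises(SchemaError):
            quantile_classes(_scored([1.0, 2.0]), k=5)

    @given(st.integers(2, 8), st.integers(0, 2**31 - 1))
    def test_class_sizes_differ_by_at_most_one_on_distinct_values(self, k, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(k, 80))
        vals = rng.permutation(n) * 1.0  # distinct
        scores = _scored(vals)
        quantile_classes(scores, k=k)
        counts = np.bincount([s.quantile_class for s in scores], minlength=k + 1)[1:]
        assert counts.max() - counts.min() <= 1

    def test_missing_scores_get_no_class(self):
        scores = _scored(range(6))
        scores[2].missing = True
        scores[2].index = float("nan")
        quantile_classes(scores, k=2)
        assert scores[2].quantile_class is None
        assert all(s.quantile_class is not None for s in scores if not s.missing)


class TestEndToEndCorner:
    def test_hot_urban_deprived_unairconditioned_corner_hits_top_class(self):
        """Zero-noise configuration: one corner extreme on all four layers."""
        from heatvuln.synth import SynthConfig, make_commune_grid

        cfg = SynthConfig(n_side=5, seed=0)
        units = make_commune_grid(cfg)
        ids = units.unit_ids
        corner = ids[0]
        # gradient away from the corner unit
        order = {u: i for i, u in enumerate(ids)}
        frac = {u: 0.9 - 0.8 * order[u] / (len(ids) - 1) for u in ids}
        temp = {u: 24.0 + 5.0 * frac[u] for u in ids}
        dep = {u: frac[u] for u in ids}
        ac = {u: 100.0 * (1 - frac[u]) for u in ids}

        cols = [
            zscore(_col(temp, name="temperature", orientation="risk")),
            zscore(_col(dep, name="fdep", orientation="risk")),
            zscore(_col(frac, name="artificial_fraction", orientation="risk")),
            zscore(_col(ac, name="ac_rate", orientation="protective")),
        ]
        scores = composite_index(*cols)
        quantile_classes(scores, k=5)
        by_id = {s.unit_id: s for s in scores}
        assert by_id[corner].quantile_class == 5

    def test_scores_frame_shape(self):
        scores = _scored([1, 2, 3, 4, 5])
        quantile_classes(scores, k=2)
        df = scores_frame(scores)
        assert list(df.columns) == [
            "z_temperature", "z_fdep", "z_artificial", "z_ac",
            "index", "quantile_class", "imputed", "missing",
        ]
        assert len(df) == 5
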