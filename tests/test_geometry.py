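"""Landmark geometry: measurement formulas, orientation standardization,
rigid invariance, and Dahlberg method error."""
import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from craniogen import geometry
from craniogen.geometry import (
    ANGLE_DEFS,
    DISTANCE_DEFS,
    RATIO_VAR,
    GeometryError,
    LandmarkSet,
    MissingLandmarkError,
    compute_measurement_record,
    dahlberg_error,
    derive_mid_dacryon,
    interlandmark_distance,
    measurement_table,
    standardize_orientation,
    three_point_angle,
)


class TestElementaryMeasures:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 0, 0), (3, 4, 0), 5.0), ((1, 2, 3), (1, 2, 3), 0.0)],
    )
    def test_distance_examples(self, a, b, expected):
        assert interlandmark_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_distance_matches_norm_oracle_and_symmetry(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=3), rng.normal(size=3)
            expected = float(np.sqrt(np.sum((a - b) ** 2)))
            assert interlandmark_distance(a, b) == pytest.approx(expected, abs=1e-12)
            assert interlandmark_distance(b, a) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "a,v,b,expected",
        [
            ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
            ((-1, 0, 0), (0, 0, 0), (2, 0, 0), 180.0),
            ((2, 0, 0), (0, 0, 0), (5, 0, 0), 0.0),
        ],
    )
    def test_angle_examples(self, a, v, b, expected):
        assert three_point_angle(a, v, b) == pytest.approx(expected, abs=1e-9)

    def test_angle_matches_dot_product_oracle(self, rng):
        for _ in range(50):
            a, v, b = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
            u1, u2 = a - v, b - v
            expected = np.degrees(np.arccos(np.clip(
                np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2)), -1, 1)))
            assert three_point_angle(a, v, b) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(GeometryError):
            three_point_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    _coord = st.tuples(
        st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100)
    )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=_coord, v=_coord, b=_coord)
    def test_angle_range_and_symmetry_property(self, a, v, b):
        assume(interlandmark_distance(a, v) > 1e-6)
        assume(interlandmark_distance(b, v) > 1e-6)
        angle = three_point_angle(a, v, b)
        assert 0.0 <= angle <= 180.0
        assert three_point_angle(b, v, a) == pytest.approx(angle, abs=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=_coord, b=_coord, c=_coord)
    def test_distance_triangle_inequality_property(self, a, b, c):
        assert interlandmark_distance(a, c) <= (
            interlandmark_distance(a, b) + interlandmark_distance(b, c) + 1e-9
        )


class TestMidDacryon:
    def test_symmetric_and_degenerate_midpoints(self):
        lm = LandmarkSet("s", {"dR": (-10, 0, 0), "dL": (10, 0, 0)})
        assert np.allclose(derive_mid_dacryon(lm)["md"], [0, 0, 0])
        lm = LandmarkSet("s", {"dR": (1, 2, 3), "dL": (1, 2, 3)})
        assert np.allclose(derive_mid_dacryon(lm)["md"], [1, 2, 3])

    def test_random_midpoint_oracle(self, rng):
        for _ in range(20):
            dr, dl = rng.normal(size=3) * 10, rng.normal(size=3) * 10
            lm = LandmarkSet("s", {"dR": dr, "dL": dl})
            assert np.allclose(derive_mid_dacryon(lm)["md"],
                               np.mean([dr, dl], axis=0), atol=1e-12)

    def test_missing_dacryon_is_error(self):
        with pytest.raises(MissingLandmarkError):
            derive_mid_dacryon(LandmarkSet("s", {"dR": (0, 0, 0)}))

    def test_displaced_supplied_md_overwritten_with_warning(self, caplog):
        lm = LandmarkSet("s", {"dR": (-5, 0, 0), "dL": (5, 0, 0), "md": (0, 2, 0)})
        with caplog.at_level("WARNING"):
            out = derive_mid_dacryon(lm)
        assert np.allclose(out["md"], [0, 0, 0])
        assert any("overwritten" in r.message for r in caplog.records)


class TestStandardizeOrientation:
    def test_idempotent_on_standardized_template(self, template):
        std = standardize_orientation(template)
        again = standardize_orientation(std)
        for name in std.points:
            assert np.allclose(again[name], std[name], atol=1e-9)

    def test_invariant_to_random_rigid_motion(self, template, rng, make_rotation):
        base = standardize_orientation(template)
        for _ in range(10):
            rot, shift = make_rotation(rng), rng.normal(size=3) * 50
            moved = template.replace_points(
                {k: rot @ v + shift for k, v in template.points.items()}
            )
            recovered = standardize_orientation(moved)
            for name in base.points:
                assert np.allclose(recovered[name], base[name], atol=1e-6)

    def test_rigidity_preserves_all_pairwise_distances(self, template, rng, make_rotation):
        moved = template.replace_points(
            {k: make_rotation(rng) @ v + 5 for k, v in template.points.items()}
        )
        std = standardize_orientation(moved)
        names = list(template.points)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d_in = interlandmark_distance(moved[a], moved[b])
                d_out = interlandmark_distance(std[a], std[b])
                assert d_out == pytest.approx(d_in, abs=1e-9)

    def test_missing_and_degenerate_inputs(self, template):
        incomplete = template.replace_points(
            {k: v for k, v in template.points.items() if k != "pns"}
        )
        with pytest.raises(MissingLandmarkError):
            standardize_orientation(incomplete)
        collinear = template.replace_points(
            template.points | {"ans": np.array([0.0, 0.0, -10.0]),
                               "pns": np.array([0.0, 0.0, -20.0]),
                               "n": np.array([0.0, 0.0, 0.0])}
        )
        # n, ans, pns collinear -> midsagittal plane undefined
        with pytest.raises(GeometryError):
            standardize_orientation(collinear)


class TestMeasurementRecord:
    def test_template_values_match_per_variable_oracles(self, template):
        rec = compute_measurement_record(template)
        pts = dict(template.points)
        pts["md"] = 0.5 * (pts["dR"] + pts["dL"])
        for var, a, b in DISTANCE_DEFS:
            expected = float(np.linalg.norm(pts[a] - pts[b]))
            assert rec[var] == pytest.approx(expected, abs=1e-12), var
        for var, a, v, b in ANGLE_DEFS:
            u1, u2 = pts[a] - pts[v], pts[b] - pts[v]
            expected = float(np.degrees(np.arccos(
                np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2)))))
            assert rec[var] == pytest.approx(expected, abs=1e-9), var
        assert rec[RATIO_VAR] == pytest.approx(rec["n-md"] / rec["dR-dL"], abs=1e-12)

    def test_template_is_calibrated_to_reference_means(self, template):
        """Template measurements sit close to the Japanese male cohort means."""
        from craniogen.reference import JAPANESE_MALE_SUMMARY

        rec = compute_measurement_record(template)
        for var, (mean, _) in JAPANESE_MALE_SUMMARY.items():
            tol = 0.02 if var == RATIO_VAR else 0.8
            assert abs(rec[var] - mean) < tol, f"{var}: {rec[var]:.2f} vs {mean}"

    def test_rigid_invariance_of_all_21_variables(self, template, rng, make_rotation):
        base = compute_measurement_record(template)
        for _ in range(5):
            rot, shift = make_rotation(rng), rng.normal(size=3) * 100
            moved = template.replace_points(
                {k: rot @ v + shift for k, v in template.points.items()}
            )
            rec = compute_measurement_record(moved)
            for var in base.values:
                assert rec[var] == pytest.approx(base[var], abs=1e-9), var

    def test_scaling_degrees_of_homogeneity(self, template):
        base = compute_measurement_record(template)
        doubled = template.replace_points(
            {k: 2.0 * v for k, v in template.points.items()}
        )
        rec = compute_measurement_record(doubled)
        for var, *_ in DISTANCE_DEFS:
            assert rec[var] == pytest.approx(2 * base[var], rel=1e-12)
        for var, *_ in ANGLE_DEFS:
            assert rec[var] == pytest.approx(base[var], abs=1e-9)
        assert rec[RATIO_VAR] == pytest.approx(base[RATIO_VAR], rel=1e-12)

    def test_missing_landmark_error_names_affected_variables(self, template):
        incomplete = template.replace_points(
            {k: v for k, v in template.points.items() if k != "s"}
        )
        with pytest.raises(MissingLandmarkError, match="s-n-g"):
            compute_measurement_record(incomplete)

    def test_nasal_root_angles_decrease_with_anterior_nasion(self, template):
        """Anterior nasion displacement flattens the nasal root: md-n-g and
        s-n-g decrease monotonically."""
        values = {"md-n-g": [], "s-n-g": []}
        for dy in np.linspace(0, 2.0, 9):
            moved = template.replace_points(
                template.points | {"n": template["n"] + np.array([0, dy, 0])}
            )
            rec = compute_measurement_record(moved)
            for var in values:
                values[var].append(rec[var])
        for var, seq in values.items():
            assert np.all(np.diff(seq) < 0), var

    def test_vectorized_table_matches_per_subject_path(self, template, rng):
        n = 15
        stacked = {
            name: np.broadcast_to(p, (n, 3)) + rng.normal(0, 1.0, size=(n, 3))
            for name, p in template.points.items()
        }
        table = measurement_table(stacked, [f"s{i}" for i in range(n)])
        for i in range(n):
            lm = LandmarkSet(f"s{i}", {k: v[i] for k, v in stacked.items()})
            rec = compute_measurement_record(lm)
            for var in rec.values:
                assert table.iloc[i][var] == pytest.approx(rec[var], abs=1e-10)


class TestDahlberg:
    def test_identical_repeats_give_zero(self):
        pts = [(1, 2, 3), (4, 5, 6)]
        assert dahlberg_error(pts, pts, "X") == 0.0

    def test_direct_formula_evaluation(self):
        first = [(1, 0, 0), (1, 0, 0)]
        second = [(0, 0, 0), (0, 0, 0)]
        assert dahlberg_error(first, second, "X") == pytest.approx(np.sqrt(2 / 4))

    def test_random_pairs_match_formula_and_identity(self, rng):
        for axis in ("X", "Y", "Z"):
            a = rng.normal(size=(30, 3))
            b = a + rng.normal(0, 0.3, size=(30, 3))
            me = dahlberg_error(a, b, axis)
            d = a[:, "XYZ".index(axis)] - b[:, "XYZ".index(axis)]
            assert me == pytest.approx(np.sqrt(np.sum(d**2) / (2 * 30)), abs=1e-12)
            # identity ME^2 * 2N = sum(d^2), exactly
            assert me**2 * 2 * 30 == pytest.approx(np.sum(d**2), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(geometry.LandmarkValidationError):
            dahlberg_error([(0, 0, 0)], [(0, 0, 0), (1, 1, 1)], "X")
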