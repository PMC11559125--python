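import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import identity_plan, toy_area
from spotstitch.geometry import (
    AffineTransform,
    GroupPlan,
    apply_affine,
    compute_rescale_factors,
    parse_transform_table,
    parse_transform_xml,
    parse_transforms,
    transform_group_coords,
)
from spotstitch.spaceranger_io import ScaleFactors


def sf(d, h):
    return ScaleFactors(spot_diameter_fullres=d, tissue_hires_scalef=h)


class TestRescaleFactors:
    def test_identical_areas_scale_to_one(self):
        plan = compute_rescale_factors({"a": sf(200, 0.1), "b": sf(200, 0.1)})
        assert plan.s == {"a": 1.0, "b": 1.0}

    def test_printed_formula_with_distinct_maxima(self):
        # numerator (max d)(max h) = 250 * 0.10; s_a = 25/(200*0.08)
        plan = compute_rescale_factors({"a": sf(200, 0.08), "b": sf(250, 0.10)})
        assert plan.s["a"] == pytest.approx(1.5625, abs=1e-12)
        assert plan.s["b"] == pytest.approx(1.0, abs=1e-12)
        assert plan.reference_area == "b"

    def test_single_area_degenerate_group(self):
        plan = compute_rescale_factors({"only": sf(180, 0.12)})
        assert plan.s["only"] == 1.0
        assert plan.intra_group_scalar["only"] == 1.0
        assert plan.reference_area == "only"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_rescale_factors({})

    def test_product_max_variant(self):
        # maxima of d and h from different areas: printed formula gives
        # s > 1 everywhere, the variant pins the reference at exactly 1
        areas = {"a": sf(300, 0.05), "b": sf(100, 0.20)}
        printed = compute_rescale_factors(areas)
        assert min(printed.s.values()) > 1.0
        variant = compute_rescale_factors(areas, use_product_max=True)
        assert min(variant.s.values()) == 1.0

    @given(
        d=st.lists(st.floats(50, 500), min_size=1, max_size=5),
        h=st.lists(st.floats(0.05, 0.5), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_rescaled_pixel_scale_is_constant_when_maxima_coincide(self, d, h):
        n = min(len(d), len(h))
        d, h = d[:n], h[:n]
        # force the same area to carry both maxima
        i = int(np.argmax(d))
        h[i] = max(h)
        plan = compute_rescale_factors(
            {f"a{k}": sf(d[k], h[k]) for k in range(n)}
        )
        products = [plan.s[f"a{k}"] * d[k] * h[k] for k in range(n)]
        np.testing.assert_allclose(products, products[0], rtol=1e-12)


class TestAffine:
    def test_identity_leaves_points_unchanged(self):
        pts = np.array([[1.5, -2.0], [0.0, 0.0], [3.0, 4.0]])
        np.testing.assert_array_equal(apply_affine(pts, AffineTransform.identity()), pts)

    def test_pure_translation(self):
        t = AffineTransform(np.array([[1, 0, 10], [0, 1, 20]], dtype=float))
        np.testing.assert_array_equal(apply_affine([[0.0, 0.0]], t), [[10.0, 20.0]])

    def test_quarter_turn(self):
        rot90 = AffineTransform(np.array([[0, -1, 0], [1, 0, 0]], dtype=float))
        np.testing.assert_allclose(apply_affine([[3.0, 4.0]], rot90), [[-4.0, 3.0]])

    def test_empty_input_empty_output(self):
        out = apply_affine(np.empty((0, 2)), AffineTransform.identity())
        assert out.shape == (0, 2)

    def test_nonrigid_determinant_warns(self):
        with pytest.warns(UserWarning, match="determinant"):
            AffineTransform(np.array([[2.0, 0, 0], [0, 2.0, 0]]))

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.array([[1.0, 1.0, 0], [1.0, 1.0, 0]]))

    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
        data=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=2, max_size=10
        ),
    )
    @settings(derandomize=True, max_examples=50)
    def test_rigid_transforms_preserve_pairwise_distances(self, angle, tx, ty, data):
        c, s = np.cos(angle), np.sin(angle)
        t = AffineTransform(np.array([[c, -s, tx], [s, c, ty]]))
        pts = np.array(data)
        out = apply_affine(pts, t)
        for i in range(len(pts) - 1):
            before = np.hypot(*(pts[i] - pts[i + 1]))
            after = np.hypot(*(out[i] - out[i + 1]))
            assert after == pytest.approx(before, abs=1e-9)

    def test_vectorized_equals_per_point(self):
        rng = np.random.default_rng(5)
        t = AffineTransform(np.array([[0.6, -0.8, 3.0], [0.8, 0.6, -7.0]]))
        pts = rng.normal(size=(40, 2))
        batch = apply_affine(pts, t)
        singles = np.vstack([apply_affine(p[None, :], t) for p in pts])
        # batched and row-at-a-time matmuls may differ by one ulp
        np.testing.assert_allclose(batch, singles, rtol=1e-15, atol=1e-15)


XML = """<?xml version="1.0"?>
<trakem2>
  <t2_patch title="A1" transform="matrix(1,0,0,1,0,0)"/>
  <t2_patch title="B1" data="matrix(0,1,-1,0,50,0)"/>
</trakem2>
"""


class TestTransformParsing:
    def test_identity_entry(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(XML)
        t = parse_transform_xml(p, ["A1"])["A1"]
        np.testing.assert_array_equal(t.matrix, [[1, 0, 0], [0, 1, 0]])

    def test_trakem2_parameter_order(self, tmp_path):
        # matrix(0,1,-1,0,50,0) -> [[0,-1,50],[1,0,0]]: (1,0)->(50,1), (0,1)->(49,0)
        p = tmp_path / "t.xml"
        p.write_text(XML)
        t = parse_transform_xml(p, ["B1"])["B1"]
        np.testing.assert_array_equal(t.matrix, [[0, -1, 50], [1, 0, 0]])
        np.testing.assert_allclose(apply_affine([[1.0, 0.0]], t), [[50.0, 1.0]])
        np.testing.assert_allclose(apply_affine([[0.0, 1.0]], t), [[49.0, 0.0]])

    def test_missing_member_is_named(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(XML)
        with pytest.raises(ValueError, match="D1"):
            parse_transform_xml(p, ["A1", "D1"])

    def test_malformed_matrix_string(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text('<x><e title="A1" transform="matrix(1,2)"/></x>')
        with pytest.raises(ValueError, match="malformed"):
            parse_transform_xml(p, ["A1"])

    def test_plain_table_with_comments(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("# planted transforms\nA1 1 0 0 1 0 0\nB1 0 1 -1 0 50 0\n")
        got = parse_transform_table(p, ["A1", "B1"])
        np.testing.assert_array_equal(got["B1"].matrix, [[0, -1, 50], [1, 0, 0]])

    def test_dispatch_by_content(self, tmp_path):
        x = tmp_path / "t.xml"
        x.write_text(XML)
        t = tmp_path / "t.txt"
        t.write_text("A1 1 0 0 1 0 0\n")
        assert "A1" in parse_transforms(x, ["A1"])
        assert "A1" in parse_transforms(t, ["A1"])


class TestTransformGroupCoords:
    def test_identity_single_area_preserves_fullres_coords(self):
        area = toy_area("a")
        out = transform_group_coords([area], identity_plan([area]))
        np.testing.assert_allclose(
            out["pxl_row_stitched"], area.spots["pxl_row_in_fullres"], atol=1e-9
        )
        np.testing.assert_allclose(
            out["pxl_col_stitched"], area.spots["pxl_col_in_fullres"], atol=1e-9
        )

    def test_translated_duplicate_area_lands_on_landmarks(self):
        # second copy of the same grid translated by one spot pitch in x
        # (in the rescaled-hires space): landmark spots must coincide
        a, b = toy_area("a"), toy_area("b")
        pitch = 55.0 * 100.0 / 55.0
        h = a.scalefactors.tissue_hires_scalef
        plan = identity_plan([a, b])
        plan.transforms["b"] = AffineTransform(
            np.array([[1, 0, pitch * h], [0, 1, 0]], dtype=float)
        )
        out = transform_group_coords([a, b], plan)
        xa = out[out["area_id"] == "a"].set_index("barcode")
        xb = out[out["area_id"] == "b"].set_index("barcode")
        # spot (r, c) of b must coincide with spot (r, c+2) of a
        moved = xb.loc["S02X02-1"]
        target = xa.loc["S02X04-1"]
        assert moved["pxl_col_stitched"] == pytest.approx(
            target["pxl_col_stitched"], abs=1e-6
        )
        assert moved["pxl_row_stitched"] == pytest.approx(
            target["pxl_row_stitched"], abs=1e-6
        )

    def test_half_turn_maps_grid_onto_itself(self):
        # 180-degree rotation about the grid's own center permutes the
        # lattice: every rotated spot must coincide with some original spot
        a, b = toy_area("a", n_rows=7, n_cols=9), toy_area("b", n_rows=7, n_cols=9)
        h = a.scalefactors.tissue_hires_scalef
        xy = a.spots[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
        center = (xy.min(axis=0) + xy.max(axis=0)) / 2.0 * h
        plan = identity_plan([a, b])
        plan.transforms["b"] = AffineTransform(
            np.array([[-1, 0, 2 * center[0]], [0, -1, 2 * center[1]]], dtype=float)
        )
        out = transform_group_coords([a, b], plan)
        pa = out[out["area_id"] == "a"][["pxl_col_stitched", "pxl_row_stitched"]].to_numpy()
        pb = out[out["area_id"] == "b"][["pxl_col_stitched", "pxl_row_stitched"]].to_numpy()
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(pa).query(pb)
        assert dist.max() < 1e-6

    def test_matches_per_spot_scalar_pipeline(self):
        # brute-force oracle: one spot at a time, plain floats
        a = toy_area("a", d=80.0, h=0.11, n_rows=5, n_cols=7)
        b = toy_area("b", d=100.0, h=0.09, n_rows=5, n_cols=7)
        plan = identity_plan([a, b])
        plan.transforms["b"] = AffineTransform(
            np.array([[0, -1, 40.0], [1, 0, 13.0]], dtype=float)
        )
        out = transform_group_coords([a, b], plan)
        ref = plan.rescale.lift[plan.rescale.reference_area]
        k = 0
        for area in (a, b):
            lift = plan.rescale.lift[area.area_id]
            m = plan.transforms[area.area_id].matrix
            for _, spot in area.spots.iterrows():
                x = spot["pxl_col_in_fullres"] * lift
                y = spot["pxl_row_in_fullres"] * lift
                gx = (m[0, 0] * x + m[0, 1] * y + m[0, 2]) / ref
                gy = (m[1, 0] * x + m[1, 1] * y + m[1, 2]) / ref
                assert out.at[k, "pxl_col_stitched"] == pytest.approx(gx, abs=1e-9)
                assert out.at[k, "pxl_row_stitched"] == pytest.approx(gy, abs=1e-9)
                k += 1

    def test_pitch_homogenized_across_heterogeneous_areas(self):
        # different d and h per area: post-transform nearest-neighbor
        # distances must agree across areas to 1e-6 relative
        a = toy_area("a", d=80.0, h=0.11)
        b = toy_area("b", d=100.0, h=0.09)
        plan = identity_plan([a, b])
        plan.transforms["b"] = AffineTransform(
            np.array([[1, 0, 5000.0], [0, 1, 0]], dtype=float)
        )
        out = transform_group_coords([a, b], plan)
        from scipy.spatial import cKDTree

        medians = []
        for area_id in ("a", "b"):
            pts = out[out["area_id"] == area_id][
                ["pxl_col_stitched", "pxl_row_stitched"]
            ].to_numpy()
            d_nn, _ = cKDTree(pts).query(pts, k=2)
            medians.append(np.median(d_nn[:, 1]))
        assert medians[0] == pytest.approx(medians[1], rel=1e-6)

    def test_area_missing_from_plan_rejected(self):
        a, b = toy_area("a"), toy_area("b")
        plan = identity_plan([a])
        with pytest.raises(ValueError, match="b"):
            transform_group_coords([a, b], plan)

    def test_plan_requires_transform_per_member(self):
        a = toy_area("a")
        plan = identity_plan([a])
        with pytest.raises(ValueError, match="ghost"):
            GroupPlan(
                group_id="g",
                members=["a", "ghost"],
                transforms=plan.transforms,
                rescale=plan.rescale,
            )
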