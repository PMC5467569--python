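"""Axis fields, colourmaps, cardinal planes, limb axes, symmetry."""

import numpy as np
import pytest

import straightax as sx
from straightax.axes import PlaneSpec, normalized_ap

from .conftest import tube_mask
from .oracles import dijkstra_distances
from .test_cdt import tube_landmarks


@pytest.fixture(scope="module")
def identity_transform():
    m = tube_mask((12, 12, 20))
    names, pts = tube_landmarks(m)
    return sx.fit_cdt(sx.LandmarkSet(names, pts, pts.copy()), m, m)


class TestStraightFields:
    def test_fields_are_world_coordinates(self):
        m = tube_mask((10, 10, 12), origin=(-4.0, -4.0, 0.0))
        f = sx.straight_axis_fields(m)
        # a voxel at world (3, -2, 7): index (7, 2, 7)
        assert m.data[7, 2, 7] == 1
        assert f.ap.data[7, 2, 7] == 7.0
        assert f.dv.data[7, 2, 7] == -2.0
        assert f.lr.data[7, 2, 7] == 3.0
        assert f.ml.data[7, 2, 7] == 3.0

    def test_ap_spans_mask_z_extent_and_ml_nonnegative(self):
        m = tube_mask((10, 10, 12))
        f = sx.straight_axis_fields(m)
        mb = m.data.astype(bool)
        assert f.ap.data[mb].min() == 0.0
        assert f.ap.data[mb].max() == 11.0
        assert (f.ml.data[mb] >= 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sx.straight_axis_fields(sx.Volume(np.zeros((4, 4, 4), dtype=np.uint8)))

    def test_unknown_axis_name_lists_valid_names(self):
        f = sx.straight_axis_fields(tube_mask())
        with pytest.raises(ValueError, match="ap"):
            f.get("pa")


class TestCurvedFields:
    def test_identity_transform_reproduces_straight_fields(self, identity_transform):
        t = identity_transform
        fc = sx.curved_axis_fields(t)
        fs = sx.straight_axis_fields(t.target_mask)
        mb = t.source_mask.data.astype(bool)
        for ax in ("ap", "dv", "lr"):
            np.testing.assert_allclose(
                fc.get(ax).data[mb], fs.get(ax).data[mb], atol=1e-9
            )

    def test_recovered_fields_close_to_phantom_truth(self, bundle, fields):
        tr = bundle.truth_axis_fields
        mb = bundle.curved_mask.data.astype(bool)
        for ax, tol in (("ap", 3.0), ("dv", 3.0), ("lr", 3.0)):
            e = fields.get(ax).data[mb] - tr.get(ax).data[mb]
            assert np.sqrt(np.mean(e**2)) <= tol

    def test_lr_changes_sign_across_midline_plane(self, bundle, fields):
        rng = np.random.default_rng(3)
        mb = bundle.curved_mask.data.astype(bool)
        truth = bundle.truth_axis_fields.lr.data
        rec = fields.lr.data
        off = mb & (np.abs(truth) > 1.0)
        sel = np.argwhere(off)
        sel = sel[rng.choice(len(sel), 500, replace=False)]
        agree = np.sign(rec[tuple(sel.T)]) == np.sign(truth[tuple(sel.T)])
        assert agree.mean() >= 0.98

    def test_normalized_ap_spans_unit_interval(self, fields):
        nap = normalized_ap(fields)
        mb = fields.mask.data.astype(bool)
        assert nap.data[mb].min() == 0.0 and nap.data[mb].max() == 1.0


class TestColourmap:
    def test_ramp_endpoints_and_midpoint(self):
        m = sx.Volume(np.ones((3, 1, 1), dtype=np.uint8))
        f = m.with_data(np.array([0.0, 5.0, 10.0]).reshape(3, 1, 1))
        rgb = sx.axis_colourmap(f, m)
        assert tuple(rgb[0, 0, 0]) == (255, 0, 0)      # min -> pure red
        assert tuple(rgb[2, 0, 0]) == (0, 0, 255)      # max -> pure blue
        r, g, bl = rgb[1, 0, 0]
        assert abs(int(r) - int(bl)) <= 1 and g == 0   # midpoint -> equal mix

    def test_monotone_field_gives_monotone_hue(self):
        m = sx.Volume(np.ones((10, 1, 1), dtype=np.uint8))
        f = m.with_data(np.linspace(0, 1, 10).reshape(10, 1, 1))
        rgb = sx.axis_colourmap(f, m)
        blue = rgb[:, 0, 0, 2].astype(int)
        assert np.all(np.diff(blue) >= 0)
        rev = sx.axis_colourmap(f, m, reverse=True)
        assert np.all(np.diff(rev[:, 0, 0, 2].astype(int)) <= 0)

    def test_constant_field_warns_and_is_mid_ramp(self):
        m = sx.Volume(np.ones((3, 3, 3), dtype=np.uint8))
        with pytest.warns(UserWarning, match="constant"):
            rgb = sx.axis_colourmap(m.with_data(np.full((3, 3, 3), 2.0)), m)
        assert abs(int(rgb[1, 1, 1, 0]) - int(rgb[1, 1, 1, 2])) <= 1

    def test_out_of_mask_is_black(self):
        m = sx.Volume(np.zeros((3, 3, 3), dtype=np.uint8))
        m.data[1, 1, 1] = 1
        m.data[0, 0, 0] = 1
        rgb = sx.axis_colourmap(m.with_data(m.data.astype(float)), m)
        assert tuple(rgb[2, 2, 2]) == (0, 0, 0)


class TestCardinalPlanes:
    def test_identity_transverse_plane_is_a_slice(self, identity_transform):
        t = identity_transform
        rng = np.random.default_rng(1)
        v = sx.Volume(rng.random(t.source_mask.shape), t.source_mask.spacing,
                      t.source_mask.origin)
        ext = sx.extract_cardinal_plane(t, PlaneSpec("transverse", 5.0), v)
        mb = t.source_mask.data[:, :, 5].astype(bool)
        np.testing.assert_allclose(ext.image[mb], v.data[:, :, 5][mb], atol=1e-6)

    def test_transverse_plane_orthogonal_to_phantom_midline(self, bundle, transform):
        """Inverse-mapped transverse planes must meet the curved midline
        within 10 degrees of perpendicular to the local tangent."""
        L = bundle.geometry.L
        for frac in (0.3, 0.5, 0.7):
            ext = sx.extract_cardinal_plane(
                transform, PlaneSpec("transverse", frac * L), bundle.curved_volume
            )
            pts = ext.points[ext.in_mask]
            centred = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            normal = vt[-1]
            tangent = bundle.geometry.tangent(frac)
            cosang = abs(float(normal @ tangent))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 10.0

    def test_sagittal_midplane_contains_the_midline(self, bundle, transform):
        ext = sx.extract_cardinal_plane(
            transform, PlaneSpec("sagittal", 0.0), bundle.curved_volume
        )
        pts = ext.points[ext.in_mask]
        # every interior midline point has a plane sample within 1 voxel;
        # the cap extremes are extrapolation zones, allowed 2 voxels
        for mp in bundle.midline_points[8:-8:8]:
            assert np.min(np.linalg.norm(pts - mp, axis=1)) <= 1.0
        for mp in (bundle.midline_points[0], bundle.midline_points[-1]):
            assert np.min(np.linalg.norm(pts - mp, axis=1)) <= 2.0

    def test_plane_outside_mask_warns_and_is_empty(self, identity_transform):
        with pytest.warns(UserWarning, match="misses"):
            ext = sx.extract_cardinal_plane(
                identity_transform,
                PlaneSpec("transverse", 500.0),
                sx.Volume(
                    np.zeros(identity_transform.source_mask.shape),
                    identity_transform.source_mask.spacing,
                    identity_transform.source_mask.origin,
                ),
            )
        assert ext.empty

    def test_unknown_plane_kind_rejected(self):
        with pytest.raises(ValueError, match="transverse"):
            PlaneSpec("axial", 3.0)


class TestLimbPdField:
    def test_straight_cylinder_equals_axial_distance(self):
        m = tube_mask((9, 9, 16), radius=2.5)
        base = (4.0, 4.0, 0.0)
        pd = sx.limb_pd_field(m, base)
        assert pd.data[4, 4, 0] == 0.0
        for z in (3, 8, 14):
            assert pd.data[4, 4, z] == pytest.approx(float(z), rel=0.13)

    def test_bent_limb_matches_dijkstra_oracle(self):
        # an L-shaped limb
        m = np.zeros((12, 6, 12), dtype=np.uint8)
        m[2:5, 1:5, 1:10] = 1
        m[2:10, 1:5, 7:10] = 1
        vol = sx.Volume(m)
        base_idx = (3, 2, 1)
        pd = sx.limb_pd_field(vol, vol.index_to_world(np.array(base_idx)))
        oracle = dijkstra_distances(m, (1, 1, 1), [base_idx])
        np.testing.assert_allclose(pd.data, oracle, atol=1e-9)


class TestSymmetryCheck:
    def test_mirrored_phantom_limb_tips_agree(self, bundle):
        left = [l for l in bundle.limbs if l.spec.side == "left"]
        right = [l for l in bundle.limbs if l.spec.side == "right"]
        pairs = [
            (l.curved_tip - l.direction, r.curved_tip - r.direction)
            for l, r in zip(left, right)
        ]
        rep = sx.symmetry_check(bundle.truth_axis_fields, pairs, tolerance=1.0)
        assert rep["ok"].all()

    def test_same_point_twice_gives_twice_lr(self, bundle):
        p = bundle.geometry.midline(0.5) + np.array([4.0, 0.0, 0.0])
        rep = sx.symmetry_check(bundle.truth_axis_fields, [(p, p)])
        lr = bundle.truth_axis_fields.sample_nearest("lr", p)[0]
        assert rep["d_lr_mirror"][0] == pytest.approx(2 * abs(lr))

    def test_symmetric_straddling_pair_is_antisymmetric(self, bundle):
        c = bundle.geometry.midline(0.5)
        # half-integer offset: the even-sized grid has voxel centres at
        # x = +-0.5, +-1.5, ... so +-4.5 is grid-symmetric about x=0
        off = np.array([4.5, 0.0, 0.0])
        rep = sx.symmetry_check(bundle.truth_axis_fields, [(c - off, c + off)])
        assert rep["d_lr_mirror"][0] <= 1e-9
        assert rep["ok"][0]
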