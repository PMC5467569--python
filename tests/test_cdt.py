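"""Deformation model: exact interpolation, affine reproduction,
invertibility, resampling, subdivision, serialization."""

import warnings

import numpy as np
import pytest

import straightax as sx
from straightax.cdt import CdtModel, CdtParams, subdivide_landmarks

from .conftest import c_mask, tube_mask
from .oracles import dijkstra_path


def tube_landmarks(mask, n_axial=4):
    """Landmark scaffold on a small cylinder: axis + surface points,
    placed on voxel centres so interpolation conditions are exact."""
    shape = mask.shape
    cx, cy = float(shape[0] // 2), float(shape[1] // 2)
    zs = np.linspace(1, shape[2] - 2, n_axial).round()
    names, pts = [], []
    for i, z in enumerate(zs):
        names.append(f"ax-{i}")
        pts.append((cx, cy, z))
        names.append(f"sx-{i}")
        pts.append((cx + 3, cy, z))
        names.append(f"sy-{i}")
        pts.append((cx, cy + 3, z))
    return names, np.array(pts, dtype=float)


class TestForwardFit:
    def test_translation_reproduced_everywhere(self):
        m = tube_mask()
        names, pts = tube_landmarks(m)
        t_vec = np.array([0.5, -1.0, 2.0])
        ls = sx.LandmarkSet(names, pts, pts + t_vec)
        t = sx.fit_cdt(ls, m, m)
        rng = np.random.default_rng(0)
        nodes = np.argwhere(m.data.astype(bool))
        q = m.index_to_world(nodes[rng.choice(len(nodes), 50, replace=False)])
        np.testing.assert_allclose(t.transform_points(q), q + t_vec, atol=1e-9)

    def test_exact_interpolation_at_zero_regularization(self, bundle, transform):
        assert transform.fit_residual <= 1e-6 * min(bundle.curved_mask.spacing)
        mapped = transform.transform_points(bundle.landmarks.source_points)
        err = np.linalg.norm(mapped - bundle.landmarks.target_points, axis=1)
        assert err.max() <= 1e-6 * min(bundle.curved_mask.spacing)

    def test_affine_reproduction_on_small_tube(self):
        m = tube_mask((14, 14, 20), radius=5.0)
        names, pts = tube_landmarks(m)
        rng = np.random.default_rng(2)
        A = np.eye(3) + rng.uniform(-0.08, 0.08, (3, 3))
        assert np.linalg.cond(A) < 5
        b = rng.uniform(-1, 1, 3)
        ls = sx.LandmarkSet(names, pts, pts @ A.T + b)
        t = sx.fit_cdt(ls, m, m)
        nodes = np.argwhere(m.data.astype(bool))
        nodes = nodes[(nodes[:, 2] > 0) & (nodes[:, 2] < m.shape[2] - 1)]
        q = m.index_to_world(nodes[rng.choice(len(nodes), 200, replace=False)])
        q = q + rng.uniform(-0.4, 0.4, q.shape)
        keep = m.data.astype(bool)[tuple(m.world_to_nearest_index(q).T)]
        err = np.linalg.norm(t.transform_points(q[keep]) - (q[keep] @ A.T + b), axis=1)
        assert err.max() <= 1e-5

    def test_too_few_or_coplanar_landmarks_rejected(self):
        m = tube_mask()
        with pytest.raises(ValueError, match="at least 4"):
            CdtModel(
                sx.LandmarkSet(["a", "b", "c"], np.eye(3) + 4.0, np.eye(3) + 4.0), m, m
            )
        coplanar = np.array([[4, 4, z] for z in range(4, 16, 3)], dtype=float)
        with pytest.raises(ValueError, match="coplanar"):
            CdtModel(
                sx.LandmarkSet([f"p{i}" for i in range(4)], coplanar, coplanar), m, m
            )

    def test_straightening_pulls_midline_onto_axis(self, bundle, transform):
        mapped = transform.transform_points(bundle.midline_points)
        rms = np.sqrt(np.mean(mapped[:, 0] ** 2 + mapped[:, 1] ** 2))
        assert rms <= 2.0


class TestInvertibility:
    def test_round_trip_mean_within_tolerance(self, bundle, transform):
        rng = np.random.default_rng(1)
        m = bundle.curved_mask.data.astype(bool)
        nodes = np.argwhere(m)
        pts = bundle.curved_mask.index_to_world(
            nodes[rng.choice(len(nodes), 1000, replace=False)]
        )
        back = transform.transform_points(transform.transform_points(pts), inverse=True)
        err = np.linalg.norm(back - pts, axis=1)
        eps = 0.5 * min(bundle.curved_mask.spacing)
        assert err.mean() <= eps

    def test_round_trip_tail_on_fold_free_fit(self, bundle_quarter, transform_quarter):
        """Where the forward field is fold-free (quarter-turn phantom),
        99% of points must round-trip within the inversion tolerance."""
        rng = np.random.default_rng(2)
        m = bundle_quarter.curved_mask.data.astype(bool)
        nodes = np.argwhere(m)
        pts = bundle_quarter.curved_mask.index_to_world(
            nodes[rng.choice(len(nodes), 1000, replace=False)]
        )
        t = transform_quarter
        back = t.transform_points(t.transform_points(pts), inverse=True)
        err = np.linalg.norm(back - pts, axis=1)
        eps = 0.5 * min(bundle_quarter.curved_mask.spacing)
        assert np.mean(err <= eps) >= 0.99

    def test_identity_landmarks_give_identity_transform(self):
        m = tube_mask()
        names, pts = tube_landmarks(m)
        t = sx.fit_cdt(sx.LandmarkSet(names, pts, pts.copy()), m, m)
        rng = np.random.default_rng(5)
        nodes = np.argwhere(m.data.astype(bool))
        q = m.index_to_world(nodes[rng.choice(len(nodes), 40, replace=False)])
        np.testing.assert_allclose(t.transform_points(q), q, atol=1e-9)
        np.testing.assert_allclose(t.transform_points(q, inverse=True), q, atol=1e-6)


class TestTransformPoints:
    def test_point_far_outside_mask_rejected_with_index(self, transform):
        inside = transform.landmarks.source_points[:1]
        far = np.array([[500.0, 500.0, 500.0]])
        with pytest.raises(ValueError, match="0"):
            transform.transform_points(np.vstack([far]))
        # in-mask points pass
        transform.transform_points(inside)


class TestApplyTransform:
    def test_identity_restricts_to_mask(self):
        m = tube_mask()
        names, pts = tube_landmarks(m)
        t = sx.fit_cdt(sx.LandmarkSet(names, pts, pts.copy()), m, m)
        rng = np.random.default_rng(0)
        v = sx.Volume(rng.random(m.shape), m.spacing, m.origin)
        out = t.apply(v)
        mb = m.data.astype(bool)
        np.testing.assert_allclose(out.data[mb], v.data[mb], atol=1e-9)
        assert np.all(out.data[~mb] == 0)

    def test_nearest_interpolation_keeps_mask_binary(self, bundle, transform):
        out = transform.apply(bundle.midline_expression.with_data(
            (bundle.midline_expression.data > 0).astype(np.uint8)
        ), interpolation="nearest")
        assert set(np.unique(out.data)).issubset({0, 1})

    def test_straightened_midline_expression_hugs_the_axis(self, bundle, transform):
        out = transform.apply(bundle.midline_expression)
        hits = np.argwhere(out.data > 100.0)
        w = out.index_to_world(hits)
        r = np.sqrt(w[:, 0] ** 2 + w[:, 1] ** 2)
        assert (r <= 2.0).mean() >= 0.90

    def test_grid_mismatch_rejected(self, transform):
        v = sx.Volume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError, match="grid"):
            transform.apply(v)


class TestSubdivision:
    def test_axis_aligned_midpoint(self):
        m = tube_mask((10, 10, 16))
        ls = sx.LandmarkSet(
            ["mid-0", "mid-1"],
            np.array([[4.5, 4.5, 2.0], [4.5, 4.5, 12.0]]),
            np.array([[4.5, 4.5, 2.0], [4.5, 4.5, 12.0]]),
        )
        out = subdivide_landmarks(ls, m, m)
        assert len(out) == 3
        mid = out.source_points[1]
        assert abs(mid[2] - 7.0) <= 0.5

    def test_identity_phantom_midpoints_are_identity_pairs(self, identity_bundle):
        b = identity_bundle
        ls = sx.LandmarkSet(
            ["mid-0", "mid-1"],
            b.geometry.midline(np.array([0.3, 0.5])),
            b.geometry.straight_midline(np.array([0.3, 0.5])),
        )
        out = subdivide_landmarks(ls, b.curved_mask, b.straight_mask)
        ins = [i for i, n in enumerate(out.names) if "+sub" in n]
        assert ins
        np.testing.assert_allclose(
            out.source_points[ins], out.target_points[ins], atol=1e-9
        )

    def test_c_mask_midpoint_lies_on_shortest_path(self):
        m = c_mask(24)
        nodes = np.argwhere(m.data)
        top = nodes[nodes[:, 1] > 16]
        a = top[np.argmin(top[:, 0])]
        b = top[np.argmax(top[:, 0])]
        ls = sx.LandmarkSet(
            ["arm-0", "arm-1"],
            m.index_to_world(np.vstack([a, b])).astype(float),
            m.index_to_world(np.vstack([a, b])).astype(float),
        )
        out = subdivide_landmarks(ls, m, m)
        mid = out.source_points[1]
        path = dijkstra_path(m.data, m.spacing, a, b)
        path_w = m.index_to_world(path)
        assert np.min(np.linalg.norm(path_w - mid, axis=1)) <= 1.0

    def test_refinement_does_not_exceed_noise_floor(self):
        """Subdividing a coarse landmark set keeps the midline-straightening
        RMS at or below max(base RMS, 1 voxel): refinement is monotone down
        to the geodesic-midpoint discretisation noise."""
        b = sx.make_phantom(sx.default_config(seed=0, n_landmarks=12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            def midline_rms(ls):
                t = sx.fit_cdt(ls, b.curved_mask, b.straight_mask)
                mp = t.transform_points(b.midline_points)
                return float(np.sqrt(np.mean(mp[:, 0] ** 2 + mp[:, 1] ** 2)))

            base = midline_rms(b.landmarks)
            refined = midline_rms(
                subdivide_landmarks(b.landmarks, b.curved_mask, b.straight_mask)
            )
        assert refined <= max(base, 1.0)

    def test_disconnected_pair_raises_with_name(self):
        m = tube_mask((10, 10, 16))
        m.data[:, :, 8] = 0
        ls = sx.LandmarkSet(
            ["mid-0", "mid-1"],
            np.array([[4.5, 4.5, 2.0], [4.5, 4.5, 14.0]]),
            np.array([[4.5, 4.5, 2.0], [4.5, 4.5, 14.0]]),
        )
        with pytest.raises(ValueError, match="mid-0"):
            subdivide_landmarks(ls, m, m)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, transform):
        d = tmp_path / "tf"
        transform.save(d)
        back = sx.CdtTransform.load(d)
        np.testing.assert_array_equal(back.forward_field, transform.forward_field)
        np.testing.assert_array_equal(back.inverse_field, transform.inverse_field)
        assert back.landmarks == transform.landmarks
        assert back.fit_residual == transform.fit_residual
        assert back.delta == transform.delta

    def test_summary_mentions_key_diagnostics(self, transform):
        s = transform.summary()
        assert "landmarks" in s and "round-trip" in s and "residual" in s
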