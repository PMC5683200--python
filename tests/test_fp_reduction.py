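import numpy as np
import pytest

from itrst.candidates import CandidateRegion
from itrst.fp_reduction import (
    FROCPoint,
    GroundTruthNode,
    TrainingPolicy,
    apply_classifier,
    axis_lengths,
    extract_features,
    feature_names,
    froc_evaluate,
    label_candidates,
    loo_cross_validation,
    train_classifier,
)
from itrst.volume import Volume3D


def _region_from_mask(mask, spacing=0.5, label=1):
    coords = np.argwhere(mask)
    return CandidateRegion(
        label=label,
        coords=coords,
        centroid_mm=coords.mean(axis=0) * spacing,
        volume_mm3=float(len(coords) * spacing**3),
        grid_shape=mask.shape,
    )


def _ball(shape, center, radius_mm, spacing=0.5):
    grids = np.meshgrid(*[np.arange(n) * spacing for n in shape], indexing="ij")
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius_mm**2


class TestFeatures:
    spacing = 0.5

    def _ball_candidate(self, radius_mm=5.0):
        shape = (40, 40, 40)
        mask = _ball(shape, (10, 10, 10), radius_mm, self.spacing)
        vol = Volume3D(np.full(shape, 55.0), (self.spacing,) * 3)
        return _region_from_mask(mask, self.spacing), vol

    def test_digital_ball_geometry(self):
        cand, vol = self._ball_candidate()
        f = extract_features(cand, vol, None, D=(0.0,))
        analytic = 4 / 3 * np.pi * 5.0**3
        assert f[0] == pytest.approx(analytic, rel=0.05)  # u1 volume
        # voxel-face surface overestimates the smooth sphere (~1.5x),
        # and sphericity uses it in the denominator
        assert 0.5 < f[2] <= 1.0  # u3 sphericity
        assert f[3] == pytest.approx(5.0, rel=0.15)  # u4 max interior distance
        assert f[4] == pytest.approx(10.0, rel=0.1)  # u5 long axis
        assert f[5] == pytest.approx(10.0, rel=0.1)  # u6 short axis
        assert f[5] <= f[4] + 1e-9

    def test_constant_intensity_degenerate_moments(self):
        cand, vol = self._ball_candidate()
        f = extract_features(cand, vol, None, D=(0.0,))
        avg, var, med, mx, mn, skew, kurt = f[9:16]
        assert avg == med == mx == mn == 55.0
        assert var == skew == kurt == 0.0

    def test_vector_length_and_names(self):
        cand, vol = self._ball_candidate(radius_mm=3.0)
        f = extract_features(cand, vol, None, D=(0.0, 1.0, 2.0))
        assert len(f) == 30
        assert len(feature_names((0, 1, 2))) == 30
        assert np.all(np.isfinite(f))

    def test_dilated_region_sees_surroundings(self):
        shape = (40, 40, 40)
        vals = np.zeros(shape)
        mask = _ball(shape, (10, 10, 10), 4.0, self.spacing)
        vals[mask] = 100.0  # region bright, surroundings 0
        vol = Volume3D(vals, (self.spacing,) * 3)
        cand = _region_from_mask(mask, self.spacing)
        f0 = extract_features(cand, vol, None, D=(0.0,))
        f2 = extract_features(cand, vol, None, D=(2.0,))
        assert f0[9] == pytest.approx(100.0)
        assert f2[9] < f0[9]  # dilation pulls in dark neighbours
        assert f2[13] == 0.0  # minimum now from outside the ball

    def test_normalised_y_uses_lung_bounding_box(self):
        cand, vol = self._ball_candidate()
        lung = np.zeros(vol.shape, dtype=bool)
        lung[:, 4:37, :] = True  # y range 2 .. 18 mm; centroid y = 10 mm
        f = extract_features(cand, vol, lung, D=(0.0,))
        y0, y1 = 4 * self.spacing, 36 * self.spacing
        assert f[7] == pytest.approx((10.0 - y0) / (y1 - y0), abs=0.02)

    def test_empty_candidate_rejected(self):
        vol = Volume3D(np.zeros((8, 8, 8)))
        cand = CandidateRegion(1, np.empty((0, 3), dtype=int),
                               np.zeros(3), 0.0, (8, 8, 8))
        with pytest.raises(ValueError):
            extract_features(cand, vol, None)

    def test_axis_lengths_of_elongated_box(self):
        coords = np.argwhere(np.ones((21, 5, 5))) * 0.5
        long_ax, short_ax = axis_lengths(coords)
        assert long_ax == pytest.approx(10.0, abs=0.1)
        assert short_ax == pytest.approx(2.0, abs=0.1)


class TestLabeling:
    def _setup(self, short_axis):
        shape = (30, 30, 30)
        node_mask = _ball(shape, (7.5, 7.5, 7.5), short_axis / 2, 0.5)
        node = GroundTruthNode(np.argwhere(node_mask), short_axis, short_axis, shape)
        inside = _region_from_mask(_ball(shape, (7.5, 7.5, 7.5), 2.0, 0.5))
        outside = _region_from_mask(_ball(shape, (12.0, 12.0, 12.0), 2.0, 0.5))
        return [inside, outside], [node]

    def test_candidate_inside_target_node_positive(self):
        cands, nodes = self._setup(short_axis=10.0)
        policy = TrainingPolicy(r_target=10.0, w_train=0.5)
        labels = label_candidates(cands, nodes, policy)
        assert labels.tolist() == [True, False]

    def test_node_below_training_threshold_gives_negative(self):
        cands, nodes = self._setup(short_axis=4.0)  # 0.4 * r_target
        policy = TrainingPolicy(r_target=10.0, w_train=0.5)
        labels = label_candidates(cands, nodes, policy)
        assert labels.tolist() == [False, False]


class TestClassifier:
    def _separable(self, rng, n=40):
        pos = rng.normal(loc=(3, 3), scale=0.3, size=(n, 2))
        neg = rng.normal(loc=(-3, -3), scale=0.3, size=(n, 2))
        x = np.vstack([pos, neg])
        y = np.array([True] * n + [False] * n)
        return x, y

    def test_separable_data_fully_fit(self, rng):
        x, y = self._separable(rng)
        state = train_classifier(x, y, w_F=0.5)
        assert (state.pipeline.predict(x) == y).all()

    def test_duplication_invariance_on_separable_data(self, rng):
        x, y = self._separable(rng)
        # large C: the hard-margin solution is unaffected by sample
        # duplication (which otherwise just rescales the soft penalty)
        a = train_classifier(x, y, w_F=0.5, C=1e4)
        b = train_classifier(np.vstack([x, x]), np.concatenate([y, y]),
                             w_F=0.5, C=1e4)
        grid = rng.normal(scale=3.0, size=(50, 2))
        da = a.pipeline.decision_function(grid)
        db = b.pipeline.decision_function(grid)
        assert np.allclose(da, db, atol=1e-6)

    def test_vanishing_negative_weight_predicts_all_positive(self, rng):
        # overlapping classes: with the negative class nearly free the
        # decision collapses to the positive side
        pos = rng.normal(loc=0.3, scale=1.0, size=(60, 2))
        neg = rng.normal(loc=-0.3, scale=1.0, size=(60, 2))
        x = np.vstack([pos, neg])
        y = np.array([True] * 60 + [False] * 60)
        state = train_classifier(x, y, w_F=1e-4)
        assert state.pipeline.predict(x).all()

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_classifier(x, np.ones(10, dtype=bool), w_F=0.5)

    def test_apply_no_candidates(self, rng):
        x, y = self._separable(rng)
        state = train_classifier(x, y, w_F=0.5)
        mask, kept = apply_classifier(state, [], np.empty((0, 2)), (5, 5, 5))
        assert kept == [] and not mask.any()

    def test_apply_mask_is_union_of_kept(self, rng):
        x, y = self._separable(rng, n=3)
        state = train_classifier(x, y, w_F=0.5)
        shape = (20, 20, 20)
        regions = [
            _region_from_mask(_ball(shape, (3, 3, 3), 1.5, 0.5)),
            _region_from_mask(_ball(shape, (7, 7, 7), 1.5, 0.5)),
        ]
        feats = np.array([[3.0, 3.0], [3.1, 2.9]])  # both clearly positive
        mask, kept = apply_classifier(state, regions, feats)
        assert len(kept) == 2
        union = regions[0].mask() | regions[1].mask()
        assert np.array_equal(mask, union)

    def test_feature_length_mismatch_rejected(self, rng):
        x, y = self._separable(rng)
        state = train_classifier(x, y, w_F=0.5)
        region = _region_from_mask(_ball((10, 10, 10), (2, 2, 2), 1.0, 0.5))
        with pytest.raises(ValueError):
            apply_classifier(state, [region], np.zeros((1, 5)))


def _gt(shape, center, radius_mm, short_axis, spacing=0.5):
    mask = _ball(shape, center, radius_mm, spacing)
    return GroundTruthNode(np.argwhere(mask), short_axis, short_axis, shape)


class TestFROC:
    shape = (40, 40, 40)

    def test_all_targets_hit_no_extras(self):
        node = _gt(self.shape, (5, 5, 5), 3.0, 10.0)
        det = _region_from_mask(_ball(self.shape, (5, 5, 5), 2.0, 0.5))
        pt = froc_evaluate([[det]], [[node]], r_target=10.0)
        assert (pt.rate_mean, pt.fps_mean) == (1.0, 0.0)

    def test_no_detections(self):
        node = _gt(self.shape, (5, 5, 5), 3.0, 10.0)
        pt = froc_evaluate([[]], [[node]], r_target=10.0)
        assert (pt.rate_mean, pt.fps_mean) == (0.0, 0.0)

    def test_two_targets_one_double_hit_three_misses(self):
        """Two targets; one hit by two regions; three regions
        overlapping nothing -> rate 0.5, 3 FPs."""
        n1 = _gt(self.shape, (5, 5, 5), 3.0, 10.0)
        n2 = _gt(self.shape, (15, 15, 15), 3.0, 10.0)
        hits = [
            _region_from_mask(_ball(self.shape, (5, 5, 5), 1.5, 0.5), label=1),
            _region_from_mask(_ball(self.shape, (6, 5, 5), 1.5, 0.5), label=2),
        ]
        misses = [
            _region_from_mask(_ball(self.shape, (15, 5, 5), 1.5, 0.5), label=3),
            _region_from_mask(_ball(self.shape, (5, 15, 5), 1.5, 0.5), label=4),
            _region_from_mask(_ball(self.shape, (5, 5, 15), 1.5, 0.5), label=5),
        ]
        pt = froc_evaluate([hits + misses], [[n1, n2]], r_target=10.0)
        assert (pt.rate_mean, pt.fps_mean) == (0.5, 3.0)

    def test_subtarget_node_overlap_is_not_fp(self):
        small = _gt(self.shape, (5, 5, 5), 3.0, short_axis=4.0)  # below target
        det = _region_from_mask(_ball(self.shape, (5, 5, 5), 2.0, 0.5))
        pt = froc_evaluate([[det]], [[small]], r_target=10.0)
        assert np.isnan(pt.rate_mean)  # no targets at all
        assert pt.fps_mean == 0.0

    def test_cancer_overlap_is_not_fp(self):
        node = _gt(self.shape, (15, 15, 15), 3.0, 10.0)
        cancer = _ball(self.shape, (5, 5, 5), 3.0, 0.5)
        det = _region_from_mask(_ball(self.shape, (5, 5, 5), 2.0, 0.5))
        pt = froc_evaluate([[det]], [[node]], 10.0, cancer_masks=[cancer])
        assert pt.fps_mean == 0.0

    def test_zero_target_volume_excluded_from_rate(self):
        node = _gt(self.shape, (5, 5, 5), 3.0, 10.0)
        det = _region_from_mask(_ball(self.shape, (5, 5, 5), 2.0, 0.5))
        stray = _region_from_mask(_ball(self.shape, (25, 25, 25), 2.0, 0.5))
        pt = froc_evaluate([[det], [stray]], [[node], []], r_target=10.0)
        assert pt.rate_mean == 1.0  # only volume 0 counts for the rate
        assert pt.fps_mean == 0.5  # volume 1 still contributes its FP

    def test_order_invariance(self, rng):
        nodes = [_gt(self.shape, (5, 5, 5), 3.0, 10.0),
                 _gt(self.shape, (15, 15, 15), 3.0, 10.0)]
        regions = [
            _region_from_mask(_ball(self.shape, c, 1.5, 0.5), label=i)
            for i, c in enumerate([(5, 5, 5), (15, 15, 15), (10, 5, 15)])
        ]
        a = froc_evaluate([regions], [nodes], 10.0)
        perm = [regions[i] for i in rng.permutation(3)]
        b = froc_evaluate([perm], [nodes[::-1]], 10.0)
        assert a == b


class TestLeaveOneOut:
    def _volume_bundle(self, rng):
        shape = (40, 40, 40)
        node = _gt(shape, (5, 5, 5), 3.0, 10.0)
        tp = _region_from_mask(_ball(shape, (5, 5, 5), 2.0, 0.5), label=1)
        fp = _region_from_mask(_ball(shape, (15, 15, 15), 2.0, 0.5), label=2)
        feats = np.array([[3.0 + rng.normal(0, 0.05), 3.0],
                          [-3.0, -3.0 + rng.normal(0, 0.05)]])
        return {"candidates": [tp, fp], "features": feats, "nodes": [node],
                "cancer_mask": None}

    def test_identical_volumes_give_symmetric_folds(self, rng):
        b = self._volume_bundle(rng)
        pts = loo_cross_validation([b, b], TrainingPolicy(10.0, 0.5, 0.5), [0.5])
        assert len(pts) == 1
        assert pts[0].rate_sd == 0.0  # both folds identical

    def test_one_point_per_weight(self, rng):
        b1, b2 = self._volume_bundle(rng), self._volume_bundle(rng)
        pts = loo_cross_validation([b1, b2], TrainingPolicy(10.0, 0.5, 0.5),
                                   [0.1, 0.3, 0.5])
        assert [p.w_F for p in pts] == [0.1, 0.3, 0.5]

    def test_fewer_than_two_volumes_rejected(self, rng):
        with pytest.raises(ValueError):
            loo_cross_validation([self._volume_bundle(rng)],
                                 TrainingPolicy(10.0, 0.5, 0.5), [0.5])


class TestNodesFromLabelVolume:
    def test_rasterises_across_resolutions(self):
        from itrst.fp_reduction import nodes_from_label_volume

        shape = (40, 40, 30)
        spacing = (0.8, 0.8, 1.0)
        grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                            indexing="ij")
        lab = np.zeros(shape, dtype=np.uint8)
        center, r = (16.0, 16.0, 15.0), 4.0
        ball = sum((g - c) ** 2 for g, c in zip(grids, center)) <= r * r
        lab[ball] = 1
        native = Volume3D(lab, spacing)
        fine = Volume3D(np.zeros((51, 51, 48)), (0.625,) * 3)
        nodes = nodes_from_label_volume(native, fine)
        assert len(nodes) == 1
        node = nodes[0]
        assert node.grid_shape == fine.shape
        # volume on the fine grid approximates the native label volume
        native_vol = ball.sum() * np.prod(spacing)
        fine_vol = len(node.coords) * 0.625**3
        assert fine_vol == pytest.approx(native_vol, rel=0.1)
        # the rasterised set is solid: its own bounding box is filled
        # to a sphere-like fraction, not a sparse lattice
        ext = node.coords.max(0) - node.coords.min(0) + 1
        assert len(node.coords) / np.prod(ext) > 0.3
        assert node.short_axis_mm == pytest.approx(2 * r, abs=1.6)

    def test_empty_label_volume(self):
        from itrst.fp_reduction import nodes_from_label_volume

        native = Volume3D(np.zeros((10, 10, 10), dtype=np.uint8))
        assert nodes_from_label_volume(native, Volume3D(np.zeros((10, 10, 10)))) == []
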