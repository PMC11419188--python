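import numpy as np
import pytest

from vcore.phantom import PhantomSpec, generate_phantom_stack
from vcore.preprocess import build_tissue_mask
from vcore.rigid import (
    AlignmentError,
    KeypointSet,
    align_stack_rigid,
    detect_keypoints,
    fit_similarity_robust,
    match_descriptors_ot,
    sinkhorn_with_dustbin,
    MatchSet,
)
from vcore.transforms import SimilarityTransform, rotation_matrix


def _unit_rows(x):
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _kp(positions, descriptors):
    return KeypointSet(np.asarray(positions, float),
                       _unit_rows(np.asarray(descriptors, float)))


class TestDetect:
    def test_flat_image_yields_no_keypoints(self):
        assert len(detect_keypoints(np.full((64, 64), 0.5))) == 0

    def test_phantom_has_keypoints_on_tissue(self, small_stack):
        stack, _ = small_stack
        mask = build_tissue_mask(stack.sections[0]).mask
        kp = detect_keypoints(stack.sections[0], mask=mask)
        assert len(kp) >= 20
        np.testing.assert_allclose(
            np.linalg.norm(kp.descriptors, axis=1), 1.0, atol=1e-9
        )
        rows = np.round(kp.positions[:, 0]).astype(int)
        cols = np.round(kp.positions[:, 1]).astype(int)
        assert mask[rows, cols].all()

    def test_rotated_copy_keypoints_correspond(self, small_stack):
        """At least half the keypoints of a 90-degree rotated image map back
        onto original keypoints within 2 px."""
        stack, _ = small_stack
        img = stack.sections[0]
        kp0 = detect_keypoints(img)
        kp90 = detect_keypoints(np.rot90(img))
        h = img.shape[0]
        # np.rot90: (r, c) -> (c', r') with c' = (W-1) - c ... invert it
        mapped = np.stack([kp90.positions[:, 1],
                           (h - 1) - kp90.positions[:, 0]], axis=1)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(kp0.positions).query(mapped)
        assert (d < 2.0).mean() >= 0.5


class TestOTMatcher:
    def test_identical_sets_match_identically(self, rng):
        desc = _unit_rows(rng.normal(size=(12, 32)))
        kp = _kp(rng.uniform(0, 50, (12, 2)), desc)
        ms = match_descriptors_ot(kp, kp)
        assert ms.n_matched == 12
        np.testing.assert_array_equal(ms.pairs[:, 0], ms.pairs[:, 1])

    def test_dominant_diagonal_two_by_two(self):
        """With strongly dominant diagonal similarity the cheaper of the two
        possible assignments is selected."""
        a = _kp([[0, 0], [10, 10]], [[1, 0, 0], [0, 1, 0]])
        b = _kp([[0, 0], [10, 10]], [[0.99, 0.14, 0], [0.14, 0.99, 0]])
        cost = 1 - a.descriptors @ b.descriptors.T
        assert cost[0, 0] + cost[1, 1] < cost[0, 1] + cost[1, 0]
        ms = match_descriptors_ot(a, b)
        assert sorted(map(tuple, ms.pairs.tolist())) == [(0, 0), (1, 1)]

    def test_orthogonal_descriptor_goes_to_dustbin(self, rng):
        base = np.eye(4)
        a = _kp(rng.uniform(0, 50, (4, 2)), base)
        # B matches A's first three but has nothing near A's last axis
        b = _kp(rng.uniform(0, 50, (3, 2)), base[:3] + 0.01)
        ms = match_descriptors_ot(a, b)
        assert 3 not in ms.pairs[:, 0]
        assert ms.n_matched == 3

    def test_matcher_symmetry(self, rng):
        desc_a = _unit_rows(rng.normal(size=(10, 16)))
        perm = rng.permutation(10)
        a = _kp(rng.uniform(0, 99, (10, 2)), desc_a)
        b = _kp(rng.uniform(0, 99, (10, 2)), desc_a[perm])
        ab = {tuple(p) for p in match_descriptors_ot(a, b).pairs.tolist()}
        ba = {(j, i) for i, j in match_descriptors_ot(b, a).pairs.tolist()}
        assert ab == ba

    def test_empty_set_raises(self):
        kp = _kp([[0, 0]], [[1.0, 0.0]])
        empty = KeypointSet(np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(AlignmentError, match="no features"):
            match_descriptors_ot(kp, empty)

    def test_plan_marginals(self, rng):
        cost = rng.uniform(0, 1, size=(6, 9))
        plan = sinkhorn_with_dustbin(cost, n_iter=3000)
        np.testing.assert_allclose(plan.sum(1)[:6], 1.0, atol=1e-4)
        np.testing.assert_allclose(plan.sum(0)[:9], 1.0, atol=1e-4)


class TestRobustFit:
    @staticmethod
    def _exact_pairs(rng, n=40):
        truth = SimilarityTransform(30.0, 1.2, 10.0, -5.0)
        src = rng.uniform(0, 200, size=(n, 2))
        return truth, src, truth.apply(src)

    def test_exact_recovery(self, rng):
        truth, src, dst = self._exact_pairs(rng)
        ms = MatchSet(np.stack([np.arange(40)] * 2, 1), np.ones(40))
        fit = fit_similarity_robust(ms, src, dst, seed=0)
        assert abs(fit.transform.theta_deg - truth.theta_deg) < 1e-6
        assert abs(fit.transform.scale - truth.scale) < 1e-6
        np.testing.assert_allclose(fit.transform.translation,
                                   truth.translation, atol=1e-6)

    def test_identity_correspondence(self, rng):
        src = rng.uniform(0, 100, size=(10, 2))
        ms = MatchSet(np.stack([np.arange(10)] * 2, 1), np.ones(10))
        fit = fit_similarity_robust(ms, src, src, seed=0)
        assert fit.transform.almost_equal(SimilarityTransform(), atol=1e-9)

    def test_outlier_rejection(self, rng):
        truth, src, dst = self._exact_pairs(rng, n=50)
        out = rng.choice(50, size=10, replace=False)
        dst = dst.copy()
        dst[out] = rng.uniform(0, 200, size=(10, 2))  # 20% outliers
        ms = MatchSet(np.stack([np.arange(50)] * 2, 1), np.ones(50))
        fit = fit_similarity_robust(ms, src, dst, seed=1)
        assert abs(fit.transform.theta_deg - truth.theta_deg) < 0.5
        assert abs(fit.transform.scale / truth.scale - 1) < 0.01
        assert np.abs(fit.transform.translation - truth.translation).max() < 1.0

    def test_too_few_matches_raise(self, rng):
        ms = MatchSet(np.stack([np.arange(3)] * 2, 1), np.ones(3))
        with pytest.raises(AlignmentError, match="insufficient"):
            fit_similarity_robust(ms, rng.random((3, 2)), rng.random((3, 2)))


class TestStackAlignment:
    def test_identical_stack_gives_identity(self, small_stack):
        stack, _ = small_stack
        sections = [stack.sections[0]] * 3
        res = align_stack_rigid(sections, seed=0)
        for t in res.transforms:
            assert abs(t.theta_deg) < 1e-3
            assert np.abs(t.translation).max() < 1e-3

    def test_ground_truth_recovery(self, small_stack):
        stack, gt = small_stack
        res = align_stack_rigid(stack.sections, seed=0)
        for k in range(1, stack.n_sections):
            ok = gt.points_valid_in([0, k])
            resid = np.linalg.norm(
                res.transforms[k].apply(gt.points[k][ok]) - gt.points[0][ok],
                axis=1,
            )
            assert np.median(resid) < 2.0

    def test_reversed_stack_gives_inverse_relative_transform(self, small_stack):
        stack, _ = small_stack
        fwd = align_stack_rigid(stack.sections[:2], seed=0)
        rev = align_stack_rigid(stack.sections[:2][::-1], seed=0)
        roundtrip = fwd.transforms[1].compose(rev.transforms[1])
        pts = np.array([[64.0, 64.0], [128.0, 200.0], [200.0, 100.0]])
        resid = np.linalg.norm(roundtrip.apply(pts) - pts, axis=1)
        assert resid.max() < 1.5

    def test_no_shear_in_recovered_transforms(self, small_stack):
        stack, _ = small_stack
        res = align_stack_rigid(stack.sections, seed=0)
        for t in res.transforms:
            lin = t.linear
            expected = t.scale * rotation_matrix(t.theta_deg)
            np.testing.assert_allclose(lin, expected, atol=1e-9)

    def test_failed_pair_names_sections(self):
        good = generate_phantom_stack(
            PhantomSpec(image_size=(128, 128), n_sections=2, seed=0)
        )[0].sections[0]
        blank = np.full_like(good, 255)
        with pytest.raises(AlignmentError, match=r"\(0, 1\)"):
            align_stack_rigid([good, blank], seed=0)

    def test_skip_on_failure_carries_transform(self):
        good = generate_phantom_stack(
            PhantomSpec(image_size=(128, 128), n_sections=2, seed=0)
        )[0].sections[0]
        blank = np.full_like(good, 255)
        res = align_stack_rigid([good, blank], seed=0, skip_on_failure=True)
        assert res.pair_reports[0]["status"] == "skipped"
        assert len(res.transforms) == 2

    def test_stacked_mask_and_bbox(self, small_stack):
        stack, _ = small_stack
        res = align_stack_rigid(stack.sections, seed=0)
        assert res.stacked_mask.any()
        r0, c0, r1, c1 = res.bounding_box
        assert res.stacked_mask[r0:r1, c0:c1].any()
        assert not res.stacked_mask[:r0].any() and not res.stacked_mask[r1:].any()
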