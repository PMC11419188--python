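import numpy as np
import pytest

from vcore import imageops
from vcore.imageops import resample_similarity
from vcore.phantom import (
    GroundTruth,
    PhantomSpec,
    allocate_counts,
    class_pattern,
    depth_pair_statistic,
    generate_labeled_dataset,
    generate_phantom_stack,
    per_slice_statistic,
    stratified_split,
)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(n_sections=1)
    with pytest.raises(ValueError):
        PhantomSpec(image_size=(0, 64))
    with pytest.raises(ValueError):
        PhantomSpec(warp_amplitude=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(max_scale_dev=0.6)


def test_identity_case_sections_agree_up_to_noise():
    spec = PhantomSpec(image_size=(128, 128), n_sections=3, max_rotation=0,
                       max_translation=0, max_scale_dev=0, warp_amplitude=0,
                       seed=5)
    stack, gt = generate_phantom_stack(spec)
    for t in gt.transforms:
        assert t.almost_equal(gt.transforms[0])
        assert t.theta_deg == 0 and t.scale == 1.0
    a = stack.sections[0].astype(float)
    b = stack.sections[1].astype(float)
    assert np.abs(a - b).mean() / 255.0 < 0.03  # texture noise only


def test_seed_determinism_bytes():
    spec = PhantomSpec(image_size=(96, 96), n_sections=3, seed=11)
    s1, g1 = generate_phantom_stack(spec)
    s2, g2 = generate_phantom_stack(spec)
    for a, b in zip(s1.sections, s2.sections):
        assert a.tobytes() == b.tobytes()
    np.testing.assert_array_equal(g1.points, g2.points)


def test_different_seeds_differ_but_respect_bounds():
    t1 = generate_phantom_stack(
        PhantomSpec(image_size=(96, 96), n_sections=4, max_rotation=10, seed=1)
    )[1].transforms
    t2 = generate_phantom_stack(
        PhantomSpec(image_size=(96, 96), n_sections=4, max_rotation=10, seed=2)
    )[1].transforms
    angles1 = [t.theta_deg for t in t1[1:]]
    angles2 = [t.theta_deg for t in t2[1:]]
    assert angles1 != angles2
    for a in angles1 + angles2:
        assert -10.0 <= a <= 10.0


def test_ground_truth_correspondence_consistency():
    """Stored correspondences map onto a common base point under the stored
    transform + warp with sub-1e-6 px residual."""
    spec = PhantomSpec(image_size=(160, 160), n_sections=4, warp_amplitude=6.0,
                       warp_smoothness=40.0, seed=2)
    _, gt = generate_phantom_stack(spec)
    for i in range(spec.n_sections - 1):
        a, b = gt.correspondences(i)
        assert len(a) > 30
        resid = np.linalg.norm(gt.map_to_base(i, a) - gt.map_to_base(i + 1, b),
                               axis=1)
        assert resid.max() < 1e-6


def test_inverse_transform_recovers_base():
    """Resampling section k by its stored section->base map recovers the
    reference section within interpolation tolerance over tissue."""
    spec = PhantomSpec(image_size=(160, 160), n_sections=3, max_rotation=8,
                       max_translation=10, max_scale_dev=0.04,
                       warp_amplitude=0.0, seed=4, texture=0.3,
                       noise_sigma=0.003)
    stack, gt = generate_phantom_stack(spec)
    from scipy import ndimage

    from vcore.preprocess import build_tissue_mask

    # I_k(x) = base(T_k(x)), so rendering section k under T_k (inverse
    # warping samples at T_k^{-1}... composed back) reproduces the base frame
    rec = resample_similarity(
        imageops.to_float(stack.sections[2]), gt.transforms[2]
    )
    ref = imageops.to_float(stack.sections[0])
    tissue = ndimage.binary_erosion(
        build_tissue_mask(stack.sections[0]).mask, np.ones((5, 5))
    )
    # compare at the scale bilinear interpolation preserves: a light blur
    # removes the half-pixel edge ringing of double resampling
    rec_s = ndimage.gaussian_filter(rec, (1.0, 1.0, 0))
    ref_s = ndimage.gaussian_filter(ref, (1.0, 1.0, 0))
    assert np.abs(rec_s - ref_s).mean(axis=-1)[tissue].mean() < 3 / 255


def test_ground_truth_json_roundtrip():
    spec = PhantomSpec(image_size=(96, 96), n_sections=3, warp_amplitude=4.0,
                       seed=0)
    _, gt = generate_phantom_stack(spec)
    gt2 = GroundTruth.from_json(gt.to_json())
    np.testing.assert_allclose(gt2.points, gt.points, equal_nan=True)
    assert all(a.almost_equal(b) for a, b in zip(gt.transforms, gt2.transforms))


class TestLabeledDataset:
    def test_counts_and_split(self):
        man, stacks, _ = generate_labeled_dataset(
            10, [0.5, 0.5], depth_signal=False, seed=0, image_size=(64, 64)
        )
        assert len(man) == 10
        assert (man["label"] == 0).sum() == 5
        assert set(man["split"]) <= {"train", "val", "test"}

    def test_too_few_cores_rejected(self):
        with pytest.raises(ValueError):
            generate_labeled_dataset(2, [0.4, 0.3, 0.3])
        with pytest.raises(ValueError):
            generate_labeled_dataset(10, [0.5, 0.4])  # does not sum to 1

    def test_allocation_exact_for_divisible_n(self):
        np.testing.assert_array_equal(
            allocate_counts(12, np.array([1 / 3] * 3)), [4, 4, 4]
        )
        assert allocate_counts(10, np.array([0.5, 0.3, 0.2])).sum() == 10

    def test_stratified_split_fractions(self):
        labels = np.repeat([0, 1], 50)
        split = stratified_split(labels, seed=1)
        for lbl in (0, 1):
            sub = split[labels == lbl]
            assert (sub == "train").sum() == 35
            assert (sub == "val").sum() == 5
            assert (sub == "test").sum() == 10

    def test_class_patterns_have_common_mean(self):
        for lbl in range(4):
            assert abs(class_pattern(lbl, 4).mean() - 0.5) < 1e-12

    def test_depth_signal_statistics(self):
        """Per-slice brightness barely separates classes; the consecutive
        difference separates them essentially perfectly."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        man, stacks, _ = generate_labeled_dataset(
            36, [1 / 3] * 3, depth_signal=True, seed=0
        )
        y = man["label"].to_numpy()
        x_slice = np.stack([per_slice_statistic(s) for s in stacks])[:, :1]
        x_pair = np.stack([depth_pair_statistic(s) for s in stacks])
        clf = LogisticRegression(max_iter=500, C=1e6)
        acc_slice = cross_val_score(clf, x_slice, y, cv=3).mean()
        acc_pair = cross_val_score(clf, x_pair, y, cv=3).mean()
        assert acc_slice < 0.70  # near the 1/3 chance level
        assert acc_pair > 0.90

    def test_no_depth_signal_is_slice_decodable(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        man, stacks, _ = generate_labeled_dataset(
            36, [1 / 3] * 3, depth_signal=False, seed=0
        )
        y = man["label"].to_numpy()
        x_slice = np.stack([per_slice_statistic(s) for s in stacks])[:, :1]
        acc = cross_val_score(LogisticRegression(max_iter=500, C=1e6),
                              x_slice, y, cv=3).mean()
        assert acc > 0.8


def test_dataset_written_to_disk(tmp_path):
    man, _, _ = generate_labeled_dataset(
        4, [0.5, 0.5], seed=0, image_size=(64, 64), out_dir=tmp_path
    )
    assert (tmp_path / "manifest.csv").exists()
    first = man.iloc[0]
    assert (tmp_path / first.core_id / "section_000.png").exists()
    assert (tmp_path / first.core_id / "ground_truth.json").exists()
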