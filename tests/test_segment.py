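import numpy as np
import pytest

from vox3dmsi import (FeatureAxis, SectionImage, SerialSectionDataset,
                      assign_regions, bisecting_kmeans, roc_auc_scores,
                      roc_discriminating_features, threshold_feature_list,
                      weak_denoise)


def dataset_from_matrix(mat, mz=None):
    """One-section dataset whose foreground pixels carry the given rows."""
    mat = np.asarray(mat, float)
    n, f = mat.shape
    mz = tuple(100.0 + 10 * np.arange(f)) if mz is None else mz
    inten = mat.reshape(n, 1, f)
    return SerialSectionDataset(
        [SectionImage(inten, np.ones((n, 1), bool), 20, 20, 0)],
        FeatureAxis(mz))


class TestThresholdFeatureList:
    def test_single_peak_above_threshold(self):
        ds = dataset_from_matrix(np.array([[50000.0, 100.0, 200.0]]))
        axis = threshold_feature_list(ds, 30000.0, window_da=2.0)
        assert axis.mz_values == (100.0,)

    def test_local_maximum_rule(self):
        # two peaks 1 Da apart inside a 2 Da window: larger one survives
        ds = dataset_from_matrix(np.array([[40000.0, 50000.0]]),
                                 mz=(100.0, 101.0))
        axis = threshold_feature_list(ds, 30000.0, window_da=2.0)
        assert axis.mz_values == (101.0,)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        ds = dataset_from_matrix(rng.gamma(2, 20000, (20, 15)))
        counts = []
        for thr in (0.0, 10000.0, 30000.0, 60000.0):
            try:
                counts.append(len(threshold_feature_list(ds, thr, 25.0)))
            except ValueError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_no_survivor_raises(self):
        ds = dataset_from_matrix(np.array([[10.0, 20.0]]))
        with pytest.raises(ValueError, match="[Ll]ower"):
            threshold_feature_list(ds, 1e9)


class TestRocFeatures:
    def test_perfect_separation_scores_one(self):
        a = np.ones((12, 2)) * [10.0, 5.0]
        b = np.ones((12, 2)) * [1.0, 5.0]
        auc = roc_auc_scores(a, b)
        assert auc[0] == 1.0
        assert auc[1] == 0.5  # constant feature: midrank ties

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            na, nb = rng.integers(3, 9, 2)
            a = rng.integers(0, 5, (na, 1)).astype(float)  # heavy ties
            b = rng.integers(0, 5, (nb, 1)).astype(float)
            # oracle: concordant pairs + half ties over all pairs
            conc = sum((x > y) + 0.5 * (x == y)
                       for x in a[:, 0] for y in b[:, 0])
            assert roc_auc_scores(a, b)[0] == pytest.approx(conc / (na * nb))

    def test_null_features_dropped_at_065(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(0, 1, (2000, 6)) ** 2
        labels = np.arange(2000) < 1000
        mat[labels, 0] += 5.0  # one genuinely discriminating feature
        axis = FeatureAxis(tuple(100.0 + 10 * np.arange(6)))
        selected, score = roc_discriminating_features(
            mat, labels, axis=axis, auc_threshold=0.65)
        assert selected.mz_values == (100.0,)
        assert np.all(score[1:] < 0.6)

    def test_top_n_and_group_size_guard(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(10, 1, (40, 4))
        labels = np.arange(40) < 20
        mat[labels] += [5, 4, 3, 0]
        axis = FeatureAxis(tuple(100.0 + 10 * np.arange(4)))
        sel, _ = roc_discriminating_features(mat, labels, axis=axis,
                                             top_n=2)
        assert len(sel) == 2
        with pytest.raises(ValueError, match="10 pixels"):
            roc_discriminating_features(mat[:12], labels[:12], axis=axis)


class TestWeakDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((5, 5), 3.0)
        assert np.array_equal(weak_denoise(img), img)

    def test_single_spike_removed(self):
        img = np.full((5, 5), 2.0)
        img[2, 2] = 100.0
        assert weak_denoise(img)[2, 2] == 2.0

    def test_salt_and_pepper_error_reduced(self):
        rng = np.random.default_rng(4)
        clean = np.outer(np.linspace(1, 5, 20), np.linspace(1, 5, 20))
        noisy = clean.copy()
        spots = rng.random(clean.shape) < 0.1
        noisy[spots] = rng.choice([0.0, 50.0], spots.sum())
        filt = weak_denoise(noisy)
        assert np.abs(filt - clean).mean() < np.abs(noisy - clean).mean()

    def test_background_untouched(self):
        img = np.full((4, 4), 7.0)
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        img2 = img.copy()
        img2[3, 3] = 99.0
        out = weak_denoise(img2, mask)
        assert out[3, 3] == 99.0


def three_profiles(rng, n_per=30, noise=0.01):
    """Members drawn around three orthogonal-ish intensity profiles."""
    profiles = np.array([
        [10, 1, 1, 1, 5, 1],
        [1, 10, 1, 5, 1, 1],
        [1, 1, 10, 1, 1, 5],
    ], dtype=float)
    rows, truth = [], []
    for k, p in enumerate(profiles):
        rows.append(p * rng.lognormal(0, noise, (n_per, 6)))
        truth += [k] * n_per
    return np.vstack(rows), np.array(truth)


def label_agreement(a, b):
    """Fraction agreeing under the best label permutation (3 clusters)."""
    from itertools import permutations
    best = 0.0
    for perm in permutations(range(3)):
        mapped = np.array([perm[x] for x in a])
        best = max(best, (mapped == b).mean())
    return best


class TestBisectingKmeans:
    def test_recovers_separated_profiles_exactly(self):
        rng = np.random.default_rng(5)
        mat, truth = three_profiles(rng)
        tree = bisecting_kmeans(mat, 3, seed=0)
        assert label_agreement(tree.leaf_labels, truth) == 1.0

    def test_single_leaf(self):
        rng = np.random.default_rng(6)
        mat, _ = three_profiles(rng, n_per=5)
        tree = bisecting_kmeans(mat, 1, seed=0)
        assert tree.n_leaves == 1
        assert set(tree.leaf_labels) == {0}

    def test_scale_invariance_of_assignment(self):
        rng = np.random.default_rng(7)
        mat, _ = three_profiles(rng)
        tree1 = bisecting_kmeans(mat, 3, seed=0)
        mat2 = mat.copy()
        mat2[5] *= 37.0  # positive rescaling of one member
        tree2 = bisecting_kmeans(mat2, 3, seed=0)
        same5 = tree1.leaf_labels == tree1.leaf_labels[5]
        same5b = tree2.leaf_labels == tree2.leaf_labels[5]
        assert np.array_equal(same5, same5b)

    def test_leaves_partition_members(self):
        rng = np.random.default_rng(8)
        mat, _ = three_profiles(rng)
        for n_leaves in (2, 3, 5):
            tree = bisecting_kmeans(mat, n_leaves, seed=1)
            assert tree.n_leaves == n_leaves
            counts = np.bincount(tree.leaf_labels, minlength=n_leaves)
            assert counts.sum() == len(mat)
            assert np.all(counts > 0)
            members = np.concatenate([lf.members for lf in tree.leaves])
            assert sorted(members) == list(range(len(mat)))

    def test_determinism(self):
        rng = np.random.default_rng(9)
        mat, _ = three_profiles(rng, noise=0.3)
        t1 = bisecting_kmeans(mat, 4, seed=3)
        t2 = bisecting_kmeans(mat, 4, seed=3)
        assert np.array_equal(t1.leaf_labels, t2.leaf_labels)

    def test_too_few_distinct_members(self):
        mat = np.tile([1.0, 2.0, 3.0], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            bisecting_kmeans(mat, 2, seed=0)

    def test_zero_variance_members_flagged_and_assigned(self):
        rng = np.random.default_rng(10)
        mat, _ = three_profiles(rng)
        mat[7] = 4.0  # flat spectrum
        with pytest.warns(UserWarning, match="zero-variance"):
            tree = bisecting_kmeans(mat, 3, seed=0)
        assert tree.leaf_labels[7] >= 0
        assert 7 in tree.zero_variance_members


class TestAssignRegions:
    def test_merged_leaves_and_missing_leaf(self):
        rng = np.random.default_rng(11)
        mat, _ = three_profiles(rng)
        tree = bisecting_kmeans(mat, 3, seed=0)
        labels, ids = assign_regions(
            tree, {0: "tissue", 1: "tissue", 2: "background"})
        assert set(ids) == {"background", "tissue"}
        assert ids["background"] == 0
        assert set(labels) <= {0, ids["tissue"]}
        with pytest.raises(ValueError, match="leaf ids"):
            assign_regions(tree, {0: "a", 1: "b"})

    def test_geometry_painting(self):
        rng = np.random.default_rng(12)
        mat, _ = three_profiles(rng, n_per=4)
        tree = bisecting_kmeans(mat, 2, seed=0)
        idx = (np.arange(12), np.zeros(12, int), np.arange(12))
        vol, ids = assign_regions(tree, {0: "a", 1: "b"},
                                  geometry=(12, 1, 12), member_index=idx)
        assert vol.shape == (12, 1, 12)
        assert (vol > 0).sum() == 12


class TestPhantomSegmentation:
    def test_background_and_region_recovery(self, small_phantom):
        from vox3dmsi import assemble_volume, segment_volume
        from vox3dmsi.phantom import generate_phantom
        from conftest import small_spec

        # binary voxel model: rim voxels carry no mixed signal, so every
        # voxel has an unambiguous true class
        ds, truth = generate_phantom(small_spec(
            seed=21, perturb_translation_px=0.0, perturb_rotation_deg=0.0,
            edge_width_px=0.0))
        vol = assemble_volume(ds)
        # include background voxels as members: separation must be >= 99%
        data = vol.data.reshape(-1, vol.data.shape[-1])
        rms = np.sqrt(np.mean(data ** 2, axis=1, keepdims=True))
        rms[rms == 0] = 1.0
        tree = bisecting_kmeans(data / rms, 2, seed=0)
        truth_bg = (truth.region_volume == 0).ravel()
        leaf_bg = np.argmax(np.bincount(tree.leaf_labels[truth_bg],
                                        minlength=2))
        acc = ((tree.leaf_labels == leaf_bg) == truth_bg).mean()
        assert acc >= 0.99

    def test_three_region_recovery(self):
        from vox3dmsi import assemble_volume, segment_volume
        from vox3dmsi.pipeline import infer_region_mapping
        from vox3dmsi.segment import assign_regions
        from vox3dmsi.phantom import generate_phantom
        from conftest import small_spec

        ds, truth = generate_phantom(small_spec(
            seed=22, perturb_translation_px=0.0, perturb_rotation_deg=0.0))
        vol = assemble_volume(ds)
        tree, member_index = segment_volume(vol, 3, seed=0)
        mapping = infer_region_mapping(
            tree, ds.feature_axis,
            {"cancer": 210.0, "fibroblast": 250.0})
        labels, ids = assign_regions(tree, mapping,
                                     geometry=vol.masks.shape,
                                     member_index=member_index)
        truth_label = truth.region_volume
        tissue = truth_label > 0
        # map region names onto truth codes 1/2
        remap = {ids.get("cancer", -1): 1, ids.get("fibroblast", -1): 2}
        pred = np.zeros_like(truth_label)
        for k, v in remap.items():
            pred[labels == k] = v
        acc = (pred[tissue] == truth_label[tissue]).mean()
        assert acc >= 0.95
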