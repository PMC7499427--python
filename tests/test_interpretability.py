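"""Region features, probability clustering, class tests and embeddings."""

import numpy as np
import pandas as pd
import pytest

from hepanode.augmentation import enumerate_augmentations
from hepanode.interpretability import (
    cluster_by_probability,
    compute_features,
    extract_presoftmax,
    feature_class_tests,
    feature_table,
    tsne_embed,
)
from hepanode.records import LesionPhenotype, PatchRecord
from hepanode.synthetic import render_patch


def disk_patch(radius=5.0, depth=50.0, blur=0.0, irregularity=0.0, noise=0.0, seed=0):
    phen = LesionPhenotype(radius, depth, max(blur, 1e-9), irregularity, "benign")
    return render_patch(phen, background_level=100.0, noise_sd=noise, seed=seed)


class TestComputeFeatures:
    def test_disk_area_and_solidity(self):
        """Rasterized disk of radius 5: area ~ pi*25, near-perfect solidity."""
        feats = compute_features(disk_patch())
        assert 75 <= feats.area <= 82
        # pixelated convex hull of a radius-5 digital disk gives ~0.91
        assert feats.solidity >= 0.90

    def test_flat_patch_zero_edge_sharpness(self):
        feats = compute_features(disk_patch(depth=0.0))
        assert feats.edge_sharpness == pytest.approx(0.0, abs=1e-9)

    def test_central_attenuation_tracks_depth(self):
        shallow = compute_features(disk_patch(depth=20.0))
        deep = compute_features(disk_patch(depth=60.0))
        assert deep.mean_central_attenuation < shallow.mean_central_attenuation

    def test_convex_mask_solidity_exactly_one(self):
        mask = np.zeros((32, 32), bool)
        mask[12:20, 12:20] = True  # square = convex
        patch = PatchRecord("p", "l", np.full((32, 32), 80.0), mask)
        assert compute_features(patch).solidity == 1.0

    def test_star_mask_solidity_below_convex(self):
        mask = np.zeros((32, 32), bool)
        mask[15:17, 6:26] = True
        mask[6:26, 15:17] = True  # plus-sign: far from convex
        patch = PatchRecord("p", "l", np.full((32, 32), 80.0), mask)
        assert compute_features(patch).solidity < 0.9

    def test_empty_and_border_masks_rejected(self):
        empty = PatchRecord("p", "l", np.zeros((32, 32)), np.zeros((32, 32), bool))
        with pytest.raises(ValueError, match="empty"):
            compute_features(empty)
        border = np.zeros((32, 32), bool)
        border[0:10, 0:10] = True
        with pytest.raises(ValueError, match="border"):
            compute_features(PatchRecord("p", "l", np.zeros((32, 32)), border))

    def test_dihedral_invariance(self):
        """Area/solidity exact, attenuation/edge features to 1e-9, under
        every rotation/reflection of the full 32x32 patch."""
        patch = disk_patch(radius=5.0, depth=40.0, blur=1.0, irregularity=0.4, noise=4.0, seed=5)
        base = compute_features(patch)
        for rot in range(4):
            for refl in (False, True):
                px = np.rot90(patch.pixels, k=rot)
                mk = np.rot90(patch.mask, k=rot)
                if refl:
                    px, mk = np.fliplr(px), np.fliplr(mk)
                feats = compute_features(PatchRecord("p", "l", px, mk))
                assert feats.area == base.area
                assert feats.solidity == base.solidity
                assert feats.edge_sharpness == pytest.approx(base.edge_sharpness, abs=1e-9)
                assert feats.mean_central_attenuation == pytest.approx(
                    base.mean_central_attenuation, abs=1e-9
                )


class TestClustering:
    def test_separated_probabilities_split_perfectly(self):
        probs = {f"l{i}": 0.1 for i in range(5)} | {f"m{i}": 0.9 for i in range(5)}
        clustering = cluster_by_probability(probs, k=2, seed=0)
        assert np.allclose(clustering.centroids, [0.1, 0.9])
        low = {clustering.cluster_of[f"l{i}"] for i in range(5)}
        high = {clustering.cluster_of[f"m{i}"] for i in range(5)}
        assert low == {0} and high == {1}

    def test_k_one_returns_global_mean(self, rng):
        probs = {f"l{i}": float(p) for i, p in enumerate(rng.random(8))}
        clustering = cluster_by_probability(probs, k=1, seed=0)
        assert clustering.centroids[0] == pytest.approx(np.mean(list(probs.values())))

    def test_matches_exhaustive_1d_partition_search(self, rng):
        """k-means WCSS on 12 points equals the optimum over all ordered
        3-partitions (1-d clusters are contiguous in sorted order)."""
        values = np.sort(rng.random(12))
        probs = {f"l{i}": float(v) for i, v in enumerate(values)}
        clustering = cluster_by_probability(probs, k=3, seed=0)
        assigned = np.array([clustering.cluster_of[f"l{i}"] for i in range(12)])
        wcss = sum(
            ((values[assigned == c] - values[assigned == c].mean()) ** 2).sum()
            for c in range(3)
        )
        best = np.inf
        for i in range(1, 11):
            for j in range(i + 1, 12):
                parts = [values[:i], values[i:j], values[j:]]
                cand = sum(((p - p.mean()) ** 2).sum() for p in parts)
                best = min(best, cand)
        assert wcss == pytest.approx(best, rel=1e-9)

    def test_too_few_lesions_rejected(self):
        with pytest.raises(ValueError):
            cluster_by_probability({"a": 0.1, "b": 0.2}, k=3)


class TestFeatureClassTests:
    def test_identical_distributions_null_calibrated(self):
        r = np.random.default_rng(31)
        reps, rejections = 300, 0
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "lesion_id": [f"l{i}" for i in range(200)],
                    "area": r.normal(50, 5, 200),
                    "mean_central_attenuation": r.normal(60, 5, 200),
                    "edge_sharpness": r.normal(20, 3, 200),
                    "solidity": r.uniform(0.7, 1.0, 200),
                }
            )
            labels = {f"l{i}": int(i < 100) for i in range(200)}
            rejections += feature_class_tests(df, labels)["welch_p"].iloc[0] < 0.05
        assert abs(rejections / reps - 0.05) <= 0.035

    def test_three_sd_shift_detected(self, rng):
        df = pd.DataFrame(
            {
                "lesion_id": [f"l{i}" for i in range(100)],
                "area": np.r_[rng.normal(50, 5, 50), rng.normal(65, 5, 50)],
                "mean_central_attenuation": rng.normal(60, 5, 100),
                "edge_sharpness": rng.normal(20, 3, 100),
                "solidity": rng.uniform(0.7, 1.0, 100),
            }
        )
        labels = {f"l{i}": int(i >= 50) for i in range(100)}
        table = feature_class_tests(df, labels).set_index("feature")
        assert table.loc["area", "welch_p"] < 1e-4
        assert table.loc["area", "mannwhitney_p"] < 1e-4

    def test_single_class_rejected(self, rng):
        df = pd.DataFrame(
            {
                "lesion_id": ["a", "b"],
                "area": [1.0, 2.0],
                "mean_central_attenuation": [1.0, 2.0],
                "edge_sharpness": [1.0, 2.0],
                "solidity": [0.9, 1.0],
            }
        )
        with pytest.raises(ValueError):
            feature_class_tests(df, {"a": 1, "b": 1})


class TestEmbedding:
    def test_presoftmax_vectors_are_64d_and_deterministic(self, rng):
        from hepanode.nn import SmallCNN

        model = SmallCNN(seed=4)
        patches = rng.normal(100, 10, size=(6, 32, 32))
        vecs = extract_presoftmax(model, patches)
        assert vecs.shape == (6, 64)
        np.testing.assert_array_equal(vecs, extract_presoftmax(model, patches))
        # single-precision GEMM reduction order differs across batch sizes
        np.testing.assert_allclose(
            vecs[0], extract_presoftmax(model, patches[:1])[0], rtol=1e-4, atol=1e-3
        )

    def test_separated_blobs_stay_separated_in_2d(self, rng):
        from sklearn.metrics import silhouette_score

        a = rng.normal(0, 1, size=(60, 64))
        b = rng.normal(12, 1, size=(60, 64))
        emb = tsne_embed(np.vstack([a, b]), perplexity=20, seed=0)
        labels = np.r_[np.zeros(60), np.ones(60)]
        assert silhouette_score(emb.coords, labels) >= 0.5

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(80, 16))
        a = tsne_embed(x, perplexity=10, seed=3)
        b = tsne_embed(x, perplexity=10, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_infeasible_perplexity_rejected(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rng.normal(size=(20, 8)), perplexity=30)


class TestFeatureTable:
    def test_one_row_per_patch_with_ids(self, small_cohort):
        patches = [small_cohort.patches[p] for p in sorted(small_cohort.patches)[:10]]
        df = feature_table(patches)
        assert len(df) == 10
        assert set(df.columns) >= {"patch_id", "lesion_id", "area", "solidity"}
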