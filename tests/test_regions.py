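"""Shapley attribution, pigmentation clustering, and the impact table."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest

from eggsight.preprocess import boundary_band
from eggsight.regions import (AttributionConfig, AttributionMap, RegionSet,
                              build_impact_table, grid_superpixels,
                              positive_part, quartile_counts,
                              region_mean_positive, segment_pigmentation,
                              shap_attribution)


def exact_shapley_oracle(value_fn, n_players):
    """Textbook Shapley computation by explicit subset enumeration."""
    phi = np.zeros(n_players)
    players = range(n_players)
    for i in players:
        others = [j for j in players if j != i]
        for r in range(len(others) + 1):
            for coalition in combinations(others, r):
                w = (factorial(len(coalition))
                     * factorial(n_players - len(coalition) - 1)
                     / factorial(n_players))
                gain = value_fn(set(coalition) | {i}) - value_fn(set(coalition))
                phi[i] += w * gain
    return phi


class TestShapAttribution:
    def linear_setup(self, size=8, block=4):
        """Linear model over 4 superpixels on a (3, 8, 8) image."""
        rng = np.random.default_rng(0)
        beta = rng.normal(size=(2, 3 * size * size))

        def model_fn(batch):
            flat = batch.reshape(len(batch), -1)
            return flat @ beta.T

        image = rng.random((3, size, size))
        baseline = np.zeros((3, size, size))
        return model_fn, image, baseline, beta

    def test_linear_model_matches_exact_enumeration_oracle(self):
        model_fn, image, baseline, beta = self.linear_setup()
        labels = grid_superpixels(8, 4)

        def value_fn(coalition, cls=0):
            img = baseline.copy()
            for sp in coalition:
                img[:, labels == sp] = image[:, labels == sp]
            return model_fn(img[None])[0, cls]

        maps = shap_attribution(model_fn, image, [baseline],
                                AttributionConfig(superpixel_size=4))
        phi_oracle = exact_shapley_oracle(value_fn, 4)
        for sp in range(4):
            got = maps[0].values[labels == sp].sum()
            assert got == pytest.approx(phi_oracle[sp], abs=1e-6)

    def test_constant_model_gets_zero_attribution(self):
        def model_fn(batch):
            return np.tile([0.25, 0.75], (len(batch), 1))

        image = np.random.default_rng(1).random((3, 8, 8))
        maps = shap_attribution(model_fn, image, [np.zeros((3, 8, 8))],
                                AttributionConfig(superpixel_size=4))
        for m in maps.values():
            assert np.allclose(m.values, 0.0, atol=1e-12)

    def test_additivity_for_sampled_estimator(self):
        """Permutation sampling keeps sum(attr) = f(x) - mean_b f(b)."""
        rng = np.random.default_rng(2)
        beta = rng.normal(size=(3, 3 * 16 * 16))

        def model_fn(batch):
            return np.tanh(batch.reshape(len(batch), -1) @ beta.T * 0.05)

        image = rng.random((3, 16, 16))
        baselines = [rng.random((3, 16, 16)) for _ in range(2)]
        cfg = AttributionConfig(superpixel_size=4, n_permutations=4, seed=0,
                                exact_max_superpixels=2)  # force sampling
        maps = shap_attribution(model_fn, image, baselines, cfg)
        f_x = model_fn(image[None])[0]
        f_b = np.mean([model_fn(b[None])[0] for b in baselines], axis=0)
        for c, m in maps.items():
            gap = abs(m.values.sum() - (f_x[c] - f_b[c]))
            assert gap <= 0.05 * max(abs(f_x[c] - f_b[c]), 1e-9)

    def test_empty_baseline_set_rejected(self):
        with pytest.raises(ValueError):
            shap_attribution(lambda b: np.zeros((len(b), 2)),
                             np.zeros((3, 8, 8)), [])

    def test_superpixel_grid_must_divide_size(self):
        with pytest.raises(ValueError):
            grid_superpixels(64, 7)


class TestPositivePart:
    def test_negative_entries_zeroed(self):
        out = positive_part(np.array([[-1.0, 2.0], [0.0, -3.0]]))
        assert out.tolist() == [[0.0, 2.0], [0.0, 0.0]]

    def test_all_negative_becomes_all_zero(self):
        assert (positive_part(-np.ones((3, 3))) == 0).all()

    def test_idempotent(self):
        values = np.random.default_rng(3).normal(size=(5, 5))
        once = positive_part(values)
        assert np.array_equal(positive_part(once), once)


class TestRegionStatistics:
    def test_uniform_map_mean(self):
        region = np.zeros((6, 6), dtype=bool)
        region[2:4, 2:5] = True
        mean, empty = region_mean_positive(np.full((6, 6), 0.4), region)
        assert mean == pytest.approx(0.4) and not empty

    def test_empty_region_flagged(self):
        mean, empty = region_mean_positive(np.ones((4, 4)),
                                           np.zeros((4, 4), dtype=bool))
        assert mean == 0.0 and empty

    def test_quartile_threshold_definition(self):
        pm = np.array([[1.0, 0.8], [0.6, 0.4]])
        region = np.ones((2, 2), dtype=bool)
        assert quartile_counts(pm, region) == (3, 2)

    def test_all_zero_map(self):
        assert quartile_counts(np.zeros((4, 4)),
                               np.ones((4, 4), dtype=bool)) == (0, 0)

    def test_random_fixtures_match_brute_force(self):
        """100 random map/mask pairs against per-pixel oracles."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            pm = rng.random((12, 12)) * rng.random()
            region = rng.random((12, 12)) < 0.4
            q2, q3 = quartile_counts(pm, region)
            m = pm.max()
            assert q2 == int(sum(1 for v in pm[region] if v > 0.5 * m))
            assert q3 == int(sum(1 for v in pm[region] if v > 0.75 * m))
            assert q3 <= q2
            mean, empty = region_mean_positive(pm, region)
            if region.sum():
                assert mean == pytest.approx(pm[region].sum() / region.sum())
            else:
                assert empty

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quartile_counts(np.ones((4, 4)), np.ones((5, 5), dtype=bool))


class TestSegmentPigmentation:
    def test_two_tone_image_single_cluster(self):
        """k=2, keep=1 isolates the darker tone exactly."""
        img = np.full((32, 32, 3), 0.9)
        egg = np.ones((32, 32), dtype=bool)  # frame-filling two-tone image
        dark_tone = np.zeros((32, 32), dtype=bool)
        dark_tone[10:20, 10:20] = True
        img[dark_tone] = 0.5
        rs = segment_pigmentation(img, egg, k=2, keep=1, seed=0)
        assert (rs.cluster_masks[0] == dark_tone).all()

    def test_three_level_purity_against_ground_truth(self, rendered_egg):
        """Clusters recover the generator's spot-contrast levels."""
        rs = segment_pigmentation(rendered_egg.image, rendered_egg.egg_mask,
                                  seed=0)
        rs.validate()
        spot_union = np.zeros_like(rendered_egg.egg_mask)
        for m in rendered_egg.spot_masks:
            spot_union |= m
        purities = []
        for level_mask in rendered_egg.spot_masks:
            if level_mask.sum() == 0:
                continue
            overlaps = [(level_mask & cm).sum() for cm in rs.cluster_masks]
            best = int(np.argmax(overlaps))
            cluster_on_spots = rs.cluster_masks[best] & spot_union
            if cluster_on_spots.sum() == 0:
                purities.append(0.0)
                continue
            purities.append((rs.cluster_masks[best] & level_mask).sum()
                            / cluster_on_spots.sum())
        assert len(purities) == 3
        assert min(purities) >= 0.9

    def test_masks_disjoint_and_inside_egg(self, rendered_egg):
        rs = segment_pigmentation(rendered_egg.image, rendered_egg.egg_mask,
                                  seed=1)
        union = np.zeros_like(rendered_egg.egg_mask)
        for m in rs.cluster_masks:
            assert not (union & m).any()
            union |= m
        assert not union[~rendered_egg.egg_mask].any()

    def test_luminance_ordering(self, rendered_egg):
        rs = segment_pigmentation(rendered_egg.image, rendered_egg.egg_mask,
                                  seed=2)
        luma = rendered_egg.image @ np.array([0.299, 0.587, 0.114])
        means = [luma[m].mean() for m in rs.cluster_masks if m.sum()]
        assert means == sorted(means)

    def test_k_not_exceeding_keep_rejected(self, rendered_egg):
        with pytest.raises(ValueError):
            segment_pigmentation(rendered_egg.image, rendered_egg.egg_mask,
                                 k=4, keep=4)


class TestImpactTable:
    def hand_setup(self):
        """Two tiny images with hand-set attribution maps and regions."""
        size = 4
        egg = np.ones((size, size), dtype=bool)
        cluster0 = np.zeros_like(egg)
        cluster0[0, :2] = True
        cluster1 = np.zeros_like(egg)
        cluster1[1, :2] = True
        edge = np.zeros_like(egg)
        edge[3, :] = True
        rs = RegionSet(cluster_masks=[cluster0, cluster1], egg_mask=egg,
                       edge_mask=edge)
        amap0 = np.zeros((size, size))
        amap0[0, 0] = 1.0   # Q2+Q3 in cluster 0
        amap0[1, 0] = 0.6   # Q2 only, cluster 1
        amap1 = np.zeros((size, size))
        amap1[3, 1] = 1.0   # edges
        images = [np.zeros((3, size, size), dtype=np.float32),
                  np.zeros((3, size, size), dtype=np.float32)]
        y = np.array([0, 1])

        def model_fn(batch):  # always correct: first image class0, rest class1
            out = np.tile([0.1, 0.9], (len(batch), 1))
            if len(batch) == 2:
                out[0] = [0.9, 0.1]
            return out

        atts = [{0: AttributionMap(amap0, 0), 1: AttributionMap(amap0, 1)},
                {0: AttributionMap(amap1, 0), 1: AttributionMap(amap1, 1)}]
        return model_fn, images, y, [rs, rs], atts

    def test_hand_computed_table(self):
        model_fn, images, y, rsets, atts = self.hand_setup()
        table = build_impact_table(model_fn, images, y, rsets,
                                   baseline_set=[images[0]],
                                   class_labels=["a", "b"],
                                   attributions=atts)
        assert table.q2.loc["a", "Cluster_0"] == 1
        assert table.q3.loc["a", "Cluster_0"] == 1
        assert table.q2.loc["a", "Cluster_1"] == 1
        assert table.q3.loc["a", "Cluster_1"] == 0
        assert table.q2.loc["b", "Edges"] == 1
        assert table.q2.loc["b", "Cluster_0"] == 0
        assert table.mean_positive.loc["a", "Cluster_0"] == pytest.approx(0.5)

    def test_q3_never_exceeds_q2(self):
        model_fn, images, y, rsets, atts = self.hand_setup()
        table = build_impact_table(model_fn, images, y, rsets, [images[0]],
                                   class_labels=["a", "b"], attributions=atts)
        assert (table.q3.values <= table.q2.values).all()

    def test_misclassified_images_contribute_nothing(self):
        model_fn, images, y, rsets, atts = self.hand_setup()
        y_wrong = np.array([1, 1])  # first image now misclassified
        with pytest.warns(UserWarning):
            table = build_impact_table(model_fn, images, y_wrong, rsets,
                                       [images[0]], class_labels=["a", "b"],
                                       attributions=atts)
        assert table.q2.loc["a"].sum() == 0
        assert table.n_images == {"a": 0, "b": 1}

    def test_table_frame_layout(self):
        model_fn, images, y, rsets, atts = self.hand_setup()
        table = build_impact_table(model_fn, images, y, rsets, [images[0]],
                                   class_labels=["a", "b"], attributions=atts)
        frame = table.to_frame()
        assert list(frame.columns.get_level_values(0).unique()) == ["Q2", "Q3"]
        assert list(frame.columns.get_level_values(1).unique()) == [
            "Cluster_0", "Cluster_1", "Edges"]
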