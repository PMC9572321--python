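"""Feature extraction: first-order statistics, GLCM, texture measures."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import ripegrade as rg
from ripegrade.features import (DegenerateRegionError, FEATURE_NAMES, GlcmConfig,
                                first_order_stats, glcm, texture_features,
                                extract_features, extract_table)
from ripegrade.preprocess import apply_mask


def glcm_bruteforce(channel, mask, cfg):
    """Independent pair-enumeration oracle for the co-occurrence matrix."""
    vals = channel[mask]
    lo, hi = vals.min(), vals.max()

    def quant(v):
        if hi == lo:
            return 0
        return min(int((v - lo) / (hi - lo) * cfg.levels), cfg.levels - 1)

    h, w = channel.shape
    mats = []
    for dy, dx in cfg.offsets:
        C = np.zeros((cfg.levels, cfg.levels))
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                    C[quant(channel[y, x]), quant(channel[y2, x2])] += 1
        if cfg.symmetric:
            C = C + C.T
        if C.sum() > 0:
            mats.append(C / C.sum())
    return np.mean(mats, axis=0)


class TestFirstOrderStats:
    def test_constant_sample_conventions(self):
        s = first_order_stats(np.full(10, 0.7))
        assert (s["min"], s["mean"], s["max"]) == (0.7, 0.7, 0.7)
        assert (s["std"], s["cv"], s["skewness"], s["kurtosis"]) == (0, 0, 0, 0)
        assert s["median"] == 0.7 and s["mode"] == 0.7

    def test_small_sample_frozen_values(self):
        s = first_order_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s["mean"] == 2.5
        assert s["std"] == pytest.approx(1.1180, abs=1e-4)
        assert s["cv"] == pytest.approx(0.4472, abs=1e-4)
        assert s["median"] == 2.5
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert s["kurtosis"] == pytest.approx(1.64)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            first_order_stats(np.array([]))

    def test_gaussian_kurtosis_is_three(self):
        """Non-excess convention: a large Gaussian sample gives kurtosis ~ 3."""
        v = np.random.default_rng(0).normal(size=200_000)
        assert first_order_stats(v)["kurtosis"] == pytest.approx(3.0, abs=0.05)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=60))
    def test_moments_match_scipy(self, values):
        v = np.asarray(values)
        s = first_order_stats(v)
        assert s["mean"] == pytest.approx(v.mean(), rel=1e-9, abs=1e-9)
        assert s["std"] == pytest.approx(v.std(), rel=1e-9, abs=1e-9)
        assert s["min"] <= s["median"] <= s["max"]
        assert s["min"] <= s["mean"] <= s["max"]
        if v.std() > 1e-6 * (1 + abs(v.mean())):
            assert s["skewness"] == pytest.approx(sps.skew(v), rel=1e-6, abs=1e-9)
            assert s["kurtosis"] == pytest.approx(
                sps.kurtosis(v, fisher=False), rel=1e-6, abs=1e-9)


class TestGlcm:
    def test_two_level_example(self):
        ch = np.array([[0.0, 0.0], [1.0, 1.0]])
        cfg = GlcmConfig(levels=2, offsets=((0, 1),))
        P = glcm(ch, np.ones((2, 2), bool), cfg)
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_region_single_entry(self):
        P = glcm(np.full((4, 4), 0.3), np.ones((4, 4), bool),
                 GlcmConfig(levels=4, offsets=((0, 1),)))
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_masking_row_changes_only_touching_pairs(self):
        rng = np.random.default_rng(2)
        ch = rng.random((6, 6))
        full = np.ones((6, 6), bool)
        part = full.copy()
        part[2, :] = False
        cfg = GlcmConfig(levels=4, offsets=((1, 0),))
        assert not np.allclose(glcm(ch, full, cfg), glcm(ch, part, cfg))
        np.testing.assert_allclose(glcm(ch, part, cfg),
                                   glcm_bruteforce(ch, part, cfg))

    def test_too_few_pairs_raises(self):
        with pytest.raises(DegenerateRegionError):
            glcm(np.ones((1, 2)), np.array([[True, False]]),
                 GlcmConfig(levels=2, offsets=((0, 1),)))

    @pytest.mark.parametrize("h", range(2, 9))
    @pytest.mark.parametrize("w", range(2, 9))
    def test_matches_bruteforce_exhaustively(self, h, w):
        """Oracle equivalence on every image size up to 8x8 (random content
        and random mask per size, seeded)."""
        rng = np.random.default_rng(h * 100 + w)
        for trial in range(3):
            ch = rng.random((h, w))
            mask = rng.random((h, w)) > 0.3
            cfg = GlcmConfig(levels=4)
            try:
                P = glcm(ch, mask, cfg)
            except DegenerateRegionError:
                continue
            np.testing.assert_allclose(P, glcm_bruteforce(ch, mask, cfg),
                                       atol=1e-12)


class TestTextureFeatures:
    def test_diagonal_two_level_closed_form(self):
        t = texture_features(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert t["contrast"] == 0
        assert t["homogeneity"] == 1
        assert t["energy"] == 0.5
        assert t["entropy"] == 1
        assert t["covariance"] == pytest.approx(0.25)
        assert t["correlation"] == pytest.approx(1.0)

    def test_single_entry_conventions(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        t = texture_features(P)
        assert (t["contrast"], t["homogeneity"], t["energy"], t["entropy"]) == \
            (0, 1, 1, 0)
        assert t["correlation"] == 1.0  # zero marginal deviation convention

    def test_uniform_matrix_maximum_entropy(self):
        L = 4
        t = texture_features(np.full((L, L), 1 / L ** 2))
        assert t["entropy"] == pytest.approx(2 * np.log2(L))
        assert t["energy"] == pytest.approx(1 / L ** 2)
        assert t["correlation"] == pytest.approx(0.0, abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            texture_features(np.ones((2, 2)))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_feature_ranges(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((5, 5))
        P /= P.sum()
        t = texture_features(P)
        assert 0 < t["energy"] <= 1
        assert t["entropy"] >= 0
        assert 0 < t["homogeneity"] <= 1
        assert abs(t["correlation"]) <= 1 + 1e-12


class TestExtraction:
    def test_emits_exactly_285_named_features(self, tiny_dataset):
        _, masked, _ = tiny_dataset
        feats = extract_features(masked[0])
        assert len(feats) == 285
        assert list(feats.index) == list(FEATURE_NAMES)
        assert np.isfinite(feats.to_numpy()).all()

    def test_zero_noise_image_degenerate_features(self, zero_noise_profile,
                                                  zero_noise_scene):
        img, mask = rg.generate_image(zero_noise_profile, zero_noise_scene)
        feats = extract_features(apply_mask(img, mask))
        std_cols = [f"std_{c}" for c in rg.CHANNEL_NAMES]
        contrast_cols = [f"contrast_{c}" for c in rg.CHANNEL_NAMES]
        assert (feats[std_cols] == 0).all()
        assert (feats[contrast_cols] == 0).all()

    def test_background_pixels_do_not_affect_features(self, profiles, small_scene):
        img, mask = rg.generate_image(profiles["ripe"], small_scene)
        a = extract_features(apply_mask(img, mask))
        tampered = img.copy()
        tampered[~mask] = 0.123
        b = extract_features(apply_mask(tampered, mask))
        pd.testing.assert_series_equal(a, b)

    def test_order_stats_are_ordered(self, tiny_dataset):
        _, _, table = tiny_dataset
        for c in rg.CHANNEL_NAMES:
            assert (table[f"min_{c}"] <= table[f"median_{c}"] + 1e-12).all()
            assert (table[f"median_{c}"] <= table[f"max_{c}"] + 1e-12).all()
            assert (table[f"min_{c}"] <= table[f"mean_{c}"] + 1e-12).all()
            assert (table[f"mean_{c}"] <= table[f"max_{c}"] + 1e-12).all()

    def test_table_shape_and_row_permutation(self, tiny_dataset):
        ds, masked, table = tiny_dataset
        assert table.shape == (24, 287)
        perm = np.random.default_rng(0).permutation(len(masked))
        table2 = extract_table([masked[i] for i in perm],
                               [ds.labels[i] for i in perm],
                               [ds.image_ids[i] for i in perm])
        reordered = table.iloc[perm].reset_index(drop=True)
        pd.testing.assert_frame_equal(table2, reordered)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_table([], [])

    def test_failed_image_reports_id(self):
        bad = apply_mask(np.ones((3, 3, 3)) * 0.4,
                         np.array([[True, True, False]] * 3, dtype=bool).T)
        bad.mask = np.zeros((3, 3), bool)
        bad.mask[0, 0] = True
        bad.mask[2, 2] = True  # two isolated pixels: no co-occurring pairs
        with pytest.raises(RuntimeError, match="brokenimg"):
            extract_table([bad], ["ripe"], ["brokenimg"])
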