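"""Unit tests for channel correction, segmentation, labeling and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from routescape import imaging as im
from routescape.synthetic import ImageScenario, gen_multiplex_image

from conftest import random_image


def brute_force_scores(img, L, eps):
    """Independent per-pixel loop implementing the score formula."""
    H, W = L.labels.shape
    dapi_ch = img.channel_roles["dapi"]
    out = {}
    for prot in img.protein_roles:
        ch = img.channel_roles[prot]
        row = {}
        for j, name in enumerate(L.schema):
            total, count = 0.0, 0
            for y in range(H):
                for x in range(W):
                    if L.labels[y, x] == j:
                        z_dapi = max(img.pixels[y, x, dapi_ch], eps)
                        total += img.pixels[y, x, ch] / z_dapi
                        count += 1
            row[name] = total / count if count else np.nan
        out[prot] = row
    return pd.DataFrame.from_dict(out, orient="index")


class TestCorrectChannels:
    def test_copied_channel_residual_zero(self, rng):
        img = random_image(rng, 16, 16)
        pix = img.pixels.copy()
        pix[:, :, 5] = pix[:, :, 4]
        img = im.MultiplexImage(pix, img.channel_roles)
        out = im.correct_channels(img, penalty=0.0)
        assert np.allclose(out.channel("prot5"), 0.0, atol=1e-8)

    def test_orthogonal_channel_unchanged(self, rng):
        # a channel with disjoint support (raw inner product zero with all
        # others) cannot be explained by them and is returned unchanged
        pix = np.zeros((10, 10, 8))
        pix[:5, :, :7] = rng.random((5, 10, 7)) + 0.1
        pix[5:, :, 7] = rng.random((5, 10)) + 0.1
        img = im.MultiplexImage(pix, dict(dapi=0, af=1, tumor=2, vessel=3, p=7))
        out = im.correct_channels(img, penalty=0.0)
        assert np.allclose(out.channel("p"), img.channel("p"), atol=1e-10)

    def test_large_penalty_converges_to_raw(self, rng):
        img = random_image(rng, 12, 12)
        out = im.correct_channels(img, penalty=1e9)
        for prot in img.protein_roles:
            assert np.allclose(out.channel(prot), img.channel(prot), atol=1e-5)

    def test_penalty_zero_equals_ols_residual(self, rng):
        img = random_image(rng, 12, 12)
        out = im.correct_channels(img, penalty=0.0)
        flat = img.pixels.reshape(-1, 8)
        c = img.channel_roles["prot4"]
        X = np.delete(flat, c, axis=1)
        beta, *_ = np.linalg.lstsq(X, flat[:, c], rcond=None)
        expected = np.clip(flat[:, c] - X @ beta, 0, None).reshape(12, 12)
        assert np.allclose(out.channel("prot4"), expected, atol=1e-8)

    def test_constant_channel_flagged_unchanged(self, rng):
        img = random_image(rng, 8, 8)
        pix = img.pixels.copy()
        pix[:, :, 4] = 0.7
        img = im.MultiplexImage(pix, img.channel_roles)
        with pytest.warns(UserWarning, match="constant"):
            out = im.correct_channels(img, penalty=1.0)
        assert np.allclose(out.channel("prot4"), 0.7)

    def test_unmixing_recovers_planted_markers(self):
        scen = ImageScenario(seed=5)
        img, _ = gen_multiplex_image(scen)
        clean, _ = gen_multiplex_image(
            ImageScenario(seed=5, noise_sd=0.0, mixing_matrix=np.eye(8))
        )
        out = im.correct_channels(img, penalty=0.0)
        for marker in ("marker_pv", "marker_diffuse", "marker_bulk"):
            r = np.corrcoef(out.channel(marker).ravel(), clean.channel(marker).ravel())[0, 1]
            assert r >= 0.95


class TestSegmentBase:
    def test_k_centroids_and_masks(self, rng):
        img = random_image(rng, 20, 20)
        pix = img.pixels.copy()
        pix[:10, :, 2] += 3.0  # tumor block
        pix[15:, :, 3] += 3.0  # vessel block
        img = im.MultiplexImage(pix, img.channel_roles)
        T, V = im.segment_base(img, k=5, seed=0)
        assert T.shape == (20, 20)
        assert T[:10].mean() > 0.9 and V[15:].mean() > 0.9
        assert not (T & V).any()

    def test_zero_vessel_channel_gives_valid_masks(self, rng):
        pix = rng.random((16, 16, 8)) + 0.05
        pix[:, :, 3] = 0.0
        pix[:8, :, 2] += 3.0
        img = im.MultiplexImage(pix, dict(dapi=0, af=1, tumor=2, vessel=3))
        T, V = im.segment_base(img, k=5, seed=0)
        # empty-mask contract: no error, V is simply whatever cluster is
        # maximal in the (flat) vessel channel, possibly empty of signal
        assert V.dtype == bool

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            im.segment_base(random_image(rng, 8, 8), k=1)

    def test_noise_free_scenario_recovers_masks(self):
        scen = ImageScenario(seed=3, noise_sd=0.0)
        img, truth = gen_multiplex_image(scen)
        corr = im.correct_channels(img, penalty=5.0)
        T, V = im.segment_base(corr, seed=3)
        assert (T == truth.tumor_mask).mean() >= 0.99
        assert (V == truth.vessel_mask).mean() >= 0.99


class TestLabelCompartments:
    def test_all_background_is_parenchyma(self):
        T = np.zeros((64, 64), bool)
        V = np.zeros((64, 64), bool)
        L = im.label_compartments((T, V))
        assert (L.labels == L.schema.index("parenchyma")).all()

    def test_band_mask_enables_nine_classes(self):
        band = np.zeros((64, 64), bool)
        band[:10] = True
        p = im.CompartmentParams(band_mask=band)
        assert len(p.schema) == 9 and "corpus_callosum" in p.schema
        assert len(im.CompartmentParams().schema) == 8

    def test_vessel_precedence_over_tumor(self):
        T = np.ones((40, 40), bool)
        V = np.zeros((40, 40), bool)
        V[18:22, 18:22] = True
        L = im.label_compartments((T, V), im.CompartmentParams(window=5))
        assert L.class_mask("vessel").sum() == 16
        # tumor pixels near the vessel are perivascular
        assert L.class_mask("perivascular").any()

    def test_window_larger_than_image_rejected(self):
        T = np.zeros((8, 8), bool)
        with pytest.raises(ValueError):
            im.label_compartments((T, T), im.CompartmentParams(window=31))


class TestCompartmentScores:
    def test_constant_ratio(self):
        pix = np.zeros((6, 6, 8))
        pix[:, :, 0] = 2.0  # DAPI
        pix[:, :, 4] = 3.0  # protein
        img = im.MultiplexImage(pix, dict(dapi=0, af=1, tumor=2, vessel=3, p=4))
        L = im.label_compartments((np.zeros((6, 6), bool), np.zeros((6, 6), bool)),
                                  im.CompartmentParams(window=3))
        s = im.compartment_scores(img, L, eps=1.0)
        assert s.scores.loc["p", "parenchyma"] == pytest.approx(1.5)

    def test_hand_computed_3x3(self):
        # one class of 4 pixels with printed integer intensities
        pix = np.zeros((3, 3, 8))
        pix[:, :, 0] = [[1, 2, 4], [2, 1, 8], [5, 2, 2]]
        pix[:, :, 4] = [[3, 8, 2], [6, 2, 4], [10, 7, 1]]
        img = im.MultiplexImage(pix, dict(dapi=0, af=1, tumor=2, vessel=3, p=4))
        T = np.zeros((3, 3), bool)
        T[0, 0] = T[0, 1] = T[1, 0] = T[1, 1] = True
        L = im.label_compartments((T, np.zeros((3, 3), bool)),
                                  im.CompartmentParams(window=1, density_mode="absolute",
                                                       density_thresholds=(2.0, 3.0)))
        s = im.compartment_scores(img, L, eps=1.0)
        expected = (3 / 1 + 8 / 2 + 6 / 2 + 2 / 1) / 4  # mean of per-pixel ratios
        assert s.scores.loc["p", "low_density"] == pytest.approx(expected)

    def test_empty_class_missing(self, rng):
        img = random_image(rng, 8, 8)
        L = im.label_compartments(
            (np.zeros((8, 8), bool), np.zeros((8, 8), bool)),
            im.CompartmentParams(window=3),
        )
        s = im.compartment_scores(img, L)
        assert np.isnan(s.scores.loc["prot4", "vessel"])
        assert s.pixel_counts["vessel"] == 0

    def test_eps_must_be_positive(self, rng):
        img = random_image(rng, 4, 4)
        L = im.label_compartments((np.zeros((4, 4), bool),) * 2,
                                  im.CompartmentParams(window=3))
        with pytest.raises(ValueError):
            im.compartment_scores(img, L, eps=0.0)

    def test_matches_brute_force_small(self, rng):
        for _ in range(5):
            h, w = rng.integers(4, 12, 2)
            img = random_image(rng, int(h), int(w))
            T = rng.random((h, w)) < 0.4
            V = rng.random((h, w)) < 0.1
            L = im.label_compartments((T, V), im.CompartmentParams(window=3))
            s = im.compartment_scores(img, L, eps=0.5)
            bf = brute_force_scores(img, L, eps=0.5)
            assert np.allclose(
                s.scores.to_numpy(), bf.loc[s.scores.index, s.scores.columns].to_numpy(),
                atol=1e-12, equal_nan=True,
            )


class TestAreasAndDE:
    def test_single_class_area_one(self):
        T = np.zeros((10, 10), bool)
        L = im.label_compartments((T, T), im.CompartmentParams(window=3))
        fr = im.compartment_areas(L)
        assert fr["parenchyma"] == 1.0 and fr.sum() == pytest.approx(1.0)

    def test_areas_sum_to_one(self, rng):
        T = rng.random((30, 30)) < 0.5
        V = rng.random((30, 30)) < 0.1
        L = im.label_compartments((T, V), im.CompartmentParams(window=5))
        assert im.compartment_areas(L).sum() == pytest.approx(1.0)

    def _mk_scores(self, vals):
        df = pd.DataFrame({"c": vals}, index=["p"]).T
        return im.ScoreMatrix(pd.DataFrame({"c1": vals}, index=["p"]),
                              pd.Series({"c1": 10}))

    def test_welch_matches_textbook_formula(self, rng):
        a = np.array([1.1, 2.3, 0.7])
        b = np.array([2.0, 2.2, 3.1])
        scores = {}
        groups = {}
        for i, v in enumerate(a):
            scores[f"pv{i}"] = self._mk_scores([v])
            groups[f"pv{i}"] = "perivascular"
        for i, v in enumerate(b):
            scores[f"df{i}"] = self._mk_scores([v])
            groups[f"df{i}"] = "diffuse"
        out = im.spatial_de(scores, groups)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t_hand = (b.mean() - a.mean()) / se  # level order is alphabetical
        assert out["t"].iloc[0] == pytest.approx(t_hand)
        assert out["p"].iloc[0] == pytest.approx(
            stats.ttest_ind(b, a, equal_var=False).pvalue
        )

    def test_clear_shift_detected(self):
        scores, groups = {}, {}
        for i, v in enumerate([1.0, 1.0, 1.0]):
            scores[f"a{i}"] = self._mk_scores([v + 1e-6 * i])
            groups[f"a{i}"] = "perivascular"
        for i, v in enumerate([2.0, 2.0, 2.0]):
            scores[f"b{i}"] = self._mk_scores([v + 1e-6 * i])
            groups[f"b{i}"] = "diffuse"
        out = im.spatial_de(scores, groups)
        assert abs(out["mean_diff"].iloc[0]) == pytest.approx(1.0, abs=1e-5)
        assert out["p"].iloc[0] < 0.01

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            scores, groups = {}, {}
            for i in range(3):
                scores[f"a{i}"] = self._mk_scores([r.normal()])
                groups[f"a{i}"] = "perivascular"
                scores[f"b{i}"] = self._mk_scores([r.normal()])
                groups[f"b{i}"] = "diffuse"
            ps.append(im.spatial_de(scores, groups)["p"].iloc[0])
        ps = np.array(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.05).mean() < 0.15


class TestKOShift:
    def test_identical_inputs_zero_shift(self):
        df = pd.DataFrame({"high_density": [0.2, 0.25, 0.22, 0.21]})
        out = im.score_ko_shift(df, df.copy())
        assert out["mean_diff"].iloc[0] == pytest.approx(0.0)
        assert out["ci_low"].iloc[0] <= 0 <= out["ci_high"].iloc[0]

    def test_interval_covers_planted_shift(self):
        delta, hits, n_sim = 0.1, 0, 400
        rng = np.random.default_rng(1)
        for _ in range(n_sim):
            ctrl = pd.DataFrame({"c": rng.normal(0.3, 0.05, 4)})
            ko = pd.DataFrame({"c": rng.normal(0.3 + delta, 0.05, 4)})
            out = im.score_ko_shift(ko, ctrl, conf=0.90)
            hits += out["ci_low"].iloc[0] <= delta <= out["ci_high"].iloc[0]
        assert hits / n_sim >= 0.85

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            im.score_ko_shift(pd.DataFrame({"c": [1.0]}), pd.DataFrame({"c": [1.0]}))
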