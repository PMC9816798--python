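"""Two-band index screening: formulas, surfaces, extreme selection."""

import numpy as np
import pytest
from scipy import stats

import wheatyield as wy
from wheatyield.band_selection import INDEX_TYPES
from wheatyield.synth import HyperspectralTable, nearest_band


def _toy_table(rng, n_samples=10, n_bands=5):
    centers = np.linspace(400, 2400, n_bands)
    refl = rng.uniform(0.05, 0.6, size=(n_samples, n_bands))
    y = rng.uniform(1.39, 6.75, n_samples)
    return HyperspectralTable(refl, centers, y)


class TestPairIndex:
    def test_identity_cases(self):
        spec = np.array([[0.3, 0.1, 0.2]])
        assert wy.compute_pair_index(spec, 1, 1, "SSI") == pytest.approx(0.0)
        assert wy.compute_pair_index(spec, 1, 1, "RSI") == pytest.approx(1.0)
        assert wy.compute_pair_index(spec, 1, 1, "NDSI") == pytest.approx(0.0)

    def test_worked_example(self):
        spec = np.array([[0.3, 0.1]])
        assert wy.compute_pair_index(spec, 0, 1, "SSI") == pytest.approx(0.2)
        assert wy.compute_pair_index(spec, 0, 1, "RSI") == pytest.approx(3.0)
        assert wy.compute_pair_index(spec, 0, 1, "NDSI") == pytest.approx(0.5)

    def test_swap_antisymmetry_and_reciprocity(self, rng):
        spec = rng.uniform(0.05, 0.9, size=(6, 4))
        for i, j in [(0, 1), (2, 3), (1, 3)]:
            ssi = wy.compute_pair_index(spec, i, j, "SSI")
            ndsi = wy.compute_pair_index(spec, i, j, "NDSI")
            rsi = wy.compute_pair_index(spec, i, j, "RSI")
            assert np.allclose(wy.compute_pair_index(spec, j, i, "SSI"), -ssi)
            assert np.allclose(wy.compute_pair_index(spec, j, i, "NDSI"), -ndsi)
            assert np.allclose(wy.compute_pair_index(spec, j, i, "RSI"), 1.0 / rsi)

    def test_guard_violations_flagged(self):
        spec = np.array([[0.3, 0.0]])
        assert np.isnan(wy.compute_pair_index(spec, 0, 1, "RSI"))
        spec2 = np.array([[0.0, 0.0]])
        assert np.isnan(wy.compute_pair_index(spec2, 0, 1, "NDSI"))


class TestSurface:
    def test_163_bands_give_13203_unordered_pairs(self, rng):
        cfg = wy.SceneConfig(seed=0)
        y = rng.uniform(1.39, 6.75, 39)
        tab = wy.simulate_hyperspectral_samples(y, cfg)
        surf = wy.pairwise_correlation_surface(tab, "NDSI")
        assert surf.n_unordered_pairs == 13203
        assert 163 * 162 // 2 == 13203

    @pytest.mark.parametrize("n_bands", [4, 7])
    def test_pair_count_formula(self, rng, n_bands):
        tab = _toy_table(rng, n_bands=n_bands)
        surf = wy.pairwise_correlation_surface(tab, "SSI")
        assert surf.n_unordered_pairs == n_bands * (n_bands - 1) // 2

    @pytest.mark.parametrize("index_type", INDEX_TYPES)
    def test_matches_per_pair_pearson_oracle(self, rng, index_type):
        tab = _toy_table(rng)
        surf = wy.pairwise_correlation_surface(tab, index_type)
        nb = tab.n_bands
        for i in range(nb):
            for j in range(nb):
                if i == j:
                    assert np.isnan(surf.r[i, j])
                    continue
                vals = wy.compute_pair_index(tab.reflectance, i, j, index_type)
                r_ref, p_ref = stats.pearsonr(vals, tab.yields)
                assert surf.r[i, j] == pytest.approx(r_ref, abs=1e-10)
                assert surf.p[i, j] == pytest.approx(p_ref, abs=1e-10)

    @pytest.mark.parametrize("index_type", ["SSI", "NDSI"])
    def test_antisymmetry(self, rng, index_type):
        tab = _toy_table(rng)
        surf = wy.pairwise_correlation_surface(tab, index_type)
        iu, ju = np.triu_indices(tab.n_bands, k=1)
        assert np.allclose(surf.r[iu, ju], -surf.r[ju, iu])

    def test_self_correlation_is_one(self, rng):
        tab = _toy_table(rng)
        # make yield exactly equal to NDSI(1, 3)
        vals = wy.compute_pair_index(tab.reflectance, 1, 3, "NDSI")
        tab = HyperspectralTable(tab.reflectance, tab.band_centers_nm, vals)
        surf = wy.pairwise_correlation_surface(tab, "NDSI")
        assert surf.r[1, 3] == pytest.approx(1.0)

    def test_constant_index_flagged(self, rng):
        tab = _toy_table(rng)
        tab.reflectance[:, 0] = 0.2
        tab.reflectance[:, 1] = 0.2
        surf = wy.pairwise_correlation_surface(tab, "SSI")
        assert np.isnan(surf.r[0, 1])


class TestSelection:
    def test_single_planted_pair_recovered_noise_free(self, rng):
        c = wy.hyperspectral_band_centers()
        pair = (nearest_band(1779, c), nearest_band(2216, c), +1)
        cfg = wy.SceneConfig(seed=3, noise_sd=0.0, planted_pairs=[pair])
        y = rng.uniform(1.39, 6.75, 39)
        tab = wy.simulate_hyperspectral_samples(y, cfg)
        best = wy.select_extreme_pairs(
            wy.pairwise_correlation_surface(tab, "NDSI")
        ).best
        assert {best.i, best.j} == {pair[0], pair[1]}

    def test_ties_resolved_lexicographically(self):
        centers = np.linspace(400, 1000, 4)
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 6, 12)
        # bands 0,1 and 2,3 carry the same exact linear signal
        refl = np.empty((12, 4))
        refl[:, 0] = 0.3 + 0.01 * y
        refl[:, 1] = 0.3 - 0.01 * y
        refl[:, 2] = 0.3 + 0.01 * y
        refl[:, 3] = 0.3 - 0.01 * y
        tab = HyperspectralTable(refl, centers, y)
        surf = wy.pairwise_correlation_surface(tab, "SSI")
        ext = wy.select_extreme_pairs(surf)
        assert (ext.positive.i, ext.positive.j) == (0, 1)

    def test_no_significant_pairs_warns_and_returns_empty(self, rng):
        tab = _toy_table(rng, n_samples=5)
        surf = wy.pairwise_correlation_surface(tab, "NDSI")
        # force p-values above any reasonable alpha by tiny alpha
        with pytest.warns(UserWarning):
            ext = wy.select_extreme_pairs(surf, alpha=1e-12)
        assert ext.positive is None and ext.negative is None

    def test_fully_missing_surface_is_error(self):
        centers = np.linspace(400, 1000, 3)
        surf = wy.BandPairSurface(
            "NDSI", np.full((3, 3), np.nan), np.full((3, 3), np.nan), centers
        )
        with pytest.raises(ValueError):
            wy.select_extreme_pairs(surf)

    def test_reported_pairs_pass_significance(self, rng):
        cfg = wy.SceneConfig(seed=5)
        y = rng.uniform(1.39, 6.75, 39)
        tab = wy.simulate_hyperspectral_samples(y, cfg)
        sel = wy.select_all_index_types(tab, alpha=0.001)
        for ext in sel.values():
            for cand in (ext.positive, ext.negative):
                if cand is not None:
                    assert cand.p < 0.001


class TestCustomFeatures:
    def _selection(self, rng):
        cfg = wy.SceneConfig(seed=6)
        y = rng.uniform(1.39, 6.75, 39)
        tab = wy.simulate_hyperspectral_samples(y, cfg)
        return tab, wy.select_all_index_types(tab), y

    def test_four_dates_give_3x4_matrix(self, rng):
        tab, sel, y = self._selection(rng)
        tables = [tab] * 4
        feats, names, dates = wy.extract_custom_features(
            tables, sel, ["d1", "d2", "d3", "d4"]
        )
        assert feats.shape == (39, 3, 4)
        assert names == list(INDEX_TYPES)

    def test_single_date_gives_3x1(self, rng):
        tab, sel, _ = self._selection(rng)
        feats, _, _ = wy.extract_custom_features(tab, sel)
        assert feats.shape == (39, 3, 1)

    def test_features_match_pointwise_pair_index(self, rng):
        tab, sel, _ = self._selection(rng)
        feats, names, _ = wy.extract_custom_features(tab, sel)
        for k, t in enumerate(names):
            best = sel[t].best
            direct = wy.compute_pair_index(tab.reflectance, best.i, best.j, t)
            assert np.allclose(feats[:, k, 0], direct)
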