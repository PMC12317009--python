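import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoborder import (detect_borders, feature_vector, hotelling_p,
                        make_laminar_model, md_function, render_ribbon)
from cytoborder.borders import profile_features, significant_maxima


def direct_moments(x, w):
    """Independent, literal evaluation of the weighted central moments."""
    total = w.sum()
    mu = (x * w).sum() / total
    var = (w * (x - mu) ** 2).sum() / total
    sd = np.sqrt(var)
    skew = (w * (x - mu) ** 3).sum() / total / sd**3 if sd > 0 else 0.0
    kurt = (w * (x - mu) ** 4).sum() / total / sd**4 if sd > 0 else 0.0
    return [w.mean(), mu, sd, skew, kurt]


class TestFeatureVector:
    def test_symmetric_profile_centroid_and_skew(self):
        x = np.linspace(0, 1, 21)
        y = np.exp(-((x - 0.5) ** 2) / 0.02)
        fv = feature_vector(y, x)
        assert fv[1] == pytest.approx(0.5, abs=1e-12)
        assert fv[3] == pytest.approx(0.0, abs=1e-9)

    def test_constant_profile_closed_form(self):
        x = np.linspace(0, 1, 101)
        with pytest.warns(RuntimeWarning):
            fv = feature_vector(np.full(101, 0.4), x)
        assert fv[0] == pytest.approx(0.4)
        assert fv[1] == pytest.approx(0.5)
        # uniform weights on a grid over [0,1]: sd of the discrete uniform
        assert fv[2] == pytest.approx(np.sqrt(np.mean((x - 0.5) ** 2)), rel=1e-9)
        # zero derivative: degenerate block reports zero spread
        assert fv[5] == 0.0 and fv[7] == 0.0 and fv[8] == 0.0

    def test_four_point_profile_against_direct_formulas(self):
        x = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        y = np.array([0.2, 0.4, 0.6, 0.8])
        dy = np.abs(np.diff(y))
        xm = 0.5 * (x[:-1] + x[1:])
        expected = direct_moments(x, y) + direct_moments(xm, dy)
        fv = feature_vector(y, x)
        assert np.allclose(fv, expected, rtol=1e-12)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            feature_vector(np.zeros(10))

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            feature_vector(np.array([0.1, 0.2]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=6, max_size=40))
    def test_features_finite_for_positive_profiles(self, values):
        fv = feature_vector(np.array(values))
        assert fv.shape == (10,)
        assert np.all(np.isfinite(fv))


class TestMDFunction:
    def make_features(self, rng, n=100):
        return rng.normal(size=(n, 10)) @ np.diag(np.linspace(0.5, 2.0, 10))

    def test_identical_blocks_zero_distance(self, rng):
        block = rng.random((12, 50)) * 0.5 + 0.2
        profiles = np.vstack([block, block])     # both blocks identical
        df = md_function(profiles, 12)
        centre = np.nonzero(df.positions == 12)[0][0]
        assert df.md[centre] == 0.0
        assert df.pvalues[centre] == 1.0

    def test_affine_feature_invariance(self, rng, agranular_model, contrast_model):
        rib = render_ribbon([agranular_model, contrast_model], [40, 40], seed=2)
        feats = profile_features(rib.profiles, rib.depth_grid)
        scale = np.linspace(0.3, 9.0, 10)
        offset = np.linspace(-2.0, 5.0, 10)
        df1 = md_function(rib.profiles, 15, features=feats)
        df2 = md_function(rib.profiles, 15, features=feats * scale + offset)
        assert np.allclose(df1.md, df2.md, atol=1e-8)

    def test_block_order_symmetry(self, agranular_model, contrast_model):
        rib = render_ribbon([agranular_model, contrast_model], [40, 40], seed=3)
        df = md_function(rib.profiles, 15)
        rev = md_function(rib.profiles[::-1], 15)
        assert np.allclose(df.md, rev.md[::-1], atol=1e-8)

    def test_peak_at_known_border(self, agranular_model, contrast_model):
        rib = render_ribbon([agranular_model, contrast_model], [76, 86], seed=5)
        df = md_function(rib.profiles, 23)
        peak = df.positions[np.argmax(df.md)]
        assert abs(peak - 76) <= 3
        assert df.pvalues[np.argmax(df.md)] < 0.001

    def test_too_small_block_rejected(self, rng):
        profiles = rng.random((40, 30)) * 0.5 + 0.2
        with pytest.raises(ValueError, match="singular|block"):
            md_function(profiles, 5)

    def test_admissible_positions(self, rng):
        profiles = rng.random((60, 30)) * 0.5 + 0.2
        df = md_function(profiles, 15)
        assert df.positions[0] == 15 and df.positions[-1] == 45
        assert df.n_positions == 31

    def test_monotone_signal_on_noise_free_ribbons(self):
        # doubling the between-area density step never decreases the peak MD
        peaks = []
        for step in (0.05, 0.10):
            m1 = make_laminar_model([0.5, 0.5], [0.4, 0.4])
            m2 = make_laminar_model([0.5, 0.5], [0.4 + step, 0.4])
            rib = render_ribbon([m1, m2], [30, 30])
            df = md_function(rib.profiles, 12, shrinkage=0.5)
            peaks.append(df.md.max())
        assert peaks[1] >= peaks[0]


class TestHotelling:
    def test_zero_distance_p_one(self):
        assert hotelling_p(0.0, 20, 20) == 1.0

    def test_matches_f_distribution_quantile(self):
        # direct check of the T^2 -> F mapping at one point
        from scipy import stats
        md2 = 3.7
        t2 = (20 * 20 / 40) * md2
        f = (40 - 10 - 1) / ((40 - 2) * 10) * t2
        assert hotelling_p(md2, 20, 20) == pytest.approx(stats.f.sf(f, 10, 29))

    def test_blocks_too_small_rejected(self):
        with pytest.raises(ValueError):
            hotelling_p(1.0, 5, 5)


class TestDetectBorders:
    def test_noise_free_single_area_empty(self):
        m = make_laminar_model([0.5, 0.5], [0.6, 0.3])
        rib = render_ribbon([m], [60])
        result = detect_borders(rib.profiles, depth_grid=rib.depth_grid,
                                block_range=(12, 24))
        assert len(result) == 0

    def test_two_area_border_with_consecutive_support(self, agranular_model,
                                                      contrast_model):
        rib = render_ribbon([agranular_model, contrast_model], [76, 86], seed=8)
        result = detect_borders(rib.profiles, depth_grid=rib.depth_grid)
        assert len(result.borders) == 1
        b = result.borders[0]
        assert abs(b - 76) <= 3
        support = np.array(result.support[b])
        # at least five consecutive block sizes agree on the border
        runs = np.split(support, np.nonzero(np.diff(support) > 1)[0] + 1)
        assert max(len(r) for r in runs) >= 5

    def test_three_area_recovery_over_seeds(self):
        m1 = make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2],
                                [0.60, 0.40, 0.30, 0.50, 0.45], 0.03, "A")
        m2 = make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2],
                                [0.60, 0.55, 0.30, 0.50, 0.60], 0.03, "B")
        m3 = make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2],
                                [0.45, 0.40, 0.45, 0.65, 0.45], 0.03, "C")
        hits = 0
        for seed in range(50):
            rib = render_ribbon([m1, m2, m3], [60, 60, 60], seed=seed)
            res = detect_borders(rib.profiles, depth_grid=rib.depth_grid)
            ok = (len(res.borders) == 2
                  and abs(res.borders[0] - 60) <= 3
                  and abs(res.borders[1] - 120) <= 3)
            hits += ok
        assert hits >= 48          # >= 95% of 50 seeds

    def test_reversed_ribbon_mirrors_borders(self, agranular_model, contrast_model):
        rib = render_ribbon([agranular_model, contrast_model], [70, 92], seed=9)
        n = rib.profiles.shape[0]
        fwd = detect_borders(rib.profiles, depth_grid=rib.depth_grid)
        rev = detect_borders(rib.profiles[::-1], depth_grid=rib.depth_grid)
        mirrored = sorted(n - b for b in rev.borders)
        assert len(fwd.borders) == len(mirrored) == 1
        assert abs(fwd.borders[0] - mirrored[0]) <= 1

    def test_alpha_validation(self, agranular_model):
        rib = render_ribbon([agranular_model], [60], seed=0)
        with pytest.raises(ValueError):
            detect_borders(rib.profiles, alpha=0.0)

    def test_empty_block_range_rejected(self, agranular_model):
        rib = render_ribbon([agranular_model], [20], seed=0)
        with pytest.raises(ValueError, match="admissible"):
            detect_borders(rib.profiles, block_range=(12, 24))


class TestSignificantMaxima:
    def test_plateau_collapsed_to_midpoint(self):
        from cytoborder.borders import DistanceFunction
        md = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        df = DistanceFunction(block_size=12, positions=np.arange(12, 19),
                              md=md, pvalues=np.full(7, 1e-5),
                              pvalues_raw=np.full(7, 1e-6))
        assert significant_maxima(df, 0.001) == [15]

    def test_endpoint_maxima_excluded(self):
        from cytoborder.borders import DistanceFunction
        md = np.array([5.0, 1.0, 0.5, 1.0, 4.0])
        df = DistanceFunction(block_size=12, positions=np.arange(12, 17),
                              md=md, pvalues=np.full(5, 1e-5),
                              pvalues_raw=np.full(5, 1e-6))
        assert significant_maxima(df, 0.001) == []
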