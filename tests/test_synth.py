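"""Statistical structure of the synthetic canopy-scene generator."""

import numpy as np
import pytest
from scipy import stats

from ndwti.synth import (
    POST_HEADING_AGB_RANGE,
    SceneConfig,
    generate_dataset,
    generate_sample,
)
from ndwti.wavelet import haar_dwt2


def roi_ndvi(sample):
    nir = sample.patches["nir"].mean()
    red = sample.patches["red"].mean()
    return (nir - red) / (nir + red)


class TestGenerateSample:
    def test_agb_outside_range_rejected(self, deterministic_config, rng):
        with pytest.raises(ValueError, match="outside"):
            generate_sample(deterministic_config, 1e6, rng)

    def test_minimum_agb_is_mostly_soil(self, deterministic_config, rng):
        """At the AGB range floor the canopy barely covers the quadrat, so
        ROI-mean NDVI stays below 0.2 (derived from the generator's
        canopy/soil reflectance constants and the cover link)."""
        lo, _ = deterministic_config.agb_range
        s = generate_sample(deterministic_config, lo, rng)
        assert roi_ndvi(s) < 0.2
        cover = s.patches["nir"] > 0.3  # canopy NIR 0.45 vs soil 0.20
        assert cover.mean() < 0.25

    def test_seeded_determinism(self, deterministic_config):
        a = generate_sample(deterministic_config, 500.0, np.random.default_rng(5))
        b = generate_sample(deterministic_config, 500.0, np.random.default_rng(5))
        for band in a.patches:
            np.testing.assert_array_equal(a.patches[band], b.patches[band])

    def test_canopy_nir_exceeds_red_soil_flat(self, deterministic_config, rng):
        s = generate_sample(deterministic_config, 1000.0, rng)
        canopy = s.patches["nir"] > 0.3
        assert (s.patches["nir"][canopy] > s.patches["red"][canopy]).all()
        soil = ~canopy
        np.testing.assert_allclose(
            s.patches["nir"][soil], s.patches["red"][soil], atol=0.05
        )

    def test_ndvi_tracks_agb_monotonically(self):
        """The cover link itself is monotone: with no canopy-architecture
        jitter, Spearman(AGB, ROI NDVI) > 0.9 pre-heading at n = 200; with
        the default jitter the rank link stays above 0.8."""
        lo, hi = SceneConfig(stage="pre_heading").agb_range
        rng = np.random.default_rng(42)
        agbs = rng.uniform(lo, hi, size=200)
        for jitter, floor in ((0.0, 0.9), (None, 0.8)):
            kwargs = {} if jitter is None else {"cover_jitter_sd": jitter}
            cfg = SceneConfig(stage="pre_heading", patch_size=16, seed=11, **kwargs)
            sample_rng = np.random.default_rng(42)
            ndvis = [roi_ndvi(generate_sample(cfg, a, sample_rng)) for a in agbs]
            assert stats.spearmanr(agbs, ndvis).statistic > floor

    def test_ndvi_saturates_at_high_cover(self, deterministic_config):
        """The NDVI spread over the top AGB quartile is narrower than over
        the bottom quartile: the cover link saturates."""
        cfg = deterministic_config
        lo, hi = cfg.agb_range
        grid = np.linspace(lo, hi, 80)
        rng = np.random.default_rng(3)
        ndvi = np.array([roi_ndvi(generate_sample(cfg, a, rng)) for a in grid])
        q = len(grid) // 4
        assert np.ptp(ndvi[-q:]) < np.ptp(ndvi[:q])

    def test_speckle_raises_hh_variance(self):
        """Panicle speckle strictly raises mean HH-subband variance over
        matched seeds (paired comparison, 50 seeds)."""
        diffs = []
        for seed in range(50):
            base = dict(stage="post_heading", patch_size=16, noise_sd=0.005)
            with_sp = SceneConfig(speckle_density=6e-5, **base)
            without = SceneConfig(speckle_density=0.0, **base)
            agb = 1500.0
            hh = {}
            for name, cfg in (("sp", with_sp), ("no", without)):
                s = generate_sample(cfg, agb, np.random.default_rng(seed))
                hh[name] = haar_dwt2(s.patches["red"]).hh.var()
            diffs.append(hh["sp"] - hh["no"])
        diffs = np.asarray(diffs)
        assert diffs.mean() > 0
        assert (diffs > 0).mean() >= 0.9

    def test_hh_variance_at_noise_floor_without_canopy_texture(self):
        """With no canopy (cover ~ 0) and no speckle, HH variance reduces to
        the sensor-noise level: each HH coefficient is a +-1/2 combination of
        four iid noise pixels, so Var(HH) ~ noise_sd^2."""
        cfg = SceneConfig(
            stage="pre_heading",
            patch_size=16,
            coverage_gain=1e-9,  # cover ~ 0 over the whole range
            noise_sd=0.01,
            illumination_sd=0.0,
            cover_jitter_sd=0.0,
        )
        rng = np.random.default_rng(8)
        hh_vars = [
            haar_dwt2(generate_sample(cfg, 500.0, rng).patches["red"]).hh.var()
            for _ in range(50)
        ]
        assert np.mean(hh_vars) < 3 * cfg.noise_sd**2


class TestGenerateDataset:
    def test_plot_layout_gives_eighteen_samples(self):
        cfg = SceneConfig(plot_rows=3, plot_cols=6, patch_size=8, seed=0)
        assert len(generate_dataset(cfg)) == 18

    def test_reproducible_under_seed(self):
        cfg = SceneConfig(patch_size=8, seed=13)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for sa, sb in zip(a, b):
            assert sa.agb == sb.agb
            np.testing.assert_array_equal(sa.patches["nir"], sb.patches["nir"])

    def test_different_seeds_same_marginal_agb(self):
        """Different seeds change the patches but not the AGB distribution
        (KS test on the uniform draws)."""
        cfg_a = SceneConfig(patch_size=8, seed=1)
        cfg_b = SceneConfig(patch_size=8, seed=2)
        a = [s.agb for s in generate_dataset(cfg_a, n_draws=10)]
        b = [s.agb for s in generate_dataset(cfg_b, n_draws=10)]
        assert not np.allclose(
            generate_dataset(cfg_a)[0].patches["nir"],
            generate_dataset(cfg_b)[0].patches["nir"],
        )
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SceneConfig(patch_size=7)
        with pytest.raises(ValueError):
            SceneConfig(stage="ripening")
        with pytest.raises(ValueError):
            SceneConfig(agb_range=(500.0, 100.0))


def test_post_heading_range_defaults():
    cfg = SceneConfig(stage="post_heading")
    assert cfg.agb_range == POST_HEADING_AGB_RANGE
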