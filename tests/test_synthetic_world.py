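import numpy as np
import pytest

from rangeshift.bioclim import compute_bioclim
from rangeshift.synthetic_world import (NicheSpec, ScenarioDelta, WorldConfig,
                                        _correlated_field, apply_scenario,
                                        generate_world, sample_occurrences,
                                        true_suitability)


def small_cfg(**kw):
    base = dict(west=0.0, south=38.0, east=6.0, north=41.0, seed=1)
    base.update(kw)
    return WorldConfig(**base)


class TestGenerateWorld:
    def test_determinism_bit_for_bit(self):
        w1 = generate_world(small_cfg(seed=9))
        w2 = generate_world(small_cfg(seed=9))
        assert np.array_equal(w1.cube.tavg, w2.cube.tavg)
        assert np.array_equal(w1.cube.prec, w2.cube.prec)
        assert np.array_equal(w1.dem.values, w2.dem.values)
        for name in w1.landuse:
            assert np.array_equal(w1.landuse[name].values,
                                  w2.landuse[name].values)

    def test_zero_noise_flat_world_is_pure_seasonal_cycle(self):
        cfg = small_cfg(temp_noise_sd=0.0, temp_lat_gradient=0.0,
                        amplitude_variation=0.0, dem_relief=0.0)
        w = generate_world(cfg)
        months = np.arange(12)
        cycle = cfg.temp_south + cfg.seasonal_amplitude * np.cos(
            2 * np.pi * (months - 6) / 12)
        for m in range(12):
            assert np.allclose(w.cube.tavg[m], cycle[m])
        assert np.allclose(w.dem.values, cfg.dem_mean)

    def test_physicality_invariants(self):
        w = generate_world(small_cfg(seed=3))
        assert np.all(w.cube.tmin <= w.cube.tavg + 1e-12)
        assert np.all(w.cube.tavg <= w.cube.tmax + 1e-12)
        assert np.all(w.cube.prec >= 0)
        total = sum(l.values for l in w.landuse.values())
        assert np.all(total <= 1 + 1e-9)
        assert all(np.all((l.values >= 0) & (l.values <= 1))
                   for l in w.landuse.values())

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(west=5.0, east=5.0)
        with pytest.raises(ValueError):
            WorldConfig(resolution_arcmin=0.0)

    def test_correlation_length_recovered_by_variogram(self):
        # brute-force semivariogram range vs the configured e-folding length
        L = 10.0
        f = _correlated_field(np.random.default_rng(42), (200, 200), L)
        sill = f.var()
        gamma = [0.5 * np.mean((f[:, d:] - f[:, :-d]) ** 2)
                 for d in range(1, 31)]
        est = 1 + int(np.argmax(np.array(gamma) >= (1 - np.exp(-1)) * sill))
        assert abs(est - L) <= 0.3 * L


class TestApplyScenario:
    def test_identity_delta(self):
        w = generate_world(small_cfg())
        out = apply_scenario(w, ScenarioDelta("same", 0.0, 1.0))
        assert np.array_equal(out.cube.tavg, w.cube.tavg)
        assert np.array_equal(out.cube.prec, w.cube.prec)

    def test_uniform_warming_is_additive(self):
        w = generate_world(small_cfg())
        out = apply_scenario(w, ScenarioDelta("warm", 2.0))
        assert np.allclose(out.cube.tavg - w.cube.tavg, 2.0)
        assert np.allclose(out.cube.tmax - w.cube.tmax, 2.0)

    def test_halved_precipitation_halves_bio12(self):
        w = generate_world(small_cfg())
        out = apply_scenario(w, ScenarioDelta("dry", 0.0, 0.5))
        bio_cur = compute_bioclim(w.cube)["BIO12"].values
        bio_fut = compute_bioclim(out.cube)["BIO12"].values
        assert np.allclose(bio_fut, bio_cur / 2.0, rtol=1e-12)

    def test_landuse_transition_conserves_mass(self):
        w = generate_world(small_cfg())
        out = apply_scenario(w, ScenarioDelta(
            "urbanising", landuse_transitions={("crop", "urban"): 0.3}))
        before = w.landuse["crop"].values + w.landuse["urban"].values
        after = out.landuse["crop"].values + out.landuse["urban"].values
        assert np.allclose(before, after)
        assert np.all(out.landuse["crop"].values <= w.landuse["crop"].values)

    def test_current_label_reserved(self):
        with pytest.raises(ValueError):
            ScenarioDelta("current", 1.0)


class TestTrueSuitability:
    def test_null_niche_gives_half(self, small_world):
        suit = true_suitability(small_world, NicheSpec("sp"))
        assert np.allclose(suit.grid.values, 0.5)

    def test_saturating_intercept(self, small_world):
        suit = true_suitability(small_world, NicheSpec("sp", intercept=40.0))
        assert np.allclose(suit.grid.values, 1.0)

    def test_monotone_in_single_predictor(self, small_world):
        niche = NicheSpec("sp", linear={"BIO1": 1.0},
                          centers={"BIO1": 14.0}, scales={"BIO1": 2.0})
        suit = true_suitability(small_world, niche)
        x = small_world.predictor_stack().layers["BIO1"].values.ravel()
        order = np.argsort(x)
        s = suit.grid.values.ravel()[order]
        assert np.all(np.diff(s) >= 0)

    def test_unknown_predictor_rejected(self, small_world):
        with pytest.raises(ValueError, match="unknown predictors"):
            true_suitability(small_world, NicheSpec("sp", linear={"BIO99": 1}))


class TestSampleOccurrences:
    def test_point_mass(self, small_world):
        suit = true_suitability(small_world, NicheSpec("sp", intercept=-40.0))
        g = suit.grid
        g.values[10, 20] = 1.0
        occ = sample_occurrences(suit, 50, seed=1)
        row, col = g.cell_index(occ.records.lon.to_numpy(),
                                occ.records.lat.to_numpy())
        assert np.all(row == 10) and np.all(col == 20)

    def test_two_level_sampling_ratio(self, small_world):
        suit = true_suitability(small_world, NicheSpec("sp", intercept=-40.0))
        g = suit.grid
        half = g.ncols // 2
        g.values[:, :half] = 0.8
        g.values[:, half:] = 0.2
        n = 10_000
        occ = sample_occurrences(suit, n, seed=2)
        _, col = g.cell_index(occ.records.lon.to_numpy(),
                              occ.records.lat.to_numpy())
        frac_high = np.mean(col < half)
        p = 0.8 / (0.8 + 0.2)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac_high - p) < 4 * se

    def test_deterministic_and_zero_mass_rejected(self, small_world):
        suit = true_suitability(small_world, NicheSpec("sp", intercept=-1.0))
        a = sample_occurrences(suit, 20, seed=7)
        b = sample_occurrences(suit, 20, seed=7)
        assert a.records.equals(b.records)
        zero = true_suitability(small_world, NicheSpec("sp", intercept=-40.0))
        zero.grid.values[:] = 0.0
        with pytest.raises(ValueError, match="sampleable"):
            sample_occurrences(zero, 5, seed=0)

    def test_uncertainty_within_range(self, small_world):
        suit = true_suitability(small_world, NicheSpec("sp"))
        occ = sample_occurrences(suit, 200, seed=3,
                                 uncertainty_range_km=(2.0, 4.0))
        unc = occ.records.uncertainty_km
        assert unc.between(2.0, 4.0).all()
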