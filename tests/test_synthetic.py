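import hashlib
from importlib import resources

import numpy as np
import pytest

from maxniche import rarefy, reference_tables, valid_mask
from maxniche.synthetic import (
    make_virtual_niche,
    make_zones,
    perturb_scenario,
    sample_presences,
    simulate_bioclim_stack,
)

UNIFORM_CLOGLOG = 1.0 - np.exp(-1.0)


class TestStackSimulation:
    def corr(self, stack):
        codes = stack.codes
        X = np.column_stack([stack[c].values.ravel() for c in codes])
        return np.corrcoef(X, rowvar=False)

    def test_identity_target_gives_weak_correlations(self):
        # smoothing leaves ~ (side/smoothing)^2 effective samples, so the
        # grid must be large for the 0.1 noise bound to hold
        stack = simulate_bioclim_stack((300, 300), n_layers=4, smoothing=5, seed=0)
        r = self.corr(stack)
        off = r[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_strong_target_reached_within_tolerance(self):
        target = np.eye(3)
        target[0, 1] = target[1, 0] = 0.95
        stack = simulate_bioclim_stack((200, 200), n_layers=3, corr_target=target,
                                       smoothing=5, seed=1)
        r = self.corr(stack)
        assert abs(r[0, 1] - 0.95) < 0.05

    def test_seeded_determinism_bit_identical(self):
        a = simulate_bioclim_stack((50, 50), n_layers=3, smoothing=3, seed=9)
        b = simulate_bioclim_stack((50, 50), n_layers=3, smoothing=3, seed=9)
        for code in a.codes:
            assert np.array_equal(a[code].values, b[code].values)

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_bioclim_stack((20, 20), n_layers=3, corr_target=bad, seed=0)


class TestVirtualNiche:
    def test_zero_lambda_gives_uniform_suitability(self, small_stack):
        niche = make_virtual_niche(small_stack, {"Bio1": 0.0})
        assert np.allclose(niche.true_suitability.valid_values(), UNIFORM_CLOGLOG)

    def test_monotone_along_gradient(self):
        from maxniche import Grid, stack_layers

        ramp = np.tile(np.linspace(0, 1, 30), (10, 1))
        stack = stack_layers([("g", Grid(ramp, (0.0, 10.0, 1.0)))])
        niche = make_virtual_niche(stack, {"g": 5.0})
        row = niche.true_suitability.values[0]
        assert np.all(np.diff(row) > 0)

    def test_sharper_lambda_raises_variance(self, small_stack):
        weak = make_virtual_niche(small_stack, {"Bio1": 2.0})
        strong = make_virtual_niche(small_stack, {"Bio1": 4.0})
        assert strong.true_suitability.valid_values().var() > \
            weak.true_suitability.valid_values().var()

    def test_raw_sums_to_one(self, small_niche):
        assert small_niche.true_raw.valid_values().sum() == pytest.approx(1.0)

    def test_unknown_variable_rejected(self, small_stack):
        with pytest.raises(ValueError, match="Bio99"):
            make_virtual_niche(small_stack, {"Bio99": 1.0})


class TestPresenceSampling:
    def test_density_proportional_sampling(self):
        """Two-cell world with raw (0.9, 0.1): ~90% of singleton draws hit
        the dense cell."""
        from maxniche import Grid, stack_layers

        vals = np.array([[np.log(9.0), 0.0]])
        stack = stack_layers([("g", Grid(vals, (0.0, 1.0, 1.0)))])
        # scaled layer is (1, 0) so raw = (9/10, 1/10) with lambda = ln 9
        niche = make_virtual_niche(stack, {"g": np.log(9.0)})
        assert niche.true_raw.values[0, 0] == pytest.approx(0.9)
        hits = 0
        n = 4000
        for s in range(n):
            occ = sample_presences(niche, n=1, seed=s)
            lon = occ.records[0][0]
            hits += lon < 1.0
        # se = sqrt(.9*.1/4000) ~ 0.0047
        assert abs(hits / n - 0.9) < 0.02

    def test_duplicate_fraction_removed_by_rarefaction(self, small_niche, small_stack):
        occ = sample_presences(small_niche, n=100, dup_rate=0.5, seed=3)
        thin = rarefy(occ, valid_mask(small_stack))
        assert len(occ) == 100 and len(thin) == 50

    def test_no_duplicates_all_survive(self, small_niche, small_stack):
        occ = sample_presences(small_niche, n=80, dup_rate=0.0, seed=4)
        assert len(rarefy(occ, valid_mask(small_stack))) == 80

    def test_seeded_determinism(self, small_niche):
        a = sample_presences(small_niche, n=30, dup_rate=0.2, seed=5)
        b = sample_presences(small_niche, n=30, dup_rate=0.2, seed=5)
        assert a.records == b.records


class TestScenarioPerturbation:
    def test_zero_delta_identical(self, small_stack):
        out = perturb_scenario(small_stack, {"Bio1": (0.0, 1.0)})
        for code in small_stack.codes:
            assert np.array_equal(out[code].values, small_stack[code].values)

    def test_shift_moves_niche_optimum_along_gradient(self):
        """On a monotone ramp a favourable warming shift relocates the most
        suitable cells toward previously cooler positions."""
        from maxniche import Grid, stack_layers

        ramp = np.tile(np.linspace(0.0, 10.0, 50), (5, 1))
        stack = stack_layers([("t", Grid(ramp, (0.0, 5.0, 1.0)))])
        future = perturb_scenario(stack, {"t": (2.0, 1.0)})
        assert np.allclose(future["t"].values, ramp + 2.0)

    def test_masks_unchanged(self):
        from maxniche import Grid, stack_layers

        vals = np.array([[1.0, -9999.0], [3.0, 4.0]])
        stack = stack_layers([("t", Grid(vals, (0, 2, 1), nodata=-9999.0))])
        future = perturb_scenario(stack, {"t": (100.0, 2.0)})
        assert np.array_equal(future["t"].mask, stack["t"].mask)

    def test_unknown_layer_rejected(self, small_stack):
        with pytest.raises(ValueError):
            perturb_scenario(small_stack, {"nope": (1.0, 1.0)})


class TestZones:
    def test_single_zone_covers_everything(self):
        zones = make_zones((10, 10), k=1, seed=0)
        assert zones.labels == [1]
        assert (zones.zone_raster.values == 1).all()

    def test_partition_area_sums(self):
        zones = make_zones((12, 12), k=4, seed=1)
        total = sum(a for _, a in zones.table.values())
        assert total == pytest.approx(12 * 12 * 4.5)
        covered = (zones.zone_raster.values > 0).sum()
        assert covered == 144

    def test_zones_are_contiguous(self):
        from scipy.ndimage import label

        zones = make_zones((20, 20), k=5, seed=2)
        for z in zones.labels:
            _, n_components = label(zones.zone_raster.values == z)
            assert n_components == 1

    def test_determinism_and_k_too_large(self):
        a = make_zones((8, 8), k=3, seed=4)
        b = make_zones((8, 8), k=3, seed=4)
        assert np.array_equal(a.zone_raster.values, b.zone_raster.values)
        with pytest.raises(ValueError):
            make_zones((2, 2), k=5, seed=0)


class TestReferenceTables:
    EXPECTED_SHA256 = {
        "variable_contributions.csv":
            "321834d0dcf8c957d9e6493f47e77bf6e0e1c448246e2c951011fc8b988673a0",
        "evaluation_scores.csv":
            "bc3a566f564d0ba72cfa6a0fb60fadcc9b1e919d254a9cdc5b301be32bdcaae2",
        "continent_area_change.csv":
            "807092df7a2dfe93c28eefcf660eb8095c188ae36a858b5f762c2460fd3dd080",
        "korea_ad_areas.csv":
            "5f525c70d932787984112e5252a6e4a5d860f954fc44f9f5e7004a760da9e7cf",
    }

    def test_packaged_tables_unchanged(self):
        for name, expected in self.EXPECTED_SHA256.items():
            data = resources.files("maxniche.data").joinpath(name).read_bytes()
            assert hashlib.sha256(data).hexdigest() == expected, name

    def test_shapes_and_key_values(self):
        t = reference_tables()
        assert len(t.korea_ad_areas) == 17
        numeric = t.korea_ad_areas.select_dtypes("number")
        assert numeric.shape[1] == 10  # total + current + 8 scenario periods
        after = t.evaluation_scores.set_index("parameter")["after_rarefying"]
        assert after["AUC"] == pytest.approx(0.776)
        contrib = t.variable_contributions.set_index("code")["model_contribution_pct"]
        assert contrib["Bio2"] == pytest.approx(0.40)
        assert len(t.continent_area_change) == 8
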