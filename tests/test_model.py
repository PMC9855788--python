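import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from maxniche import (
    FeatureSet,
    MaxEnt,
    ensemble_replicates,
    fit_maxent,
    jackknife_gains,
    mtss_from_model,
    percent_contribution,
    permutation_importance,
    predict_cloglog,
    predict_raw,
    roc_auc,
)
from maxniche import synthetic, valid_mask

UNIFORM_CLOGLOG = 1.0 - np.exp(-1.0)


def penalized_objective(lam, Fp, Fb, beta):
    """The L1-regularised negative log-likelihood, written independently."""
    lam = np.atleast_1d(lam)
    eta = Fb @ lam
    return float(-Fp.mean(axis=0) @ lam + logsumexp(eta) - np.log(len(Fb))
                 + beta @ np.abs(lam))


class TestFit:
    def test_no_signal_heavy_regularization_gives_uniform(self):
        rng = np.random.default_rng(0)
        B = pd.DataFrame({"x": rng.uniform(0, 1, 100)})
        P = B.iloc[rng.choice(100, 30)]
        m = fit_maxent(P, B, reg_multiplier=100.0, feature_classes={"L"})
        assert np.allclose(m.lambda_, 0.0)
        assert np.allclose(m.raw_, 1.0 / 100)
        assert np.allclose(m.predict(B), UNIFORM_CLOGLOG)
        assert m.entropy_ == pytest.approx(np.log(100))

    def test_positive_association_gives_positive_weight(self):
        rng = np.random.default_rng(1)
        B = pd.DataFrame({"x": rng.uniform(0, 1, 200)})
        P = pd.DataFrame({"x": rng.uniform(0.8, 1.0, 50)})
        m = fit_maxent(P, B, feature_classes={"L"})
        assert m.lambda_[0] > 0

    def test_objective_at_fit_beats_zero_and_gain_nonnegative(self, small_fit):
        m, P, B = small_fit
        Fp = m.features_.transform(P.to_numpy())
        Fb = m.features_.transform(B.to_numpy())
        J_fit = penalized_objective(m.lambda_, Fp, Fb, m.beta_)
        J_zero = penalized_objective(np.zeros_like(m.lambda_), Fp, Fb, m.beta_)
        assert J_fit <= J_zero + 1e-12
        assert m.gain_ >= 0

    def test_matches_brute_force_grid_search_one_feature(self):
        """On a 20-cell toy the coordinate-descent optimum agrees with an
        exhaustive grid search over lambda to 2e-3."""
        rng = np.random.default_rng(2)
        B = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        P = pd.DataFrame({"x": rng.choice(B["x"].to_numpy()[12:], 8)})
        m = fit_maxent(P, B, feature_classes={"L"}, tol=1e-10, max_iter=2000)
        Fp = m.features_.transform(P.to_numpy())
        Fb = m.features_.transform(B.to_numpy())
        grid = np.arange(-10.0, 10.0, 1e-3)
        J = [penalized_objective(l, Fp, Fb, m.beta_) for l in grid]
        lam_star = grid[int(np.argmin(J))]
        assert m.lambda_[0] == pytest.approx(lam_star, abs=2e-3)

    def test_matches_brute_force_grid_search_two_features(self):
        rng = np.random.default_rng(3)
        B = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        P = pd.DataFrame({"x": np.r_[rng.uniform(0.4, 0.7, 10)]})
        m = fit_maxent(P, B, feature_classes={"L", "Q"}, tol=1e-10, max_iter=5000)
        Fp = m.features_.transform(P.to_numpy())
        Fb = m.features_.transform(B.to_numpy())
        # nested grid search: coarse sweep, then refine around the optimum
        lo = np.array([-10.0, -10.0]); hi = np.array([10.0, 10.0])
        best = np.zeros(2)
        for step in (0.5, 0.05, 5e-3, 5e-4):
            g1 = np.arange(lo[0], hi[0] + step, step)
            g2 = np.arange(lo[1], hi[1] + step, step)
            J = [[penalized_objective(np.array([a, b]), Fp, Fb, m.beta_) for b in g2]
                 for a in g1]
            i, j = np.unravel_index(np.argmin(J), (len(g1), len(g2)))
            best = np.array([g1[i], g2[j]])
            lo, hi = best - 2 * step, best + 2 * step
        assert np.allclose(m.lambda_, best, atol=2e-3)

    def test_nonfinite_input_rejected(self):
        B = pd.DataFrame({"x": [0.0, 1.0, np.nan]})
        with pytest.raises(ValueError):
            fit_maxent(pd.DataFrame({"x": [0.5]}), B)


class TestRawOutput:
    def test_raw_sums_to_one_and_matches_softmax(self, small_fit):
        m, P, B = small_fit
        assert m.raw_.sum() == pytest.approx(1.0)
        eta = m.features_.transform(B.to_numpy()) @ m.lambda_
        q = np.exp(eta - logsumexp(eta))
        assert np.allclose(predict_raw(m, B), q)

    def test_raw_closed_form_softmax(self):
        """lambda.f = (0, ln2, ln4) over three background cells gives raw
        (1/7, 2/7, 4/7)."""
        B = np.array([[0.0], [5.0], [10.0]])  # linear feature -> (0, .5, 1)
        m = MaxEnt(feature_classes={"L"})
        m.features_ = FeatureSet.from_background(B, codes=["x"], classes={"L"})
        m.codes_ = ["x"]
        lam = np.array([2.0 * np.log(2.0)])  # eta = (0, ln2, ln4)
        eta = m.features_.transform(B) @ lam
        m.lambda_ = lam
        m.log_z_ = float(logsumexp(eta) - np.log(3))
        m.n_background_ = 3
        m.background_X_ = B
        q = np.exp(eta - logsumexp(eta))
        m.raw_ = q
        assert np.allclose(predict_raw(m, B), [1 / 7, 2 / 7, 4 / 7])

    def test_raw_undefined_off_background(self, small_fit):
        m, P, B = small_fit
        with pytest.raises(ValueError, match="background"):
            predict_raw(m, P)


class TestCloglog:
    def test_uniform_model_constant_one_minus_inv_e(self, small_stack):
        rng = np.random.default_rng(5)
        mask = valid_mask(small_stack)
        from maxniche import sample_background
        bg = sample_background(mask, 400, seed=6)
        B = pd.DataFrame(small_stack.values_at(bg.cells), columns=small_stack.codes)
        P = B.iloc[rng.choice(len(B), 50)]
        m = fit_maxent(P, B, reg_multiplier=1000.0, feature_classes={"L"})
        g = predict_cloglog(m, small_stack)
        assert np.allclose(g.valid_values(), UNIFORM_CLOGLOG, atol=1e-9)

    def test_range_and_monotonicity(self, small_fit, small_stack):
        m, P, B = small_fit
        g = predict_cloglog(m, small_stack)
        v = g.valid_values()
        assert v.min() >= 0 and v.max() <= 1
        eta = m.decision_function(B)
        c = m.predict(B)
        order = np.argsort(eta)
        assert np.all(np.diff(c[order]) >= -1e-15)

    def test_missing_layer_named(self, small_fit, small_stack):
        m, _, _ = small_fit
        partial = small_stack.subset(small_stack.codes[:2])
        with pytest.raises(ValueError, match=small_stack.codes[-1]):
            predict_cloglog(m, partial)


class TestImportance:
    def test_single_variable_contribution_is_100(self):
        rng = np.random.default_rng(7)
        B = pd.DataFrame({"x": rng.uniform(0, 1, 150)})
        P = pd.DataFrame({"x": rng.uniform(0.7, 1.0, 40)})
        m = fit_maxent(P, B, feature_classes={"L", "Q"})
        assert percent_contribution(m)["x"] == pytest.approx(100.0)

    def test_contributions_sum_to_100_and_informative_dominates(self, small_fit):
        m, P, B = small_fit
        contrib = percent_contribution(m)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)
        assert max(contrib, key=contrib.get) in {"Bio1", "Bio3"}

    def test_permutation_importance_normalised_and_ranked(self, small_fit):
        m, P, B = small_fit
        imp = permutation_importance(m, P, B, seed=0)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)
        assert max(imp, key=imp.get) in {"Bio1", "Bio3"}

    def test_zero_weight_variable_has_zero_importance(self):
        rng = np.random.default_rng(8)
        B = pd.DataFrame({"a": rng.uniform(0, 1, 200), "b": rng.uniform(0, 1, 200)})
        P = pd.DataFrame({"a": rng.uniform(0.75, 1.0, 40),
                          "b": rng.uniform(0, 1, 40)})
        m = fit_maxent(P, B, feature_classes={"L"}, reg_multiplier=2.0)
        j_b = [j for j, f in enumerate(m.features_.definitions) if f.variables == ("b",)]
        assert np.allclose(m.lambda_[j_b], 0.0)  # L1 zeroed the noise variable
        imp = permutation_importance(m, P, B, seed=1)
        assert imp["b"] == 0.0 and imp["a"] == pytest.approx(100.0)

    def test_jackknife_identifies_informative_variable(self):
        rng = np.random.default_rng(9)
        B = pd.DataFrame({"a": rng.uniform(0, 1, 200), "b": rng.uniform(0, 1, 200)})
        P = pd.DataFrame({"a": rng.uniform(0.75, 1.0, 50), "b": rng.uniform(0, 1, 50)})
        gains = jackknife_gains(P, B, feature_classes={"L", "Q"})
        full = fit_maxent(P, B, feature_classes={"L", "Q"})
        assert gains["a"][0] > 5 * max(gains["b"][0], 0.01)
        for v in ("a", "b"):
            assert gains[v][1] <= full.gain_ + 1e-3  # nested models

    def test_jackknife_needs_two_variables(self):
        B = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            jackknife_gains(B, B, variables=["a"])


class TestEnsemble:
    def make_occ(self, niche, n=80):
        return synthetic.sample_presences(niche, n=n, dup_rate=0.0, seed=13)

    def test_single_replicate_equals_its_grid(self, small_stack, small_niche):
        occ = self.make_occ(small_niche)
        ens = ensemble_replicates(occ, small_stack, n_replicates=1, n_background=300,
                                  seed=1, model_params={"feature_classes": {"L", "Q"}})
        assert len(ens.reports) == 1
        # rebuild the lone replicate by hand: same split seed, same background
        from maxniche import partition, rarefy, sample_background

        mask = valid_mask(small_stack)
        bg = sample_background(mask, 300, seed=1 + 90_001)
        B = pd.DataFrame(small_stack.values_at(bg.cells), columns=small_stack.codes)
        train, _ = partition(occ, 0.75, seed=1)
        cells = np.asarray([c for c in train.cells_on(mask)
                            if c is not None and mask.values[c] > 0])
        P = pd.DataFrame(small_stack.values_at(cells), columns=small_stack.codes)
        model = fit_maxent(P, B, feature_classes={"L", "Q"})
        g = predict_cloglog(model, small_stack)
        assert np.allclose(ens.mean_grid.values, g.values, equal_nan=True)

    def test_mean_grid_within_replicate_envelope_and_auc_stable(
        self, small_stack, small_niche
    ):
        occ = self.make_occ(small_niche)
        ens = ensemble_replicates(occ, small_stack, n_replicates=10, n_background=300,
                                  seed=2, model_params={"feature_classes": {"L", "Q"}})
        aucs = [r.auc for r in ens.reports]
        assert np.std(aucs) < 0.05
        v = ens.mean_grid.valid_values()
        assert v.min() >= 0 and v.max() <= 1
        t = mtss_from_model(ens.full_model)
        assert 0 <= t <= 1


class TestSerialization:
    def test_save_load_round_trip(self, small_fit, tmp_path):
        m, P, B = small_fit
        path = str(tmp_path / "model.json")
        m.save(path)
        back = MaxEnt.load(path)
        assert np.allclose(back.predict(B), m.predict(B))
        assert back.entropy_ == pytest.approx(m.entropy_)
        with pytest.raises(ValueError):
            mtss_from_model(back)  # training data not serialised
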