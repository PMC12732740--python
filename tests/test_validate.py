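import itertools
import math

import numpy as np
import pytest

from paneldx import simulate, validate
from paneldx.validate import (auc_632plus, boot632_validate, cohens_d,
                              firth_fit, nested_cv_firth)


def _sim(seed, n_genes=30, effect=4.0, n_de=4, groups=None):
    cfg = simulate.SimConfig(
        n_genes=n_genes, group_sizes=groups or {"H": 5, "C": 11},
        n_de_genes=n_de, effect_size_log2=effect, noise_sd=0.5,
        n_modules=0, module_size=1, seed=seed)
    return simulate.simulate_study(cfg)


class TestFirth:
    def test_separable_two_by_two_closed_form(self):
        # Firth on a saturated binary design equals the Haldane 1/2-cell
        # corrected log odds: slope log(25)/2, intercept 0
        m = firth_fit(np.array([-1.0, -1.0, 1.0, 1.0])[:, None], [0, 0, 1, 1])
        assert m.coefficients[1] == pytest.approx(math.log(25) / 2, abs=1e-6)
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert m.converged

    def test_grid_search_oracle_one_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = (x + rng.normal(scale=1.0, size=12) > 0).astype(int)
        if y.min() == y.max():  # ensure both classes
            y[0] = 1 - y[0]
        m = firth_fit(x[:, None], y)

        def pll(b0, b1):
            eta = b0 + b1 * x
            pi = 1 / (1 + np.exp(-eta))
            pi = np.clip(pi, 1e-12, 1 - 1e-12)
            ll = y @ np.log(pi) + (1 - y) @ np.log(1 - pi)
            w = pi * (1 - pi)
            xd = np.column_stack([np.ones_like(x), x])
            info = xd.T @ (xd * w[:, None])
            return ll + 0.5 * np.linalg.slogdet(info)[1]

        grid = np.linspace(-4, 4, 401)
        best = max(((b0, b1) for b0 in grid for b1 in grid),
                   key=lambda p: pll(*p))
        assert m.coefficients[0] == pytest.approx(best[0], abs=2e-2)
        assert m.coefficients[1] == pytest.approx(best[1], abs=2e-2)
        assert pll(*m.coefficients) >= pll(*best) - 1e-9

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = np.array([0, 1] * 10)
        a = firth_fit(x[:, None], y)
        b = firth_fit(-x[:, None], y)
        assert b.coefficients[1] == pytest.approx(-a.coefficients[1], abs=1e-8)
        assert b.coefficients[0] == pytest.approx(a.coefficients[0], abs=1e-8)

    def test_approaches_mle_at_large_n(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.uniform(size=500) < p).astype(int)
        m = firth_fit(x[:, None], y)
        mle = LogisticRegression(C=np.inf, max_iter=5000).fit(x[:, None], y)
        assert m.coefficients[1] == pytest.approx(float(mle.coef_[0][0]),
                                                  rel=0.02)

    def test_hat_diagonals_sum_to_n_params(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 3))
        y = (rng.uniform(size=25) < 0.5).astype(int)
        m = firth_fit(x, y)
        assert m.hat_diagonals.sum() == pytest.approx(4.0, abs=1e-6)
        assert np.all(m.hat_diagonals >= 0)
        assert np.all(m.hat_diagonals <= 1 + 1e-9)

    def test_rank_deficient_design_errors(self):
        x = np.ones((10, 2))
        x[:, 1] = 2 * x[:, 0]
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="collinear"):
            firth_fit(np.column_stack([np.arange(10.0), x]), y)


class TestNestedCv:
    def test_planted_panel_high_auc_majority(self):
        wins = 0
        for seed in range(20):
            sim = _sim(seed, effect=3.0, n_de=5)
            res = nested_cv_firth(sim.study, list(sim.study.feature_ids),
                                  "C", "H", seed=seed)
            wins += res.roc.auc >= 0.9
        assert wins > 10

    def test_null_auc_centered_at_half(self):
        # single-seed null AUCs at n=21 are very noisy (selection noise adds
        # to ranking noise), so check the mean over seeds
        aucs = []
        for s in range(6):
            sim = _sim(50 + s, effect=0.0, n_de=0, groups={"H": 10, "C": 11})
            res = nested_cv_firth(sim.study, list(sim.study.feature_ids),
                                  "C", "H", seed=s)
            aucs.append(res.roc.auc)
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_every_sample_scored_once(self):
        sim = _sim(7)
        res = nested_cv_firth(sim.study, list(sim.study.feature_ids),
                              "C", "H", seed=1)
        assert np.all(np.isfinite(res.oof_scores))
        assert len(res.oof_scores) == 16
        # each fold is non-empty and a partition
        assert set(res.fold_assignments) == set(range(5))

    def test_selection_uses_top_m(self):
        sim = _sim(8)
        res = nested_cv_firth(sim.study, list(sim.study.feature_ids),
                              "C", "H", top_m=3, seed=2)
        assert all(len(s) == 3 for s in res.selected_genes_per_fold)

    def test_deterministic(self):
        sim = _sim(9)
        a = nested_cv_firth(sim.study, list(sim.study.feature_ids),
                            "C", "H", seed=3)
        b = nested_cv_firth(sim.study, list(sim.study.feature_ids),
                            "C", "H", seed=3)
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)


class TestAuc632Plus:
    def test_hand_arithmetic(self):
        # err_app=0, err_oob=0.4, gamma=0.5 -> R=0.8, w=0.632/0.7056,
        # err632+=0.3583..., auc=0.6417
        assert auc_632plus(1.0, 0.6) == pytest.approx(0.6417, abs=5e-5)

    def test_fixed_point_when_errors_equal(self):
        # holds whenever err is not clipped by gamma, i.e. auc >= 0.5
        for auc in (0.5, 0.6, 0.8, 1.0):
            assert auc_632plus(auc, auc) == pytest.approx(auc)

    def test_between_apparent_and_oob_when_oob_below_gamma(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            app = rng.uniform(0.5, 1.0)
            oob = rng.uniform(0.5, 1.0)
            out = auc_632plus(app, oob)
            assert min(app, oob) - 1e-12 <= out <= max(app, oob) + 1e-12


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_hand_example(self):
        assert cohens_d([0.9, 1.0, 1.1], [0.4, 0.5, 0.6]) == pytest.approx(5.0)

    def test_swap_negates(self):
        a, b = [1.0, 2.0, 4.0], [0.5, 1.5, 2.0]
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_sd_sentinel(self):
        assert cohens_d([1.0, 1.0], [0.0, 0.0]) == math.inf


@pytest.fixture(scope="module")
def strong_report():
    sim = _sim(21, effect=4.0, n_de=4)
    return boot632_validate(sim.study, list(sim.truth_panel), "C", "H",
                            B=200, P=200, seed=0)


class TestBoot632Validate:
    def test_strong_panel_regime(self, strong_report):
        rep = strong_report
        assert rep.boot.oob_median == pytest.approx(1.0)
        assert rep.empirical_p < 0.05
        assert rep.cohens_d > 2.0

    def test_summary_invariants(self, strong_report):
        rep = strong_report
        accepted = [it for it in rep.boot.iterations if it.accepted]
        assert rep.boot.n_accepted == len(accepted)
        for it in accepted:
            assert 0.0 <= it.apparent_auc <= 1.0
            assert 0.0 <= it.oob_auc <= 1.0
            assert 1 <= it.n_components <= 3
        assert rep.boot.ci95[0] <= rep.boot.oob_median <= rep.boot.ci95[1]
        assert len(rep.perm_aucs) <= 200

    def test_deterministic(self):
        sim = _sim(22)
        a = boot632_validate(sim.study, list(sim.truth_panel), "C", "H",
                             B=50, P=50, seed=4, n_ridge_lambdas=10)
        b = boot632_validate(sim.study, list(sim.truth_panel), "C", "H",
                             B=50, P=50, seed=4, n_ridge_lambdas=10)
        assert a.empirical_p == b.empirical_p
        np.testing.assert_array_equal(a.perm_aucs, b.perm_aucs)

    def test_permutation_null_median_near_half(self):
        for seed in (0, 1):
            sim = _sim(30 + seed, effect=4.0)
            rep = boot632_validate(sim.study, list(sim.truth_panel), "C", "H",
                                   B=50, P=50, seed=seed, n_ridge_lambdas=10)
            assert 0.4 <= np.median(rep.perm_aucs) <= 0.6

    def test_missing_panel_genes_logged_and_intersected(self, caplog):
        sim = _sim(23)
        with caplog.at_level("WARNING"):
            rep = boot632_validate(
                sim.study, list(sim.truth_panel) + ["NOT_A_GENE"], "C", "H",
                B=50, P=50, seed=1, n_ridge_lambdas=10)
        assert "NOT_A_GENE" in caplog.text
        assert rep.config["panel"] == list(sim.truth_panel)

    def test_all_absent_panel_errors(self):
        sim = _sim(24)
        with pytest.raises(ValueError):
            boot632_validate(sim.study, ["nope"], "C", "H", B=50, P=50)

    def test_too_small_cohort_errors(self):
        sim = _sim(25, groups={"H": 3, "C": 11})
        with pytest.raises(ValueError, match="3-fold"):
            boot632_validate(sim.study, list(sim.truth_panel), "C", "H",
                             B=50, P=50)

    def test_null_empirical_p_calibrated(self):
        ps, ds = [], []
        for seed in range(10):
            sim = _sim(60 + seed, effect=0.0, n_de=0,
                       groups={"H": 8, "C": 11})
            rep = boot632_validate(sim.study,
                                   list(sim.study.feature_ids)[:4], "C", "H",
                                   B=50, P=50, seed=seed, n_ridge_lambdas=10)
            ps.append(rep.empirical_p)
            ds.append(rep.cohens_d)
        assert 0.2 <= np.mean(ps) <= 0.8
        assert abs(np.mean(ds)) < 1.5
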