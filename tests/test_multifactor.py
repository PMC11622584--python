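"""Pseudoinverse regression: OLS equivalence, LOOCV, factor-matrix assembly."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api

from semenmeth import (
    ConfigurationError,
    FactorMatrix,
    MethylationDataError,
    MultifactorModel,
    SimulationConfig,
    build_factor_matrix,
    simulate_cohort,
)

from conftest import make_matrix


def random_design(rng, n=50, p=5, sites=500):
    X = pd.DataFrame(
        np.column_stack([np.ones(n), rng.uniform(0, 1, (n, p - 1))]),
        columns=["constant"] + [f"f{j}" for j in range(p - 1)],
        index=[f"S{i:03d}" for i in range(n)],
    )
    M = make_matrix(rng.uniform(0, 1, (n, sites)), samples=list(X.index))
    return X, M


class TestFit:
    def test_orthonormal_design_gives_transpose(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        X = pd.DataFrame(Q, columns=list("abcd"))
        M = make_matrix(rng.uniform(0, 1, (20, 30)), samples=list(X.index))
        model = MultifactorModel().fit(X, M)
        assert np.allclose(model.beta_.to_numpy(), Q.T @ M.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_site_ols(self, seed):
        rng = np.random.default_rng(seed)
        X, M = random_design(rng)
        model = MultifactorModel().fit(X, M)
        Xv = X.to_numpy()
        # independent oracle: normal equations per site
        beta_ols = np.linalg.solve(Xv.T @ Xv, Xv.T @ M.to_numpy())
        assert np.abs(model.beta_.to_numpy() - beta_ols).max() < 1e-8

    def test_noiseless_factor_recovery_is_exact(self, rng):
        n, p, sites = 30, 4, 100
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.uniform(0, 1, (n, p - 1))]),
            columns=["constant", "a", "b", "c"],
        )
        beta_true = rng.normal(size=(p, sites))  # full row rank a.s.
        M = make_matrix(X.to_numpy() @ beta_true, samples=list(X.index))
        model = MultifactorModel().fit(X, M)
        # beta . beta+ = I when beta has full row rank, so X_pred = X
        assert np.abs(model.X_pred_.to_numpy() - X.to_numpy()).max() < 1e-8

    def test_m_pred_equals_x_beta(self, rng):
        X, M = random_design(rng, n=20, sites=50)
        model = MultifactorModel().fit(X, M)
        assert np.allclose(
            model.M_pred_.to_numpy(), X.to_numpy() @ model.beta_.to_numpy()
        )

    def test_missing_values_rejected(self, rng):
        X, M = random_design(rng, n=10, sites=5)
        M.iloc[0, 0] = np.nan
        with pytest.raises(MethylationDataError, match="missing"):
            MultifactorModel().fit(X, M)

    def test_more_factors_than_samples_rejected(self, rng):
        X, M = random_design(rng, n=5, p=5, sites=10)
        with pytest.raises(ConfigurationError):
            MultifactorModel().fit(X, M)

    def test_least_squares_optimality_against_random_alternatives(self, rng):
        X, M = random_design(rng, n=25, p=4, sites=40)
        model = MultifactorModel().fit(X, M)
        resid = np.linalg.norm(M.to_numpy() - model.M_pred_.to_numpy())
        beta = model.beta_.to_numpy()
        for _ in range(100):
            alt = beta + rng.normal(0, 0.1, beta.shape)
            alt_resid = np.linalg.norm(M.to_numpy() - X.to_numpy() @ alt)
            assert resid <= alt_resid + 1e-9

    def test_minimum_norm_under_rank_deficiency(self, rng):
        n, sites = 20, 30
        base = np.column_stack([np.ones(n), rng.uniform(0, 1, (n, 2))])
        X = pd.DataFrame(
            np.column_stack([base, base[:, 2]]),  # duplicated column
            columns=["constant", "a", "b", "b_dup"],
        )
        M = make_matrix(rng.uniform(0, 1, (n, sites)), samples=list(X.index))
        model = MultifactorModel().fit(X, M)
        beta = model.beta_.to_numpy()
        # null space of X: (0, 0, 1, -1); adding any component must not
        # shrink the Frobenius norm below the pinv solution
        null = np.array([0.0, 0.0, 1.0, -1.0])[:, None]
        for scale in rng.normal(0, 1, 20):
            alt = beta + scale * null @ rng.normal(0, 1, (1, sites))
            assert np.linalg.norm(beta) <= np.linalg.norm(alt) + 1e-9


class TestBuildFactorMatrix:
    @staticmethod
    def pheno(n, rng):
        return pd.DataFrame(
            {
                "age": rng.uniform(27, 61.5, n),
                "batch": rng.integers(0, 2, n),
            },
            index=[f"S{i:02d}" for i in range(n)],
        )

    def test_scaling_and_layout(self, rng):
        ph = self.pheno(20, rng)
        X, report = build_factor_matrix(ph, None, ["age"])
        assert X.factor_names == ["constant", "batch", "age"]
        assert (X.values["constant"] == 1).all()
        assert set(np.unique(X.values["batch"])) == {0.0, 1.0}
        assert X.values["age"].min() == 0.0 and X.values["age"].max() == 1.0
        lo, hi = X.scaling["age"]
        assert np.allclose(X.unscale("age", X.values["age"]), ph["age"])
        assert report == []

    def test_duplicated_factor_pruned(self, rng):
        ph = self.pheno(20, rng)
        ph["age_copy"] = ph["age"]
        X, report = build_factor_matrix(
            ph, None, ["age", "age_copy"], prune_threshold=0.95, pinned=["age"]
        )
        assert "age_copy" not in X.factor_names
        assert [r["dropped"] for r in report] == ["age_copy"]
        assert report[0]["max_abs_r"] == pytest.approx(1.0)

    def test_correlated_nuisance_compositions_pruned_keeping_pinned(self, rng):
        n = 40
        ph = self.pheno(n, rng)
        sperm = rng.uniform(0.3, 0.9, n)
        comp = pd.DataFrame(
            {
                "sperm": sperm,
                "prostate_epithelium": rng.uniform(0.0, 0.3, n),
                "T_lymphocyte": 0.6 * (1 - sperm) + rng.normal(0, 0.005, n),
                "granulocyte": 0.4 * (1 - sperm) + rng.normal(0, 0.005, n),
            },
            index=ph.index,
        )
        X, report = build_factor_matrix(
            ph,
            comp,
            ["age", "sperm", "prostate_epithelium", "T_lymphocyte", "granulocyte"],
            prune_threshold=0.7,
            pinned=["age", "sperm"],
        )
        assert X.factor_names == [
            "constant",
            "batch",
            "age",
            "sperm",
            "prostate_epithelium",
        ]
        assert {r["dropped"] for r in report} == {"T_lymphocyte", "granulocyte"}

    def test_complete_simplex_drops_last_composition(self, rng):
        n = 30
        ph = self.pheno(n, rng)
        W = rng.dirichlet((5, 2, 1), n)
        comp = pd.DataFrame(W, columns=["sperm", "prostate", "gran"], index=ph.index)
        X, report = build_factor_matrix(
            ph, comp, ["age", "sperm", "prostate", "gran"], pinned=["age", "sperm"]
        )
        assert "gran" not in X.factor_names
        assert report[0]["reason"] == "compositions complete the simplex"

    def test_constant_factor_rejected(self, rng):
        ph = self.pheno(10, rng)
        ph["flat"] = 3.0
        with pytest.raises(ConfigurationError, match="constant"):
            build_factor_matrix(ph, None, ["age", "flat"])

    def test_sample_mismatch_rejected(self, rng):
        ph = self.pheno(10, rng)
        comp = pd.DataFrame({"sperm": np.linspace(0, 1, 9)},
                            index=[f"S{i:02d}" for i in range(9)])
        with pytest.raises(MethylationDataError, match="different samples"):
            build_factor_matrix(ph, comp, ["age", "sperm"])


class TestLoocv:
    def test_noiseless_planted_effects_predicted_almost_perfectly(self):
        cfg = SimulationConfig(
            n_samples=40,
            n_sites=600,
            seed=5,
            noise_model="none",
            n_age_sites=300,
            age_slope=0.15,
            n_batch_sites=0,
            delta=0.2,
        )
        cohort = simulate_cohort(cfg)
        X, _ = build_factor_matrix(
            cohort.truth.phenotypes,
            cohort.truth.compositions,
            ["age", "sperm", "prostate_epithelium"],
            pinned=["age", "sperm"],
        )
        report = MultifactorModel().loocv(X, cohort.matrix.values)
        assert (report.stats["r"] >= 0.99).all()

    def test_planted_age_signal_recovered(self):
        cfg = SimulationConfig(
            n_samples=80,
            seed=7,
            noise_model="gaussian",
            gaussian_sd=0.03,
            n_age_sites=200,
            age_slope=0.1,
            age_frac_negative=1.0,
        )
        cohort = simulate_cohort(cfg)
        X, _ = build_factor_matrix(
            cohort.truth.phenotypes,
            cohort.truth.compositions,
            ["age", "sperm", "prostate_epithelium"],
            pinned=["age", "sperm"],
        )
        report = MultifactorModel().loocv(X, cohort.matrix.values)
        assert report.stats.loc["age", "r"] >= 0.4
        assert report.stats.loc["age", "p"] < 0.05
        # MAE is reported in years, not scaled units
        assert 0 < report.stats.loc["age", "mae"] < 10

    def test_prediction_invariant_to_permuting_other_samples(self, rng):
        X, M = random_design(rng, n=15, p=3, sites=40)
        model = MultifactorModel()
        rep = model.loocv(X, M)
        perm = rng.permutation(15)
        rep_perm = model.loocv(X.iloc[perm], M.iloc[perm])
        pd.testing.assert_frame_equal(
            rep.predictions.sort_index(), rep_perm.predictions.sort_index()
        )

    def test_nuisance_factors_not_reported(self, rng):
        X, M = random_design(rng, n=15, p=3, sites=30)
        X.columns = ["constant", "batch", "age"]
        rep = MultifactorModel().loocv(X, M)
        assert list(rep.stats.index) == ["age"]

    def test_too_few_samples_rejected(self, rng):
        X, M = random_design(rng, n=6, p=4, sites=10)
        with pytest.raises(ConfigurationError, match="LOOCV"):
            MultifactorModel().loocv(X, M)


class TestFullFit:
    def test_noiseless_r_is_one(self, rng):
        n, p, sites = 30, 4, 200
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.uniform(0, 1, (n, p - 1))]),
            columns=["constant", "age", "sperm", "prostate"],
        )
        beta_true = rng.normal(0, 0.05, size=(p, sites))
        M = make_matrix(0.5 + X.to_numpy() @ beta_true, samples=list(X.index))
        model = MultifactorModel().fit(X, M)
        stats = model.evaluate_fullfit(X)
        assert np.allclose(stats["r"], 1.0, atol=1e-6)

    def test_full_fit_is_at_least_as_optimistic_as_loocv(self):
        gaps = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_samples=40,
                n_sites=400,
                seed=seed,
                noise_model="gaussian",
                gaussian_sd=0.05,
                n_age_sites=100,
                age_slope=0.08,
                n_batch_sites=0,
                delta=0.2,
            )
            cohort = simulate_cohort(cfg)
            X, _ = build_factor_matrix(
                cohort.truth.phenotypes,
                cohort.truth.compositions,
                ["age", "sperm"],
                pinned=["age", "sperm"],
            )
            model = MultifactorModel().fit(X, cohort.matrix.values)
            full_r = model.evaluate_fullfit(X).loc["age", "r"]
            loo_r = model.loocv(X, cohort.matrix.values).stats.loc["age", "r"]
            gaps.append(full_r - loo_r)
        assert np.median(gaps) >= 0

    def test_sperm_composition_recovery_at_low_noise(self):
        cfg = SimulationConfig(
            n_samples=40, seed=13, noise_model="gaussian", gaussian_sd=0.02
        )
        cohort = simulate_cohort(cfg)
        X, _ = build_factor_matrix(
            cohort.truth.phenotypes,
            cohort.truth.compositions,
            ["age", "sperm", "prostate_epithelium"],
            pinned=["age", "sperm"],
        )
        model = MultifactorModel().fit(X, cohort.matrix.values)
        assert model.evaluate_fullfit(X).loc["sperm", "r"] >= 0.95


def test_per_site_pvalues_match_statsmodels(rng):
    """Vectorised per-site t-tests agree with statsmodels OLS site by site."""
    from semenmeth.selection import score_sites

    X, M = random_design(rng, n=30, p=4, sites=20)
    model = MultifactorModel().fit(X, M)
    scores = score_sites(M, X, model)
    for site in M.columns[:5]:
        res = sm_api.OLS(M[site].to_numpy(), X.to_numpy()).fit()
        for j, f in enumerate(X.columns):
            if f == "constant":
                continue
            assert scores.loc[site, f"coef_{f}"] == pytest.approx(res.params[j])
            assert scores.loc[site, f"p_{f}"] == pytest.approx(
                res.pvalues[j], rel=1e-6
            )
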