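import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixoniche import (
    AbundanceTable,
    anova_rates,
    fit_ti_smoother,
    hellinger,
    pca_env,
    rda_species,
    regress_ti,
    regress_ti_battery,
    stepwise_ti,
)
from mixoniche.niche_stats import escoufier_select, rv_coefficient
from mixoniche.tables import EnvTable


def abundance(matrix, mode="cell"):
    arr = np.asarray(matrix, dtype=float)
    return AbundanceTable(
        pd.DataFrame(
            arr,
            index=pd.Index([f"S{i}" for i in range(arr.shape[0])], name="sample_id"),
            columns=[f"sp{j}" for j in range(arr.shape[1])],
        ),
        mode=mode,
    )


def env_from(frame: pd.DataFrame) -> EnvTable:
    df = frame.copy()
    df.insert(0, "layer", "SUR")
    df.insert(0, "station_id", [f"ST{i}" for i in range(len(df))])
    df.index = pd.Index([f"S{i}" for i in range(len(df))], name="sample_id")
    return EnvTable(df)


class TestHellinger:
    def test_uniform_row(self):
        out = hellinger(abundance([[1, 1, 1, 1]]))
        np.testing.assert_allclose(out.values, [[0.5, 0.5, 0.5, 0.5]])
        assert out.mode == "hellinger"

    def test_closed_form_row(self):
        out = hellinger(abundance([[4, 0]]))
        np.testing.assert_allclose(out.values, [[1.0, 0.0]])

    def test_unit_l2_norm(self):
        rng = np.random.default_rng(3)
        out = hellinger(abundance(rng.uniform(0.1, 9.0, (6, 8))))
        np.testing.assert_allclose(np.linalg.norm(out.values, axis=1), 1.0, rtol=1e-12)

    def test_zero_row_warned_and_zeroed(self):
        with pytest.warns(UserWarning, match="zero-sum"):
            out = hellinger(abundance([[1, 1], [0, 0]]))
        np.testing.assert_array_equal(out.values[1], [0.0, 0.0])


class TestPcaEnv:
    def test_perfectly_correlated_pair_rank_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        env = env_from(pd.DataFrame({"a": x, "b": 2 * x}))
        res = pca_env(env)
        assert res.r2_per_axis[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (5, 4))
        env = env_from(pd.DataFrame(X, columns=list("abcd")))
        res = pca_env(env, standardize=False)
        C = np.cov(X, rowvar=False)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        np.testing.assert_allclose(
            np.abs(res.loadings.to_numpy()), np.abs(V), atol=1e-8
        )
        np.testing.assert_allclose(res.r2_per_axis, w / w.sum(), atol=1e-8)
        # scores equal projections up to the fixed sign convention
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()), np.abs(Xc @ V), atol=1e-8
        )

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(11)
        env = env_from(pd.DataFrame(rng.normal(0, 1, (10, 5)), columns=list("abcde")))
        res = pca_env(env)
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_reconstruction_all_components(self):
        rng = np.random.default_rng(13)
        X = rng.normal(5, 2, (8, 4))
        env = env_from(pd.DataFrame(X, columns=list("abcd")))
        res = pca_env(env, standardize=False)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.means.to_numpy()
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_constant_variable_under_zscore_named(self):
        env = env_from(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}))
        with pytest.raises(ValueError, match="b"):
            pca_env(env, standardize=True)

    def test_missing_values_rejected(self):
        env = env_from(pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="missing"):
            pca_env(env)


class TestSmoother:
    def test_linear_limit(self):
        x = np.linspace(-3, 3, 60)
        fit = fit_ti_smoother(x, 0.1 * x)
        np.testing.assert_allclose(fit.fitted, 0.1 * fit.grid, atol=1e-6)
        assert fit.shape == "increasing"

    def test_constant_is_flat(self):
        x = np.linspace(0, 10, 40)
        fit = fit_ti_smoother(x, np.full_like(x, 0.4))
        assert fit.shape == "flat"

    def test_unimodal_peak_recovered(self):
        rng = np.random.default_rng(21)
        x = np.linspace(-1.5, 3.5, 150)
        y = -((x - 1.0) ** 2) + rng.normal(0, 0.05, x.size)
        fit = fit_ti_smoother(x, y)
        assert fit.shape == "unimodal"
        assert fit.peak == pytest.approx(1.0, abs=0.2)

    def test_band_contains_curve(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 50)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 50)
        fit = fit_ti_smoother(x, y)
        assert (fit.band_lower <= fit.fitted).all()
        assert (fit.fitted <= fit.band_upper).all()

    def test_small_n_shrinks_basis(self):
        x = np.linspace(0, 1, 10)
        with pytest.warns(UserWarning, match="shrunk"):
            fit = fit_ti_smoother(x, x**2)
        assert fit.edf <= 9


class TestRegressTi:
    def test_perfect_fit(self):
        x = np.linspace(1, 10, 20)
        res = regress_ti(2 * x, x)
        assert res.slope("x") == pytest.approx(2.0)
        assert res.p_value("x") < 1e-30
        assert res.r_squared == pytest.approx(1.0)

    def test_null_coverage_calibrated(self):
        rng = np.random.default_rng(99)
        n, sims, covered = 50, 1000, 0
        tcrit = stats.t.ppf(0.975, n - 2)
        for _ in range(sims):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            fit = stats.linregress(x, y)
            covered += abs(fit.slope) <= tcrit * fit.stderr
        assert 0.93 <= covered / sims <= 0.97

    def test_log_transform_flag(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0, 10.0, 100.0])
        y = np.log10(x) * 3.0
        res = regress_ti(y, x, log_transform=True)
        assert res.slope("x") == pytest.approx(3.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            regress_ti(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))

    def test_battery_emits_bh_qvalues(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.normal(0, 1, (40, 5)), columns=list("abcde"))
        y = pd.Series(2 * env["a"] + rng.normal(0, 0.5, 40), name="TI_M")
        out = regress_ti_battery(y, env)
        assert {"slope", "p", "r2", "q"} <= set(out.columns)
        assert (out["q"] >= out["p"] - 1e-15).all()
        assert out.loc["a", "q"] < 0.05


class TestStepwise:
    def test_perfect_predictor_selected_alone(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, (60, 10)), columns=[f"x{i}" for i in range(10)])
        res = stepwise_ti(X["x3"].to_numpy() * 1.0, X)
        assert res.predictors == ["x3"]
        assert res.trace[0][0] == "start"

    def test_null_false_selection_bounded(self):
        # under the null a consistent criterion (BIC) admits almost nothing;
        # AIC is liberal by construction (entry prob ~0.16 per variable) so
        # only a loose sanity bound applies there
        sizes_bic, sizes_aic = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(0, 1, (50, 29)), columns=[f"x{i}" for i in range(29)]
            )
            y = rng.normal(0, 1, 50)
            sizes_bic.append(len(stepwise_ti(y, X, criterion="bic").predictors))
            sizes_aic.append(len(stepwise_ti(y, X).predictors))
        assert np.median(sizes_bic) <= 2
        assert np.median(sizes_aic) <= 10

    def test_power_both_true_predictors(self):
        hits = 0
        runs = 25
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(
                rng.normal(0, 1, (104, 29)), columns=[f"x{i}" for i in range(29)]
            )
            y = 0.5 * X["x0"] - 1.0 * X["x1"] + rng.normal(0, 0.5, 104)
            sel = stepwise_ti(y.to_numpy(), X).predictors
            hits += {"x0", "x1"} <= set(sel)
        assert hits >= runs - 1

    def test_forward_only_when_overparameterized(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(0, 1, (10, 15)), columns=[f"x{i}" for i in range(15)])
        y = X["x0"].to_numpy() + rng.normal(0, 0.1, 10)
        with pytest.warns(UserWarning, match="forward-only"):
            res = stepwise_ti(y, X)
        assert "x0" in res.predictors


class TestRda:
    def test_span_inclusion_gives_fraction_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (10, 2))
        B = np.abs(rng.normal(1, 0.2, (2, 4)))
        Y = X @ B
        Y = Y - Y.min() + 0.5
        sp = AbundanceTable(
            pd.DataFrame(
                Y, index=pd.Index([f"S{i}" for i in range(10)], name="sample_id"),
                columns=[f"sp{j}" for j in range(4)],
            ),
            mode="hellinger",  # treat as already transformed: span is what matters
        )
        env = env_from(pd.DataFrame(X, columns=["e1", "e2"]))
        res = rda_species(sp, env, escoufier_threshold=1.0, n_perm=49,
                          alpha=1.0, vif_max=1e9, seed=0)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-10)

    def test_biplot_matches_regression_svd_oracle(self):
        rng = np.random.default_rng(12)
        Y = rng.uniform(0.5, 2.0, (6, 4))
        X = rng.normal(0, 1, (6, 2))
        sp = AbundanceTable(
            pd.DataFrame(
                Y, index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
                columns=[f"sp{j}" for j in range(4)],
            ),
            mode="hellinger",
        )
        env = env_from(pd.DataFrame(X, columns=["e1", "e2"]))
        res = rda_species(sp, env, escoufier_threshold=1.0, n_perm=49,
                          alpha=1.0, vif_max=1e9, seed=0)
        # independent oracle: center, regress, SVD
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        Yhat = Xc @ np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        frac = float(np.sum(s**2) / np.sum(Yc**2))
        assert res.constrained_fraction == pytest.approx(frac, abs=1e-8)
        np.testing.assert_allclose(
            np.abs(res.sample_scores.to_numpy()), np.abs(U[:, :2] * s[:2]), atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(res.species_scores.to_numpy()), np.abs(Vt[:2].T), atol=1e-8
        )

    def test_noise_env_variable_rarely_significant(self):
        keep = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            Y = rng.uniform(0.2, 1.0, (20, 5))
            sp = AbundanceTable(
                pd.DataFrame(
                    Y, index=pd.Index([f"S{i}" for i in range(20)], name="sample_id"),
                    columns=[f"sp{j}" for j in range(5)],
                ),
                mode="hellinger",
            )
            env = env_from(pd.DataFrame({"noise": rng.normal(0, 1, 20)}))
            res = rda_species(sp, env, escoufier_threshold=1.0, n_perm=199,
                              vif_max=1e9, seed=seed)
            keep += res.permutation_p["noise"] > 0.05
        assert keep >= int(0.9 * n_seeds)

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(17)
        Y = rng.uniform(0.2, 1.0, (15, 4))
        sp = AbundanceTable(
            pd.DataFrame(
                Y, index=pd.Index([f"S{i}" for i in range(15)], name="sample_id"),
                columns=[f"sp{j}" for j in range(4)],
            ),
            mode="hellinger",
        )
        env = env_from(pd.DataFrame({"a": rng.normal(0, 1, 15)}))
        p1 = rda_species(sp, env, n_perm=99, seed=5, vif_max=1e9).permutation_p
        p2 = rda_species(sp, env, n_perm=99, seed=5, vif_max=1e9).permutation_p
        pd.testing.assert_series_equal(p1, p2)

    def test_constrained_fraction_invariant_to_env_rescaling(self):
        rng = np.random.default_rng(23)
        Y = rng.uniform(0.2, 1.0, (12, 4))
        sp = AbundanceTable(
            pd.DataFrame(
                Y, index=pd.Index([f"S{i}" for i in range(12)], name="sample_id"),
                columns=[f"sp{j}" for j in range(4)],
            ),
            mode="hellinger",
        )
        X = pd.DataFrame({"a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 12)})
        r1 = rda_species(sp, env_from(X), escoufier_threshold=1.0, n_perm=29,
                         alpha=1.0, vif_max=1e9, seed=0)
        r2 = rda_species(sp, env_from(100 * X + 7), escoufier_threshold=1.0,
                         n_perm=29, alpha=1.0, vif_max=1e9, seed=0)
        assert r1.constrained_fraction == pytest.approx(r2.constrained_fraction, abs=1e-10)


class TestEscoufier:
    def test_rv_self_is_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (9, 4))
        assert rv_coefficient(X, X) == pytest.approx(1.0)

    def test_duplicate_column_not_needed(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, (20, 3))
        values = np.column_stack([base, base[:, 0]])  # col 3 duplicates col 0
        selected = escoufier_select(values, ["a", "b", "c", "a_dup"], threshold=0.95)
        assert len(selected) <= 3


class TestAnova:
    def test_equal_means_null(self):
        values = np.array([1.0, 1.0, 1.0, 1.0])
        factors = pd.DataFrame({"light": ["H", "H", "L", "L"]})
        res = anova_rates(values, factors)[("light",)]
        assert res.F == 0.0
        assert res.p == 1.0

    def test_matches_sums_of_squares_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0])
        groups = np.repeat(["a", "b", "c"], 3)
        res = anova_rates(values, pd.DataFrame({"g": groups}))[("g",)]
        # brute-force sums of squares
        grand = values.mean()
        ssb = sum(3 * (values[groups == g].mean() - grand) ** 2 for g in "abc")
        ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in "abc")
        F = (ssb / 2) / (ssw / 6)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.dfn, res.dfd) == (2, 6)
        f, p = stats.f_oneway(*[values[groups == g] for g in "abc"])
        assert res.F == pytest.approx(f, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_two_level_factor_dfn_one(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 22)
        factors = pd.DataFrame({"light": np.repeat(["H", "L"], 11)})
        res = anova_rates(values, factors)[("light",)]
        assert res.dfn == 1
        assert res.dfd == 20

    def test_multifactor_main_effects_df_bookkeeping(self):
        rng = np.random.default_rng(1)
        n = 24
        factors = pd.DataFrame(
            {
                "light": np.tile(np.repeat(["H", "L"], 6), 2),
                "nutrient": np.tile(["K", "K-N"], 12),
                "species": np.repeat([f"s{i}" for i in range(6)], 4),
            }
        )
        values = rng.normal(0, 1, n) + (factors["light"] == "H") * 0.5
        out = anova_rates(values, factors)
        multi = out[("light", "nutrient", "species")]
        assert multi.dfn == 1 + 1 + 5
        assert multi.dfd == n - 1 - multi.dfn

    def test_saturated_model_rejected(self):
        values = np.array([1.0, 2.0])
        factors = pd.DataFrame({"g": ["a", "b"]})
        with pytest.raises(ValueError):
            anova_rates(values, factors)
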