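"""Multi-environment REML: design construction, objective correctness,
optimizer agreement with a brute-force oracle, BLUP/BLUE behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sparsegp._reml import REMLEngine, REMLOptions, _ResidGroup, _Term
from sparsegp.genotypes import KinshipMatrix
from sparsegp.me_mixed_model import (
    ModelSpec,
    _make_engine,
    ar1_correlation,
    build_design,
    compute_blues,
    fa_covariance,
    genetic_correlations,
    plot_heritability,
    predict_gblup,
    reml_fit,
    VarianceComponents,
)
from sparsegp.reference import (
    dense_reml_loglik,
    gls_blue,
    make_tiny_multi_env,
    maximize_dense_reml_2env,
)

from .conftest import make_plot_table


def quiet_design(df, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_design(df, spec)


class TestAR1:
    def test_zero_rho_is_identity(self):
        np.testing.assert_allclose(ar1_correlation(3, 0.0), np.eye(3))

    def test_definition(self):
        np.testing.assert_allclose(ar1_correlation(2, 0.5), [[1, 0.5], [0.5, 1]])

    def test_inverse_is_tridiagonal(self):
        inv = np.linalg.inv(ar1_correlation(4, 0.9))
        off = inv.copy()
        for d in (-1, 0, 1):
            off -= np.diag(np.diag(inv, d), d)
        assert np.max(np.abs(off)) < 1e-8
        assert np.linalg.eigvalsh(ar1_correlation(4, 0.9))[0] > 0

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            ar1_correlation(3, 1.0)


class TestFaCovariance:
    def test_hand_example(self):
        Go = fa_covariance(np.array([[1.0], [0.5]]), np.array([0.0, 0.75]))
        np.testing.assert_allclose(Go, [[1.0, 0.5], [0.5, 1.0]])

    def test_zero_loadings_give_independent_envs(self):
        Go = fa_covariance(np.zeros((3, 1)), np.array([0.2, 0.4, 0.6]))
        np.testing.assert_allclose(Go, np.diag([0.2, 0.4, 0.6]))

    def test_always_psd_and_negative_psi_rejected(self):
        rng = np.random.default_rng(1)
        Go = fa_covariance(rng.standard_normal((5, 2)), rng.random(5))
        assert np.linalg.eigvalsh(Go)[0] >= -1e-10
        with pytest.raises(ValueError):
            fa_covariance(np.ones((2, 1)), np.array([-0.1, 0.2]))


class TestGeneticCorrelations:
    def test_diagonal_Go_gives_identity(self):
        np.testing.assert_allclose(genetic_correlations(np.diag([1.0, 2.0])), np.eye(2))

    def test_known_value_and_scale_invariance(self):
        Go = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert genetic_correlations(Go)[0, 1] == pytest.approx(0.5)
        D = np.diag([2.0, 0.3])
        R1 = genetic_correlations(Go)
        R2 = genetic_correlations(D @ Go @ D)
        assert np.max(np.abs(R1 - R2)) < 1e-10

    def test_zero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            genetic_correlations(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestPlotHeritability:
    def _vc(self, g, e):
        return VarianceComponents(
            sigma2={}, resid={"SE1": e}, Go=np.array([[g]]), env_order=["SE1"],
        )

    def test_equal_variances_give_half(self):
        assert plot_heritability(self._vc(0.7, 0.7), "SE1") == pytest.approx(0.5)

    def test_zero_genetic_variance_gives_zero(self):
        assert plot_heritability(self._vc(0.0, 1.0), "SE1") == 0.0

    def test_zero_total_variance_warns(self):
        with pytest.warns(UserWarning):
            assert plot_heritability(self._vc(0.0, 0.0), "SE1") == 0.0

    def test_unknown_env_rejected(self):
        with pytest.raises(KeyError):
            plot_heritability(self._vc(1.0, 1.0), "nope")


class TestBuildDesign:
    def test_gxe_cell_and_row_counts(self):
        df = make_plot_table(n_lines=2, envs=("SE1", "SE2"), n_reps=2, n_blocks=1)
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        assert len(design.gxe_cells()) == 4
        assert design.n_plots == 8
        assert design.term_kind["gxe"] == "fa"

    def test_eq3_rejects_multi_env_data(self):
        df = make_plot_table(envs=("SE1", "SE2"))
        with pytest.raises(ValueError, match="single environment"):
            build_design(df, ModelSpec("eq3_single_env"))

    def test_missing_column_error_names_term_and_column(self):
        df = make_plot_table().drop(columns=["block"])
        with pytest.raises(ValueError, match="block"):
            build_design(df, ModelSpec("eq1_multi_env"))
        df2 = make_plot_table().drop(columns=["year"])
        with pytest.raises(ValueError, match="year"):
            build_design(df2, ModelSpec("eq2_multi_env_multi_year"))

    def test_level_ordering_lexicographic_and_stable(self):
        df = make_plot_table(n_lines=4, envs=("SE2", "SE1"))
        d1 = quiet_design(df, ModelSpec("eq1_multi_env"))
        d2 = quiet_design(df.sample(frac=1.0, random_state=3), ModelSpec("eq1_multi_env"))
        assert d1.envs == ["SE1", "SE2"] == d2.envs
        assert d1.term_levels["rep_nested"] == d2.term_levels["rep_nested"]

    def test_eq2_nesting_keys_include_year(self):
        df = make_plot_table(envs=("SE1", "SE2"))
        df2 = df.copy()
        df2["env"] = df2["env"] + "*"
        df2["year"] = 2
        both = pd.concat([df, df2], ignore_index=True)
        design = quiet_design(both, ModelSpec("eq2_multi_env_multi_year"))
        assert all(len(k) == 4 for k in design.term_levels["rep_nested"])  # env,trial,rep,year
        assert all(len(k) == 5 for k in design.term_levels["block"])


class TestObjectiveCorrectness:
    def test_mme_loglik_equals_dense_error_contrast_likelihood(self):
        # identical objective values at arbitrary covariance parameters
        for seed in (0, 1):
            df, kin = make_tiny_multi_env(seed)
            design = quiet_design(df, ModelSpec("eq1_multi_env"))
            eng, _ = _make_engine(design, kin, REMLOptions(estimate=False))
            sigma2 = {"env": 0.8, "rep_nested": 0.35, "block": 0.15}
            Go = np.array([[0.9, 0.4], [0.4, 1.2]])
            resid = np.array([0.6, 1.1])
            eng.init_params({
                "Lambda": [[0.8], [0.4445]], "Psi": [0.26, 1.0024], "resid": resid,
                "sigma2": sigma2,
            })
            lam = np.array([[0.8], [0.4445]])
            Go_eng = lam @ lam.T + np.diag([0.26, 1.0024])
            ll_dense = dense_reml_loglik(design, kin, sigma2, Go_eng, resid)
            assert eng.loglik() == pytest.approx(ll_dense, abs=1e-8)

    def test_em_iterations_monotone_in_loglik(self):
        df, kin = make_tiny_multi_env(4)
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        opts = REMLOptions(use_ai=False, polish=False, max_iter=15, track=True)
        eng, _ = _make_engine(design, kin, opts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eng.fit()
        tr = np.array(eng.trace)
        assert np.all(np.diff(tr) > -1e-8)

    def test_converged_fit_satisfies_mme(self):
        df, kin = make_tiny_multi_env(2)
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        fit = reml_fit(design, kin)
        assert fit.mme_residual_norm < 1e-6

    def test_package_matches_brute_force_oracle(self):
        df, kin = make_tiny_multi_env(1)
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        fit = reml_fit(design, kin)
        ll_o, pars = maximize_dense_reml_2env(design, kin)
        assert fit.varcomp.loglik == pytest.approx(ll_o, abs=1e-4)
        assert np.max(np.abs(fit.varcomp.Go - pars["Go"])) < 1e-3

    def test_fa_order_two_never_below_order_one(self):
        rng = np.random.default_rng(8)
        df = make_plot_table(n_lines=10, envs=("SE1", "SE2", "SE3"), seed=8)
        lines = sorted(df["line"].unique())
        K = np.eye(10)
        kin = KinshipMatrix(lines, K, "genomic")
        U = rng.standard_normal((10, 3)) @ np.linalg.cholesky(
            np.array([[1, .5, .2], [.5, 1, .6], [.2, .6, 1]])
        ).T
        li = {l: i for i, l in enumerate(lines)}
        em = {"SE1": 0, "SE2": 1, "SE3": 2}
        df["value"] = [
            U[li[l], em[e]] for l, e in zip(df["line"], df["env"])
        ] + 0.5 * rng.standard_normal(len(df))
        lls = {}
        for m in (1, 2):
            d = quiet_design(df, ModelSpec("eq1_multi_env", fa_order=m))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lls[m] = reml_fit(d, kin).varcomp.loglik
        assert lls[2] >= lls[1] - 1e-6


class TestNullGenetics:
    def test_zero_genetic_variance_hits_boundary(self):
        # 25 lines x 10 reps x 2 SEs: heavy replication concentrates the
        # null REML estimate of the genetic variance near the boundary
        rng = np.random.default_rng(10)
        df = make_plot_table(n_lines=25, envs=("SE1", "SE2"), n_reps=10, seed=10)
        assert len(df) == 500
        df["value"] = 5.0 + 0.4 * (df["rep"] == 2) + rng.standard_normal(len(df))
        lines = sorted(df["line"].unique())
        kin = KinshipMatrix(lines, np.eye(len(lines)), "genomic")
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(design, kin)
        vp = df["value"].var()
        gtot = np.mean(np.diag(fit.varcomp.Go))
        assert gtot < 0.02 * vp
        assert fit.gblups["gblup"].abs().mean() < 0.05 * np.sqrt(vp)


def engine_single_record(K, sg2, se2, y0):
    """One observation on line 1 of a 3-line panel, no fixed effects."""
    term = _Term("genetic", "kinship", np.array([0]), q=3, keys=["a", "b", "c"])
    grp = _ResidGroup("E", np.array([0]), np.zeros(1), np.zeros(1))
    eng = REMLEngine(
        y=np.array([y0]), X=np.zeros((1, 0)), terms=[term], groups=[grp],
        K=K, fa_dims=None, spatial=False, opts=REMLOptions(estimate=False),
    )
    eng.fit(init={"sigma2": {"genetic": sg2}, "resid": np.array([se2])})
    return eng.term_solution("genetic")


class TestPrediction:
    def test_single_record_closed_form_shrinkage(self):
        K = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.25], [0.0, 0.25, 1.0]])
        sg2, se2, y0 = 0.8, 0.5, 1.7
        u = engine_single_record(K, sg2, se2, y0)
        expected = sg2 * K[:, 0] * y0 / (sg2 * K[0, 0] + se2)
        np.testing.assert_allclose(u, expected, atol=1e-10)

    def _fit_with_extra_lines(self, K_extra_block):
        df = make_plot_table(n_lines=6, envs=("SE1", "SE2"), seed=3)
        lines = sorted(df["line"].unique())
        extra = ["U1", "U2"]
        n = len(lines)
        K = np.eye(n + 2)
        K[:n, :n] = np.eye(n) + 0.3 * (np.ones((n, n)) - np.eye(n))
        K[n:, n:] = K_extra_block
        kin = KinshipMatrix(lines + extra, K, "genomic")
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return reml_fit(design, kin), extra

    def test_unrelated_unphenotyped_line_predicts_zero(self):
        fit, extra = self._fit_with_extra_lines(np.eye(2))
        preds = predict_gblup(fit, ["U1"], ["SE1", "SE2"])
        np.testing.assert_allclose(preds["gblup"], 0.0, atol=1e-12)

    def test_twin_of_tested_line_gets_equal_gblup(self):
        df = make_plot_table(n_lines=5, envs=("SE1", "SE2"), seed=6)
        lines = sorted(df["line"].unique())
        all_lines = lines + ["TWIN"]
        base = np.eye(5) + 0.2 * (np.ones((5, 5)) - np.eye(5))
        K = np.zeros((6, 6))
        K[:5, :5] = base
        K[5, :5] = base[0, :]   # TWIN duplicates L0's relationships
        K[:5, 5] = base[:, 0]
        K[5, 5] = base[0, 0]
        kin = KinshipMatrix(all_lines, K, "genomic")
        design = quiet_design(df, ModelSpec("eq1_multi_env"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(design, kin)
        g = fit.gblup_matrix()
        assert np.max(np.abs(g.loc["TWIN"] - g.loc["L0"])) < 1e-6

    def test_unknown_line_rejected(self):
        fit, _ = self._fit_with_extra_lines(np.eye(2))
        with pytest.raises(KeyError, match="unknown"):
            predict_gblup(fit, ["NOPE"], ["SE1"])


class TestShrinkageLimits:
    def _balanced_engine(self, ratio):
        rng = np.random.default_rng(11)
        n_lines, n_reps = 8, 3
        y = np.repeat(rng.standard_normal(n_lines), n_reps) + 0.3 * rng.standard_normal(
            n_lines * n_reps
        )
        term = _Term("genetic", "kinship", np.tile(np.arange(n_lines), n_reps) * 0 +
                     np.repeat(np.arange(n_lines), n_reps), q=n_lines)
        grp = _ResidGroup("E", np.arange(n_lines * n_reps), np.zeros(n_lines * n_reps),
                          np.zeros(n_lines * n_reps))
        eng = REMLEngine(
            y=y, X=np.ones((n_lines * n_reps, 1)), terms=[term], groups=[grp],
            K=np.eye(n_lines), fa_dims=None, spatial=False,
            opts=REMLOptions(estimate=False),
        )
        eng.fit(init={"sigma2": {"genetic": ratio}, "resid": np.array([1.0])})
        means = y.reshape(n_reps, n_lines) if False else np.array(
            [y[np.repeat(np.arange(n_lines), n_reps) == i].mean() for i in range(n_lines)]
        )
        return eng.term_solution("genetic"), means - y.mean()

    def test_infinite_ratio_recovers_centered_means(self):
        u, centered = self._balanced_engine(1e8)
        np.testing.assert_allclose(u, centered, atol=1e-4)

    def test_zero_ratio_shrinks_to_zero(self):
        u, _ = self._balanced_engine(1e-8)
        np.testing.assert_allclose(u, 0.0, atol=1e-6)


class TestBlues:
    def test_balanced_single_block_equals_plot_means(self):
        rng = np.random.default_rng(12)
        df = make_plot_table(n_lines=8, envs=("SE1",), n_reps=2, n_blocks=1, seed=12)
        df["value"] = (
            np.repeat(0.0, len(df))
            + df["line"].str.slice(1).astype(int) * 0.5
            + 0.2 * (df["rep"] == 2)
            + 0.3 * rng.standard_normal(len(df))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bt = compute_blues(df, ModelSpec("eq3_single_env"))
        means = df.groupby("line")["value"].mean()
        got = bt.values.set_index("line")["blue"]
        np.testing.assert_allclose(got[means.index], means, atol=1e-6)

    def test_translation_equivariance_per_environment(self):
        df = make_plot_table(n_lines=6, envs=("SE1", "SE2"), seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = compute_blues(df, ModelSpec("eq1_multi_env"))
            df2 = df.copy()
            df2.loc[df2["env"] == "SE2", "value"] += 3.7
            b2 = compute_blues(df2, ModelSpec("eq1_multi_env"))
        m1, m2 = b1.blue_matrix(), b2.blue_matrix()
        np.testing.assert_allclose(m2["SE1"], m1["SE1"], atol=1e-7)
        np.testing.assert_allclose(m2["SE2"], m1["SE2"] + 3.7, atol=1e-7)

    def test_gls_oracle_agreement(self):
        # 4 lines x 2 reps with one block effect: package BLUE equals the
        # direct GLS solution at the package's variance components
        rng = np.random.default_rng(14)
        df = make_plot_table(n_lines=4, envs=("SE1",), n_reps=2, n_blocks=2, seed=14)
        df["value"] = rng.standard_normal(len(df)) + [0.0, 0.5, 1.0, 1.5][
            df["line"].str.slice(1).astype(int).iloc[0]
        ] if False else rng.standard_normal(len(df))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bt = compute_blues(df, ModelSpec("eq3_single_env"))
        # rebuild X and Z in the same (sorted) plot order used by the model
        d = df.sort_values(["env", "col", "row"], kind="mergesort").reset_index(drop=True)
        lines = sorted(d["line"].unique())
        X = np.zeros((len(d), len(lines) + 1))
        for i, l in enumerate(lines):
            X[(d["line"] == l).to_numpy(), i] = 1.0
        X[(d["rep"] == 2).to_numpy(), -1] = 1.0
        blocks = sorted(set(zip(d["trial"], d["rep"], d["block"])))
        Zb = np.zeros((len(d), len(blocks)))
        for j, b in enumerate(blocks):
            Zb[[t == b for t in zip(d["trial"], d["rep"], d["block"])], j] = 1.0
        s2b = bt.varcomp.sigma2.get("block", 0.0)
        s2e = bt.varcomp.resid["SE1"]
        beta = gls_blue(d["value"].to_numpy(), X, Zb, s2b, s2e)
        expected = beta[: len(lines)] + beta[-1] / 2.0
        got = bt.values.set_index("line")["blue"][lines].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_standard_errors_positive(self):
        df = make_plot_table(n_lines=5, envs=("SE1", "SE2"), seed=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bt = compute_blues(df, ModelSpec("eq1_multi_env"))
        assert (bt.values["se"] > 0).all()


class TestSpatialResiduals:
    def test_spatial_fit_recovers_positive_rho(self):
        # one env, strong AR1 noise: profiled rho should be clearly positive
        from sparsegp.synthetic_data import GeneticArchitecture, TrialDesignSpec, \
            assign_trial_layout, simulate_phenotypes
        from sparsegp.genotypes import GenotypeMatrix

        rng = np.random.default_rng(16)
        lines = [f"L{i}" for i in range(30)]
        geno = GenotypeMatrix(
            lines, [f"M{j}" for j in range(200)],
            rng.integers(0, 3, size=(30, 200)).astype(float),
        )
        design = TrialDesignSpec(n_environments=1, n_trials_per_env=1,
                                 entries_per_trial=30, checks_per_trial=0,
                                 grid_rows=6, grid_cols=10, block_size=10)
        layout = assign_trial_layout(lines, design, seed=16, checks=[])
        arch = GeneticArchitecture(
            Lambda_true=np.array([[0.8]]), Psi_true=np.array([0.1]),
            env_main_var=0.0, trial_var=0.0, rep_var=0.1, block_var=0.0,
            spatial_rho_col=0.6, spatial_rho_row=0.6,
            resid_var_per_env=np.array([1.5]),
        )
        pheno, _ = simulate_phenotypes(geno, layout, arch, seed=17)
        from sparsegp.genotypes import compute_G

        kin = compute_G(geno)
        spec = ModelSpec("eq3_single_env", spatial=True)
        design_s = quiet_design(pheno, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(design_s, kin, opts=REMLOptions(max_iter=40))
        (rc, rr) = fit.varcomp.spatial_rho["SE1"]
        assert rc > 0.2 and rr > 0.2
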