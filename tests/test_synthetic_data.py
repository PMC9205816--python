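"""Population, trial-layout and phenotype simulation."""

import numpy as np
import pandas as pd
import pytest

from sparsegp.genotypes import GenotypeMatrix
from sparsegp.synthetic_data import (
    GeneticArchitecture,
    PopulationSpec,
    TrialDesignSpec,
    ar1_noise,
    assign_trial_layout,
    default_architecture,
    simulate_families,
    simulate_founder_genotypes,
    simulate_genetic_values,
    simulate_phenotypes,
)


class TestFounders:
    def test_dosage_range_and_shape(self):
        pop = PopulationSpec(n_founders=50, n_markers=1000, seed=1)
        g = simulate_founder_genotypes(pop)
        assert g.dosages.shape == (50, 1000)
        assert set(np.unique(g.dosages)) <= {0.0, 2.0}

    def test_symmetric_maf_gives_mean_dosage_one(self):
        pop = PopulationSpec(n_founders=400, n_markers=600, maf_range=(0.5, 0.5), seed=2)
        g = simulate_founder_genotypes(pop)
        means = g.dosages.mean(axis=0)
        # 3 standard errors over markers around the symmetric expectation
        se = 3 * means.std() / np.sqrt(len(means))
        assert abs(means.mean() - 1.0) < max(se, 0.01)

    def test_determinism_and_validation(self):
        pop = PopulationSpec(seed=5)
        np.testing.assert_array_equal(
            simulate_founder_genotypes(pop).dosages,
            simulate_founder_genotypes(pop).dosages,
        )
        with pytest.raises(ValueError, match="maf_range"):
            simulate_founder_genotypes(PopulationSpec(maf_range=(0.0, 0.6)))


class TestFamilies:
    def test_mendelian_transmission(self):
        # homozygous 0 x 0 -> all progeny 0; 2 x 0 (no selfing) -> all 1
        markers = ["m1", "m2"]
        f = GenotypeMatrix(["P1", "P2"], markers, np.array([[0.0, 2.0], [0.0, 0.0]]))
        pop = PopulationSpec(
            n_founders=2, n_markers=2, n_crosses=4, family_size_range=(3, 3),
            n_selfing_generations=0, seed=3,
        )
        geno, ped = simulate_families(f, pop)
        assert np.all(geno.dosages[:, 0] == 0.0)
        assert set(np.unique(geno.dosages[:, 1])) <= {1.0}
        for _, p1, p2 in ped.records:
            assert {p1, p2} == {"P1", "P2"}

    def test_family_sizes_and_pedigree_rows_consistent(self, small_population):
        pop, founders, geno, ped = small_population
        assert len(ped.records) == geno.n_lines
        fams = pd.Series([l.split(".")[0] for l in geno.line_ids]).value_counts()
        assert fams.min() >= pop.family_size_range[0]
        assert fams.max() <= pop.family_size_range[1]
        assert len(fams) == pop.n_crosses

    def test_selfing_increases_homozygosity(self):
        pop0 = PopulationSpec(n_founders=20, n_markers=800, n_crosses=20,
                              family_size_range=(4, 4), n_selfing_generations=0, seed=9)
        pop3 = PopulationSpec(**{**pop0.__dict__, "n_selfing_generations": 3})
        f = simulate_founder_genotypes(pop0)
        het0 = (simulate_families(f, pop0)[0].dosages == 1).mean()
        het3 = (simulate_families(f, pop3)[0].dosages == 1).mean()
        assert het3 < 0.25 * het0  # ~ (1/2)^3 of the F1 heterozygosity

    def test_requires_two_founders(self):
        f = GenotypeMatrix(["A"], ["m"], np.array([[0.0]]))
        with pytest.raises(ValueError, match="2 founders"):
            simulate_families(f, PopulationSpec(n_founders=1, n_markers=1))


class TestTrialLayout:
    def test_stage2_geometry_600_plots_per_env(self):
        lines = [f"L{i}" for i in range(280)]
        design = TrialDesignSpec()  # 6 envs, 5 trials x (56+4), 2 reps, 8x15 grids
        layout = assign_trial_layout(lines, design, seed=1)
        assert len(layout) == 6 * 600
        per_env = layout.groupby("env").size()
        assert (per_env == 600).all()
        # every line in exactly one trial per env, twice
        cnt = layout[~layout["line"].str.startswith("CHK")].groupby(["env", "line"]).size()
        assert (cnt == 2).all()
        tr = layout.groupby(["env", "line"])["trial"].nunique()
        assert (tr.loc[~tr.index.get_level_values("line").str.startswith("CHK")] == 1).all()

    def test_checks_in_every_trial(self):
        lines = [f"L{i}" for i in range(280)]
        layout = assign_trial_layout(lines, TrialDesignSpec(), seed=1)
        chk = layout[layout["line"] == "CHK1"]
        assert chk.groupby("env")["trial"].nunique().eq(5).all()

    def test_unique_plot_coordinates_and_block_nesting(self):
        lines = [f"L{i}" for i in range(40)]
        design = TrialDesignSpec(n_environments=2, n_trials_per_env=2,
                                 entries_per_trial=20, checks_per_trial=2,
                                 grid_rows=6, grid_cols=8, block_size=6)
        layout = assign_trial_layout(lines, design, seed=2)
        assert not layout.duplicated(["env", "row", "col"]).any()
        # blocks nested within (trial, rep)
        blk = layout.groupby(["env", "trial", "rep"])["block"].nunique()
        assert (blk > 1).all()

    def test_minimal_layout_and_determinism(self):
        design = TrialDesignSpec(n_environments=1, n_trials_per_env=1,
                                 entries_per_trial=1, checks_per_trial=2,
                                 n_replicates=1, grid_rows=3, grid_cols=1)
        layout = assign_trial_layout(["only"], design, seed=3)
        assert len(layout) == 3  # 1 entry + 2 checks
        l2 = assign_trial_layout(["only"], design, seed=3)
        pd.testing.assert_frame_equal(layout, l2)

    def test_grid_too_small_names_deficit(self):
        design = TrialDesignSpec(n_environments=1, n_trials_per_env=1,
                                 entries_per_trial=10, checks_per_trial=0,
                                 grid_rows=3, grid_cols=3)
        with pytest.raises(ValueError, match="deficit"):
            assign_trial_layout([f"L{i}" for i in range(9)], design, seed=1)


@pytest.fixture(scope="module")
def layout40(small_population):
    _, founders, geno, _ = small_population
    lines = list(geno.line_ids)[:40]
    design = TrialDesignSpec(n_environments=2, n_trials_per_env=2,
                             entries_per_trial=20, checks_per_trial=0,
                             grid_rows=5, grid_cols=8, block_size=7)
    sub = GenotypeMatrix(lines, list(geno.marker_ids), geno.dosages[:40])
    return sub, assign_trial_layout(lines, design, seed=4)


class TestPhenotypes:

    def test_common_factor_gives_identical_values_across_envs(self, layout40):
        geno, layout = layout40
        arch = GeneticArchitecture(
            Lambda_true=np.ones((2, 1)), Psi_true=np.zeros(2),
            resid_var_per_env=np.full(2, 0.5),
        )
        pheno, truth = simulate_phenotypes(geno, layout, arch, seed=5)
        np.testing.assert_allclose(truth.iloc[:, 0], truth.iloc[:, 1], atol=1e-10)

    def test_null_genetics_variance_decomposition(self, layout40):
        geno, layout = layout40
        arch = GeneticArchitecture(
            Lambda_true=np.zeros((2, 1)), Psi_true=np.zeros(2),
            env_main_var=0.0, trial_var=0.2, rep_var=0.1, block_var=0.2,
            spatial_rho_col=0.0, spatial_rho_row=0.0,
            resid_var_per_env=np.full(2, 0.5),
        )
        # average realized variance over several draws; expectation is the
        # sum of the design and residual variances
        expected = 0.2 + 0.1 + 0.2 + 0.5
        vs = []
        for s in range(12):
            pheno, truth = simulate_phenotypes(geno, layout, arch, seed=100 + s)
            assert np.all(truth.to_numpy() == 0.0)
            vs.append(pheno["value"].var())
        assert np.mean(vs) == pytest.approx(expected, rel=0.25)

    def test_fa_identity_correlation_half(self, small_population):
        # k=2, Lambda=(1, .5), Psi=(0, .75): corr = .5/sqrt(.25+.75) = 0.5
        _, founders, geno, _ = small_population
        arch = GeneticArchitecture(
            Lambda_true=np.array([[1.0], [0.5]]), Psi_true=np.array([0.0, 0.75]),
            resid_var_per_env=np.ones(2),
        )
        vals = simulate_genetic_values(geno, arch, seed=11)
        r = np.corrcoef(vals.iloc[:, 0], vals.iloc[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.08)

    def test_realized_covariance_converges_to_target(self):
        # family-structured panel of ~2000 lines
        pop = PopulationSpec(n_founders=200, n_markers=800, n_crosses=400,
                             family_size_range=(3, 7), seed=21)
        founders = simulate_founder_genotypes(pop)
        geno, _ = simulate_families(founders, pop)
        lam = np.array([[1.0, 0.0], [0.6, 0.4], [0.2, 0.7]])
        psi = np.array([0.2, 0.3, 0.4])
        arch = GeneticArchitecture(Lambda_true=lam, Psi_true=psi,
                                   resid_var_per_env=np.ones(3))
        vals = simulate_genetic_values(geno, arch, seed=22).to_numpy()
        realized = np.cov(vals.T, bias=True)
        target = arch.Go_true
        assert np.max(np.abs(realized - target)) <= 0.05 * np.max(np.diag(target))

    def test_spatial_lag1_correlations(self):
        rng = np.random.default_rng(7)
        field = ar1_noise(rng, 100, 100, rho_row=0.4, rho_col=0.25)
        r_row = np.corrcoef(field[:-1, :].ravel(), field[1:, :].ravel())[0, 1]
        r_col = np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1]
        assert r_row == pytest.approx(0.4, abs=0.05)
        assert r_col == pytest.approx(0.25, abs=0.05)
        assert field.var() == pytest.approx(1.0, abs=0.1)

    def test_heritability_identity_on_truth(self, layout40):
        # with design variances at zero, between/within line variance per SE
        # reproduces s2_g/(s2_g+s2_e)
        geno, layout = layout40
        arch = GeneticArchitecture(
            Lambda_true=np.array([[1.0], [0.8]]), Psi_true=np.array([0.1, 0.2]),
            env_main_var=0.0, trial_var=0.0, rep_var=0.0, block_var=0.0,
            spatial_rho_col=0.0, spatial_rho_row=0.0,
            resid_var_per_env=np.array([1.0, 0.5]),
        )
        pheno, truth = simulate_phenotypes(geno, layout, arch, seed=31)
        for j, env in enumerate(sorted(pheno["env"].unique())):
            sub = pheno[pheno["env"] == env]
            sg = truth.iloc[:, j].var()
            se = (sub.groupby("line")["value"].transform("mean") - sub["value"]).var() * 2
            h2_emp = sg / (sg + se)
            assert h2_emp == pytest.approx(arch.plot_heritability_true(j), abs=0.12)

    def test_simulation_pure_function_of_seed(self, layout40):
        geno, layout = layout40
        arch = default_architecture(6)
        arch2 = GeneticArchitecture(
            Lambda_true=arch.Lambda_true[:2], Psi_true=arch.Psi_true[:2],
            resid_var_per_env=arch.resid_var_per_env[:2],
        )
        p1, t1 = simulate_phenotypes(geno, layout, arch2, seed=77)
        p2, t2 = simulate_phenotypes(geno, layout, arch2, seed=77)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_non_psd_target_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite|non-negative"):
            GeneticArchitecture(
                Lambda_true=np.ones((2, 1)), Psi_true=np.array([-0.5, 0.1]),
                resid_var_per_env=np.ones(2),
            ).validate()


class TestDefaultArchitecture:
    def test_correlation_and_heritability_ranges(self):
        arch = default_architecture(6)
        Go = arch.Go_true
        d = np.sqrt(np.diag(Go))
        R = Go / np.outer(d, d)
        off = R[np.triu_indices(6, 1)]
        assert off.min() < 0 < off.max()
        assert off.max() > 0.7
        h2 = [arch.plot_heritability_true(k) for k in range(6)]
        assert min(h2) == pytest.approx(0.18, abs=1e-9)
        assert max(h2) >= 0.55
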