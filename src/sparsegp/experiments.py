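"""Canned validation experiments at fixed study-like conditions.

These are the package's own calibration studies: parameter recovery of the
factor-analytic genetic covariance and plot heritabilities from a 300-line
six-SE cohort, and the sparse-testing comparison of overlap strategies.
Both the test suite and the reproduction script run them; they are pure
functions of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, compute_G, filter_snps, impute_missing
from .me_mixed_model import (
    ModelSpec,
    REMLOptions,
    build_design,
    genetic_correlations,
    plot_heritability,
    reml_fit,
)
from .synthetic_data import (
    PopulationSpec,
    TrialDesignSpec,
    assign_trial_layout,
    default_architecture,
    simulate_families,
    simulate_founder_genotypes,
    simulate_phenotypes,
)

__all__ = ["RecoveryResult", "recovery_experiment", "recovery_study"]


@dataclass
class RecoveryResult:
    corr_true: np.ndarray
    corr_est: np.ndarray
    h2_true: np.ndarray
    h2_est: np.ndarray

    @property
    def corr_mae(self) -> float:
        iu = np.triu_indices(self.corr_true.shape[0], 1)
        return float(np.mean(np.abs(self.corr_est[iu] - self.corr_true[iu])))

    @property
    def h2_mae(self) -> float:
        return float(np.mean(np.abs(self.h2_est - self.h2_true)))


def recovery_experiment(seed: int, n_lines: int = 300) -> RecoveryResult:
    """One seed of the k=6 recovery study: simulate a 300-line cohort with
    the study-like genetic architecture (pairwise genetic correlations from
    ~-0.06 to ~0.77, plot heritabilities 0.18-0.6), two replicates, six
    trials per SE, then re-estimate the covariance by REML."""
    pop = PopulationSpec(n_founders=40, n_markers=1500, n_crosses=70, seed=seed)
    founders = simulate_founder_genotypes(pop)
    geno, _ = simulate_families(founders, pop)
    if geno.n_lines < n_lines:
        raise ValueError("population too small for the requested line count")
    lines = list(geno.line_ids)[:n_lines]
    geno = GenotypeMatrix(lines, list(geno.marker_ids), geno.dosages[:n_lines])
    arch = default_architecture(6)
    entries = int(np.ceil(n_lines / 6))
    design = TrialDesignSpec(
        n_environments=6, n_trials_per_env=6, entries_per_trial=entries,
        checks_per_trial=4, n_replicates=2,
        grid_rows=9, grid_cols=int(np.ceil(2 * (entries + 4) / 9)),
        block_size=14,
    )
    checks = founders.line_ids[: design.checks_per_trial]
    layout = assign_trial_layout(lines, design, seed=seed + 1, checks=checks, year=1)
    allg = GenotypeMatrix(
        lines + checks, list(geno.marker_ids),
        np.vstack([geno.dosages, founders.dosages[: len(checks)]]),
    )
    pheno, _ = simulate_phenotypes(allg, layout, arch, seed=seed + 2)
    G = compute_G(impute_missing(filter_snps(allg)))
    spec = ModelSpec("eq1_multi_env", fa_order=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = reml_fit(build_design(pheno, spec), G, opts=REMLOptions())
    corr_est = genetic_correlations(fit.varcomp.Go)
    corr_true = genetic_correlations(arch.Go_true)
    h2_est = np.array([plot_heritability(fit.varcomp, e) for e in fit.varcomp.env_order])
    h2_true = np.array([arch.plot_heritability_true(j) for j in range(6)])
    return RecoveryResult(corr_true, corr_est, h2_true, h2_est)


def recovery_study(base_seed: int, n_seeds: int = 10) -> tuple[float, float]:
    """Mean absolute errors of genetic correlations and heritabilities over
    ``n_seeds`` independent cohorts."""
    results = [recovery_experiment(base_seed + i) for i in range(n_seeds)]
    return (
        float(np.mean([r.corr_mae for r in results])),
        float(np.mean([r.h2_mae for r in results])),
    )
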