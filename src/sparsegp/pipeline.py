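"""End-to-end sparse-testing experiments on synthetic breeding data.

Orchestrates: population and trial simulation, kinship construction,
full-data reference fits (GBLUP and BLUE), sparse-testing allocation with
repeat randomization, masked model fits with GBLUP or PBLUP kinships and
optional historical-data augmentation, and the two accuracy measures
(per-SE predictive ability, Smith-Hazel top-fraction intersection).  The
whole experiment is a pure function of (configuration, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as sio
from .genotypes import (
    KinshipMatrix,
    block_diagonal_kinship,
    compute_A,
    compute_G,
    filter_snps,
    impute_missing,
)
from .me_mixed_model import (
    FitResult,
    ModelSpec,
    REMLOptions,
    build_design,
    compute_blues,
    reml_fit,
)
from .selection_metrics import (
    DEFAULT_ECONOMIC_WEIGHTS,
    IndexSpec,
    index_scores,
    intersection_accuracy,
    predictive_ability,
    select_top,
    smith_hazel_weights,
)
from .sparse_design import allocate_nonoverlap, allocate_overlap, mask_phenotypes
from .synthetic_data import (
    GeneticArchitecture,
    PopulationSpec,
    TrialDesignSpec,
    assign_trial_layout,
    default_architecture,
    simulate_families,
    simulate_founder_genotypes,
    simulate_phenotypes,
)

__all__ = [
    "ExperimentConfig",
    "SyntheticDataset",
    "AccuracyReport",
    "StageResults",
    "make_synthetic_dataset",
    "run_sparse_experiment",
    "augment_training",
    "stage_advancement_comparison",
    "run_stage_advancement",
    "write_report",
]


@dataclass
class ExperimentConfig:
    """Configuration of one sparse-testing experiment.

    Defaults follow the stage-2 study conditions: 280-line cohort in six
    SEs, overlap strategies 0-50%, 30 randomization repeats, top-20%
    advancement fraction and the six-SE economic weights.
    """

    population: PopulationSpec = field(default_factory=PopulationSpec)
    design: TrialDesignSpec = field(default_factory=TrialDesignSpec)
    architecture: GeneticArchitecture | None = None
    strategies: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    n_repeats: int = 30
    models: tuple = ("GBLUP",)          # subset of {"GBLUP", "PBLUP"}
    fa_order: int = 1
    spatial: bool = False
    augmentation: str = "none"          # none | single_env_history | multi_year_history
    history_n_lines: int = 150
    accuracy_fraction: float = 0.20
    advancement_fractions: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    economic_weights: tuple | None = None
    seed: int = 1

    def validate(self) -> None:
        if not self.strategies:
            raise ValueError("strategies must be nonempty")
        for f in self.strategies:
            if not 0 <= f < 1:
                raise ValueError("overlap fractions must lie in [0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for m in self.models:
            if m not in ("GBLUP", "PBLUP"):
                raise ValueError(f"unknown model {m!r}")
        if self.augmentation not in ("none", "single_env_history", "multi_year_history"):
            raise ValueError(f"unknown augmentation mode {self.augmentation!r}")

    def weights(self, k: int) -> np.ndarray:
        if self.economic_weights is not None:
            w = np.asarray(self.economic_weights, float)
            if len(w) != k:
                raise ValueError(f"economic weights have length {len(w)}, expected {k}")
            return w
        if k == len(DEFAULT_ECONOMIC_WEIGHTS):
            return np.asarray(DEFAULT_ECONOMIC_WEIGHTS)
        return np.full(k, 1.0 / k)


@dataclass
class SyntheticDataset:
    pheno: pd.DataFrame
    truth: pd.DataFrame
    kinship_G: KinshipMatrix
    kinship_A: KinshipMatrix
    genotypes: "GenotypeMatrix | None"
    lines: list[str]
    checks: list[str]
    envs: list[str]
    arch: GeneticArchitecture
    history: pd.DataFrame | None = None
    history_lines: list[str] = field(default_factory=list)

    def kinship(self, model: str, extra_lines: list[str] | None = None) -> KinshipMatrix:
        k = self.kinship_G if model == "GBLUP" else self.kinship_A
        if extra_lines:
            k = block_diagonal_kinship(k, extra_lines)
        return k


@dataclass
class AccuracyReport:
    raw: pd.DataFrame        # strategy, repeat, env, model, augmentation, predictive_ability
    sh: pd.DataFrame         # strategy, repeat, model, augmentation, sh_accuracy
    summary: pd.DataFrame
    config: dict
    n_failures: int = 0


@dataclass
class StageResults:
    """Per-line selection metrics of one testing stage."""

    gblup: pd.Series
    blue: pd.Series


def make_synthetic_dataset(cfg: ExperimentConfig) -> SyntheticDataset:
    """Simulate one cohort: founders, families, checks, trial layout,
    phenotypes, and both kinship matrices (QC'd genomic and pedigree)."""
    cfg.validate()
    pop = replace(cfg.population, seed=cfg.seed)
    founders = simulate_founder_genotypes(pop)
    geno, ped = simulate_families(founders, pop)
    design = cfg.design
    capacity = design.entries_per_trial * design.n_trials_per_env
    if geno.n_lines > capacity:
        # random family sizes can overshoot the trial capacity; keep the
        # first `capacity` lines (family order is already randomized)
        from .genotypes import GenotypeMatrix as _GM

        geno = _GM(
            list(geno.line_ids)[:capacity], list(geno.marker_ids),
            geno.dosages[:capacity],
        )
    rng = np.random.default_rng(cfg.seed + 11)
    check_idx = rng.choice(founders.n_lines, size=design.checks_per_trial, replace=False)
    checks = [founders.line_ids[i] for i in check_idx]
    lines = list(geno.line_ids)
    layout = assign_trial_layout(lines, design, seed=cfg.seed + 23, checks=checks, year=2)
    arch = cfg.architecture or default_architecture(design.n_environments)

    from .genotypes import GenotypeMatrix

    all_geno = GenotypeMatrix(
        lines + checks,
        list(geno.marker_ids),
        np.vstack([geno.dosages, founders.dosages[check_idx]]),
    )
    all_geno = impute_missing(filter_snps(all_geno))
    G = compute_G(all_geno)
    A = compute_A(ped)
    # align A to the genotyped panel (founders drop out, checks are founders)
    keep = [l for l in G.line_ids if l in set(A.line_ids)]
    ix = A.index_of(keep)
    A = KinshipMatrix(keep, A.values[np.ix_(ix, ix)], "pedigree")
    if set(keep) != set(G.line_ids):
        A = block_diagonal_kinship(A, [l for l in G.line_ids if l not in set(keep)])
    # same ordering as G
    ix = A.index_of(G.line_ids)
    A = KinshipMatrix(list(G.line_ids), A.values[np.ix_(ix, ix)], "pedigree")

    pheno, truth = simulate_phenotypes(all_geno, layout, arch, seed=cfg.seed + 37)
    envs = sorted(pheno["env"].unique())

    history = None
    history_lines: list[str] = []
    if cfg.augmentation != "none":
        history, history_lines = _simulate_history(cfg, founders, arch)
    return SyntheticDataset(
        pheno=pheno, truth=truth, kinship_G=G, kinship_A=A, genotypes=all_geno,
        lines=lines, checks=checks, envs=envs, arch=arch, history=history,
        history_lines=history_lines,
    )


def _simulate_history(cfg: ExperimentConfig, founders, arch: GeneticArchitecture):
    """Prior-year cohort treated as ungenotyped (identity kinship block)."""
    n_envs = 1 if cfg.augmentation == "single_env_history" else cfg.design.n_environments
    pop = replace(
        cfg.population,
        n_crosses=max(cfg.history_n_lines // 5, 1),
        seed=cfg.seed + 101,
    )
    from .genotypes import GenotypeMatrix

    geno_h0, _ = simulate_families(founders, pop)
    hist_lines = [f"H{l}" for l in geno_h0.line_ids]
    geno_h = GenotypeMatrix(hist_lines, list(geno_h0.marker_ids), geno_h0.dosages)
    n_trials = max(1, int(np.ceil(len(hist_lines) / cfg.design.entries_per_trial)))
    design_h = replace(cfg.design, n_environments=n_envs, n_trials_per_env=n_trials)
    layout = assign_trial_layout(
        hist_lines, design_h, seed=cfg.seed + 103,
        checks=[f"HCHK{i+1}" for i in range(design_h.checks_per_trial)], year=1,
    )
    if n_envs == 1:
        arch_h = GeneticArchitecture(
            n_qtl=arch.n_qtl,
            Lambda_true=arch.Lambda_true[:1],
            Psi_true=arch.Psi_true[:1],
            resid_var_per_env=arch.resid_var_per_env[:1],
            spatial_rho_col=arch.spatial_rho_col,
            spatial_rho_row=arch.spatial_rho_row,
            mean=arch.mean,
        )
    else:
        arch_h = arch
    from .genotypes import GenotypeMatrix

    chk = GenotypeMatrix(
        [f"HCHK{i+1}" for i in range(design_h.checks_per_trial)],
        list(geno_h.marker_ids),
        founders.dosages[: design_h.checks_per_trial],
    )
    all_h = GenotypeMatrix(
        hist_lines + chk.line_ids,
        list(geno_h.marker_ids),
        np.vstack([geno_h.dosages, chk.dosages]),
    )
    pheno_h, _ = simulate_phenotypes(all_h, layout, arch_h, seed=cfg.seed + 107)
    return pheno_h, hist_lines + chk.line_ids


def augment_training(
    current: pd.DataFrame, history: pd.DataFrame | None, mode: str
) -> tuple[pd.DataFrame, dict]:
    """Append historical records to the calibration data.

    ``single_env_history`` appends a one-SE prior-year table; its SE is
    relabeled with a ``*`` suffix and enters the factor-analytic structure
    as an additional correlated environment.  ``multi_year_history``
    appends a full multi-SE prior-year table (``**`` suffix) and switches
    the model to the multi-year variant (year-nested replicate and block
    terms).  Returns the combined table and the model adjustments.
    """
    if mode == "none" or history is None:
        return current, {"formula_kind": "eq1_multi_env", "history_envs": []}
    if set(history["year"]) & set(current["year"]):
        raise ValueError("history years collide with current years")
    hist = history.copy()
    suffix = "*" if mode == "single_env_history" else "**"
    if mode == "single_env_history" and hist["env"].nunique() != 1:
        raise ValueError("single_env_history expects a one-environment history table")
    hist["env"] = hist["env"].astype(str) + suffix
    combined = pd.concat([current, hist], ignore_index=True)
    return combined, {
        "formula_kind": "eq2_multi_env_multi_year",
        "history_envs": sorted(hist["env"].unique()),
    }


def _sh_selection(
    fit: FitResult, lines: list[str], envs: list[str], w: np.ndarray,
    fraction: float, n_reps: int, source: str
):
    """Smith-Hazel top-fraction selection from a fit's GBLUP table, using
    its own Go as the genetic covariance and Go + diag(residual / reps) as
    the per-line-mean phenotypic covariance."""
    k = len(envs)
    kpos = [fit.varcomp.env_order.index(e) for e in envs]
    Go = fit.varcomp.Go[np.ix_(kpos, kpos)]
    resid = np.array([fit.varcomp.resid[e] for e in envs])
    P = Go + np.diag(resid / max(n_reps, 1))
    b = smith_hazel_weights(IndexSpec(w, Go, P))
    mat = fit.gblup_matrix().loc[lines, envs]
    return select_top(index_scores(mat, b), fraction, source=source)


def run_sparse_experiment(
    cfg: ExperimentConfig,
    dataset: SyntheticDataset | None = None,
    opts: REMLOptions | None = None,
) -> AccuracyReport:
    """Run the full sparse-testing evaluation for every strategy, repeat
    and model, against full-data references computed once."""
    cfg.validate()
    ds = dataset or make_synthetic_dataset(cfg)
    opts = opts or REMLOptions()
    envs = ds.envs
    w = cfg.weights(len(envs))
    spec = ModelSpec(
        "eq1_multi_env", fa_order=cfg.fa_order, spatial=cfg.spatial,
        exclude_genetic_lines=tuple(ds.checks),
    )
    # full-data references, computed once and reused across strategies
    full_blues = compute_blues(ds.pheno, spec, opts=opts)
    blue_mat = full_blues.blue_matrix()
    full_fits = {
        m: reml_fit(build_design(ds.pheno, spec), ds.kinship(m), opts=opts)
        for m in cfg.models
    }
    full_sets = {
        m: _sh_selection(
            full_fits[m], ds.lines, envs, w, cfg.accuracy_fraction,
            cfg.design.n_replicates, "full_data_gblup",
        )
        for m in cfg.models
    }

    raw_rows, sh_rows = [], []
    n_fail = 0
    for f in cfg.strategies:
        for rep in range(cfg.n_repeats):
            seed = cfg.seed + 1000 * int(round(100 * f)) + rep
            if f == 0:
                plan = allocate_nonoverlap(ds.lines, envs, seed=seed, repeat_index=rep)
            else:
                plan = allocate_overlap(ds.lines, envs, f, seed=seed, repeat_index=rep)
            training, truth_cells = mask_phenotypes(ds.pheno, plan)
            training, adj = augment_training(training, ds.history, cfg.augmentation)
            mspec = replace(spec, formula_kind=adj["formula_kind"])
            for model in cfg.models:
                try:
                    kin = ds.kinship(model, ds.history_lines or None)
                    fit = reml_fit(build_design(training, mspec), kin, opts=opts)
                except Exception as exc:  # record and continue
                    warnings.warn(
                        f"fit failed (strategy={f}, repeat={rep}, model={model}): {exc}",
                        UserWarning, stacklevel=2,
                    )
                    n_fail += 1
                    for env in envs:
                        raw_rows.append((f, rep, env, model, cfg.augmentation, np.nan))
                    sh_rows.append((f, rep, model, cfg.augmentation, np.nan))
                    continue
                gmat = fit.gblup_matrix()
                for env in envs:
                    pred_lines = sorted(plan.prediction_set(env))
                    pa = predictive_ability(
                        gmat.loc[pred_lines, env], blue_mat.loc[pred_lines, env]
                    )
                    raw_rows.append((f, rep, env, model, cfg.augmentation, pa))
                sh_set = _sh_selection(
                    fit, ds.lines, envs, w, cfg.accuracy_fraction,
                    cfg.design.n_replicates, "prediction_model_gblup",
                )
                sh_rows.append(
                    (f, rep, model, cfg.augmentation,
                     intersection_accuracy(full_sets[model], sh_set))
                )

    raw = pd.DataFrame(
        raw_rows,
        columns=["strategy", "repeat", "env", "model", "augmentation", "predictive_ability"],
    )
    sh = pd.DataFrame(
        sh_rows, columns=["strategy", "repeat", "model", "augmentation", "sh_accuracy"]
    )
    summary = (
        raw.groupby(["strategy", "env", "model", "augmentation"], as_index=False)
        .agg(
            mean_predictive_ability=("predictive_ability", "mean"),
            sd_predictive_ability=("predictive_ability", "std"),
        )
    )
    cfg_doc = {
        "seed": cfg.seed, "strategies": list(map(float, cfg.strategies)),
        "n_repeats": cfg.n_repeats, "models": list(cfg.models),
        "augmentation": cfg.augmentation, "fa_order": cfg.fa_order,
        "spatial": cfg.spatial, "accuracy_fraction": cfg.accuracy_fraction,
        "n_lines": len(ds.lines), "envs": envs,
    }
    return AccuracyReport(raw=raw, sh=sh, summary=summary, config=cfg_doc, n_failures=n_fail)


# ---------------------------------------------------------------------------
# stage advancement


def stage_advancement_comparison(
    stage1: StageResults,
    stage2: StageResults,
    fractions: tuple = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Between-stage agreement of the two selection metrics.

    For GBLUP and BLUE separately: Pearson correlation of the per-line
    values across stages, and for each selection fraction the proportion of
    lines shared by the stage-wise top sets.
    """
    rows = []
    for metric, s1, s2 in (
        ("GBLUP", stage1.gblup, stage2.gblup),
        ("BLUE", stage1.blue, stage2.blue),
    ):
        common = s1.index.intersection(s2.index)
        if len(common) < 3:
            raise ValueError("need at least 3 common lines between stages")
        x, y = s1.loc[common], s2.loc[common]
        corr = float(np.corrcoef(x, y)[0, 1])
        for frac in fractions:
            top1 = select_top(x, frac, source="stage1")
            top2 = select_top(y, frac, source="stage2")
            rows.append((metric, corr, frac, intersection_accuracy(top1, top2)))
    return pd.DataFrame(rows, columns=["metric", "stage_correlation", "fraction", "top_overlap"])


def run_stage_advancement(
    n_stage1: int = 200,
    n_advance: int = 100,
    k_stage2: int = 3,
    seed: int = 1,
    h2: float = 0.25,
    opts: REMLOptions | None = None,
) -> pd.DataFrame:
    """Two-stage advancement experiment on synthetic data.

    Stage 1: one SE, all lines; stage 2: a subset advanced to ``k_stage2``
    SEs genetically correlated with the stage-1 SE.  Both stages are fitted
    with the corresponding model variants; GBLUP and BLUE per line feed
    :func:`stage_advancement_comparison`.
    """
    opts = opts or REMLOptions()
    pop = PopulationSpec(
        n_founders=30, n_markers=1200, n_crosses=max(n_stage1 // 5, 1), seed=seed
    )
    founders = simulate_founder_genotypes(pop)
    geno, _ = simulate_families(founders, pop)
    lines = list(geno.line_ids)[:n_stage1]
    from .genotypes import GenotypeMatrix

    geno = GenotypeMatrix(lines, list(geno.marker_ids), geno.dosages[: len(lines)])
    G = compute_G(impute_missing(filter_snps(geno)))

    # common-factor loadings: stage-1 SE plus correlated stage-2 SEs
    k = 1 + k_stage2
    lam = np.full((k, 1), 0.8)
    psi = 1.0 - lam[:, 0] ** 2
    resid = np.full(k, (1.0 - h2) / h2)
    arch = GeneticArchitecture(
        n_qtl=200, Lambda_true=lam, Psi_true=psi, resid_var_per_env=resid,
        spatial_rho_col=0.0, spatial_rho_row=0.0,
    )
    design = TrialDesignSpec(
        n_environments=k, n_trials_per_env=max(1, n_stage1 // 50),
        entries_per_trial=int(np.ceil(n_stage1 / max(1, n_stage1 // 50))),
        checks_per_trial=0, grid_rows=10,
        grid_cols=int(np.ceil(2 * (np.ceil(n_stage1 / max(1, n_stage1 // 50))) / 10)),
        block_size=10,
    )
    layout = assign_trial_layout(lines, design, seed=seed + 5, checks=[], year=1)
    pheno, _ = simulate_phenotypes(geno, layout, arch, seed=seed + 7)

    rng = np.random.default_rng(seed + 13)
    advanced = sorted(rng.choice(lines, size=n_advance, replace=False))
    envs = sorted(pheno["env"].unique())
    stage1_df = pheno[pheno["env"] == envs[0]].copy()
    stage2_df = pheno[(pheno["env"] != envs[0]) & pheno["line"].isin(advanced)].copy()

    spec1 = ModelSpec("eq3_single_env")
    fit1 = reml_fit(build_design(stage1_df, spec1), G, opts=opts)
    blue1 = compute_blues(stage1_df, spec1, opts=opts)
    spec2 = ModelSpec("eq1_multi_env")
    fit2 = reml_fit(build_design(stage2_df, spec2), G, opts=opts)
    blue2 = compute_blues(stage2_df, spec2, opts=opts)

    s1 = StageResults(
        gblup=fit1.gblup_matrix().loc[advanced].iloc[:, 0],
        blue=blue1.blue_matrix().loc[advanced].iloc[:, 0],
    )
    s2 = StageResults(
        gblup=fit2.gblup_matrix().loc[advanced].mean(axis=1),
        blue=blue2.blue_matrix().loc[advanced].mean(axis=1),
    )
    return stage_advancement_comparison(s1, s2)


def write_report(report: AccuracyReport, path, plots: bool = False) -> list[str]:
    """Write raw rows, summaries and a YAML manifest (plus optional plots);
    returns the list of files written."""
    from pathlib import Path

    if report.raw.empty:
        raise ValueError("report has no rows")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    raw_p = out / "predictive_ability_raw.tsv"
    report.raw.to_csv(raw_p, sep="\t", index=False)
    files.append(str(raw_p))
    sh_p = out / "sh_accuracy_raw.tsv"
    report.sh.to_csv(sh_p, sep="\t", index=False)
    files.append(str(sh_p))
    sum_p = out / "summary.tsv"
    report.summary.to_csv(sum_p, sep="\t", index=False)
    files.append(str(sum_p))
    man_p = out / "manifest.yaml"
    sio.write_yaml({"config": report.config, "n_failures": report.n_failures}, man_p)
    files.append(str(man_p))
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for env, sub in report.summary.groupby("env"):
            sub = sub.sort_values("strategy")
            ax.plot(sub["strategy"], sub["mean_predictive_ability"], marker="o", label=env)
        ax.set_xlabel("overlap fraction")
        ax.set_ylabel("mean predictive ability")
        ax.legend(fontsize=7)
        fig.tight_layout()
        plot_p = out / "predictive_ability.png"
        fig.savefig(plot_p, dpi=120)
        plt.close(fig)
        files.append(str(plot_p))
    return files
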