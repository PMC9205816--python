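"""Synthetic breeding data with the structure assumed by the analysis.

The generator emulates an early-yield-testing wheat programme: a panel of
inbred founders, many small biparental families (1-9 progeny) advanced by a
few generations of selfing, alpha-lattice-style trials (equal-size
incomplete blocks nested in replicates) in several managed selection
environments (SEs), and plot phenotypes built from

``value = mean + SE + trial + rep(SE,trial) + block(rep) + genetic(line,SE)
+ spatial AR1xAR1 noise``

where the line-by-SE genetic values carry a factor-analytic covariance
``Lambda Lambda' + Psi`` between environments and marker-derived
relatedness between lines.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, KinshipMatrix, PedigreeTable, compute_G

__all__ = [
    "PopulationSpec",
    "TrialDesignSpec",
    "GeneticArchitecture",
    "default_architecture",
    "simulate_founder_genotypes",
    "simulate_families",
    "assign_trial_layout",
    "simulate_phenotypes",
    "ar1_noise",
]

PLOT_COLUMNS = ["line", "env", "year", "trial", "rep", "block", "row", "col", "value"]


@dataclass
class PopulationSpec:
    """Founder panel and crossing design.

    Defaults emulate a stage-2 cohort: ~56 crosses with family sizes drawn
    uniformly from 1-9 give ~280 lines in expectation.
    """

    n_founders: int = 40
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_crosses: int = 56
    family_size_range: tuple[int, int] = (1, 9)
    n_selfing_generations: int = 3
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        flo, fhi = self.family_size_range
        if not (1 <= flo <= fhi <= 50):
            raise ValueError(f"family_size_range must lie within [1, 50], got {self.family_size_range}")
        for name in ("n_founders", "n_markers", "n_crosses"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_selfing_generations < 0:
            raise ValueError("n_selfing_generations must be >= 0")


@dataclass
class TrialDesignSpec:
    """Multi-environment trial layout.

    Defaults follow a stage-2 elite yield trial: six SEs, five trials of 56
    entries + 4 checks in an incomplete-block design with two replicates,
    each trial sown as an 8-row x 15-column grid.
    """

    n_environments: int = 6
    n_trials_per_env: int = 5
    entries_per_trial: int = 56
    checks_per_trial: int = 4
    n_replicates: int = 2
    grid_rows: int = 8
    grid_cols: int = 15
    block_size: int = 8

    def validate(self, n_lines: int | None = None) -> None:
        for name in (
            "n_environments", "n_trials_per_env", "entries_per_trial",
            "n_replicates", "grid_rows", "grid_cols", "block_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.checks_per_trial < 0:
            raise ValueError("checks_per_trial must be >= 0")
        plots_per_trial = self.n_replicates * (self.entries_per_trial + self.checks_per_trial)
        cap = self.grid_rows * self.grid_cols
        if cap < plots_per_trial:
            raise ValueError(
                f"trial grid too small: {self.grid_rows}x{self.grid_cols}={cap} cells "
                f"but {plots_per_trial} plots required (deficit {plots_per_trial - cap})"
            )
        if n_lines is not None and self.entries_per_trial * self.n_trials_per_env < n_lines:
            raise ValueError(
                f"{n_lines} lines do not fit in {self.n_trials_per_env} trials of "
                f"{self.entries_per_trial} entries"
            )


@dataclass
class GeneticArchitecture:
    """True genetic and non-genetic variance structure for simulation.

    ``Lambda_true`` (k x m) and ``Psi_true`` (k) define the between-SE
    genetic covariance Go = Lambda Lambda' + diag(Psi).  ``resid_var_per_env``
    is the spatial residual variance sigma^2_k of each SE; together with
    Go[k,k] it fixes the plot-level heritability Go_kk/(Go_kk + sigma^2_k).
    """

    n_qtl: int = 300
    Lambda_true: np.ndarray = field(default_factory=lambda: np.ones((2, 1)))
    Psi_true: np.ndarray = field(default_factory=lambda: np.zeros(2))
    env_main_var: float = 2.0
    trial_var: float = 0.3
    rep_var: float = 0.2
    block_var: float = 0.3
    spatial_rho_col: float = 0.3
    spatial_rho_row: float = 0.3
    resid_var_per_env: np.ndarray = field(default_factory=lambda: np.ones(2))
    mean: float = 6.0

    def __post_init__(self) -> None:
        self.Lambda_true = np.atleast_2d(np.asarray(self.Lambda_true, dtype=float))
        self.Psi_true = np.asarray(self.Psi_true, dtype=float)
        self.resid_var_per_env = np.asarray(self.resid_var_per_env, dtype=float)

    @property
    def n_envs(self) -> int:
        return self.Lambda_true.shape[0]

    @property
    def Go_true(self) -> np.ndarray:
        return self.Lambda_true @ self.Lambda_true.T + np.diag(self.Psi_true)

    def validate(self) -> None:
        k = self.n_envs
        if self.Psi_true.shape != (k,) or self.resid_var_per_env.shape != (k,):
            raise ValueError("Psi_true and resid_var_per_env must have one entry per environment")
        if np.any(self.Psi_true < 0) or np.any(self.resid_var_per_env < 0):
            raise ValueError("variances must be non-negative")
        for v in ("env_main_var", "trial_var", "rep_var", "block_var"):
            if getattr(self, v) < 0:
                raise ValueError(f"{v} must be non-negative")
        for r in (self.spatial_rho_col, self.spatial_rho_row):
            if not -1 < r < 1:
                raise ValueError("spatial correlations must lie in (-1, 1)")
        if self.n_qtl <= 0:
            raise ValueError("n_qtl must be positive")
        ev = np.linalg.eigvalsh(self.Go_true)
        if ev[0] < -1e-10:
            raise ValueError("target genetic covariance is not positive semi-definite")

    def plot_heritability_true(self, k: int) -> float:
        g = self.Go_true[k, k]
        return g / (g + self.resid_var_per_env[k])


def default_architecture(k: int = 6) -> GeneticArchitecture:
    """Study-like architecture: for six SEs, one low-heritability SE nearly
    uncorrelated with the rest (early-heat-stress pattern) and the others
    with genetic correlations up to ~0.77 and plot heritabilities 0.18-0.6;
    for other k, a generic correlated-SE pattern on the same scale."""
    if k == 6:
        lam = np.array([[0.9], [0.8], [0.85], [0.7], [-0.07], [0.75]])
        h2 = np.array([0.45, 0.50, 0.40, 0.35, 0.18, 0.60])
    else:
        lam = np.linspace(0.85, 0.6, k).reshape(-1, 1)
        h2 = np.linspace(0.25, 0.55, k)
    psi = 1.0 - lam[:, 0] ** 2
    resid = (1.0 - h2) / h2  # Go diagonal is 1.0 by construction
    return GeneticArchitecture(
        Lambda_true=lam, Psi_true=psi, resid_var_per_env=resid
    )


# ---------------------------------------------------------------------------
# Population simulation


def founder_allele_frequencies(spec: PopulationSpec) -> np.ndarray:
    """Base-population allele frequencies of the founder panel (the exact
    frequencies the founder dosages are drawn from, uniform on maf_range)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_markers)


def simulate_founder_genotypes(spec: PopulationSpec) -> GenotypeMatrix:
    """Fully inbred founder panel with per-marker allele frequency drawn
    uniformly from ``maf_range`` (dosages 0/2: inbred lines)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_markers)
    dos = 2.0 * (rng.random((spec.n_founders, spec.n_markers)) < p)
    ids = [f"FND{i + 1:03d}" for i in range(spec.n_founders)]
    return GenotypeMatrix(ids, [f"M{j + 1:05d}" for j in range(spec.n_markers)], dos)


def _meiosis_dosage(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """Transmitted allele count at unlinked loci from one parent dosage row."""
    out = parent / 2.0  # 0 -> 0, 2 -> 1 deterministic
    het = parent == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    return out


def _self_generation(rng: np.random.Generator, dos: np.ndarray) -> np.ndarray:
    """One generation of selfing at unlinked loci (single-seed descent)."""
    out = dos.copy()
    het = dos == 1
    n = int(het.sum())
    draws = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
    out[het] = draws
    return out


def simulate_families(
    founders: GenotypeMatrix, spec: PopulationSpec
) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Biparental crosses with independent-locus Mendelian sampling.

    ``n_crosses`` distinct parent pairs are drawn; each family size is
    uniform on ``family_size_range``.  Progeny are advanced by
    ``n_selfing_generations`` rounds of selfing (genotypes only; the
    pedigree records the cross).
    """
    spec.validate()
    if founders.n_lines < 2:
        raise ValueError("need at least 2 founders to make crosses")
    rng = np.random.default_rng(spec.seed + 1)
    flo, fhi = spec.family_size_range
    dosages: list[np.ndarray] = []
    ids: list[str] = []
    records: list[tuple[str, str | None, str | None]] = []
    for c in range(spec.n_crosses):
        i1, i2 = rng.choice(founders.n_lines, size=2, replace=False)
        fam = int(rng.integers(flo, fhi + 1))
        for j in range(fam):
            d = _meiosis_dosage(rng, founders.dosages[i1]) + _meiosis_dosage(
                rng, founders.dosages[i2]
            )
            for _ in range(spec.n_selfing_generations):
                d = _self_generation(rng, d)
            lid = f"L{c + 1:03d}.{j + 1}"
            ids.append(lid)
            dosages.append(d)
            records.append((lid, founders.line_ids[i1], founders.line_ids[i2]))
    geno = GenotypeMatrix(ids, list(founders.marker_ids), np.vstack(dosages))
    return geno, PedigreeTable(records)


# ---------------------------------------------------------------------------
# Trial layout


def _partition_blocks(n_plots: int, block_size: int) -> list[int]:
    """Split ``n_plots`` consecutive plots into near-equal incomplete blocks."""
    n_blocks = max(1, round(n_plots / block_size))
    base, extra = divmod(n_plots, n_blocks)
    sizes = [base + (1 if i < extra else 0) for i in range(n_blocks)]
    out = []
    for b, s in enumerate(sizes):
        out.extend([b + 1] * s)
    return out


def assign_trial_layout(
    lines: list[str],
    design: TrialDesignSpec,
    seed: int,
    checks: list[str] | None = None,
    year: int = 1,
) -> pd.DataFrame:
    """Allocate lines to trials and field plots in every environment.

    Lines are grouped once into trials (the grouping is shared across
    environments, as when a single stage-2 cohort is carried through all
    SEs); each trial is replicated ``n_replicates`` times on its own
    row x column grid, trials sit side by side along the column axis, and
    each replicate is cut into consecutive incomplete blocks of
    ~``block_size`` plots.  The ``value`` column is left empty.
    """
    design.validate(n_lines=len(lines))
    checks = list(checks) if checks else [f"CHK{i + 1}" for i in range(design.checks_per_trial)]
    if len(checks) != design.checks_per_trial:
        raise ValueError("number of check ids must equal checks_per_trial")
    rng = np.random.default_rng(seed)
    order = list(np.array(lines, dtype=object)[rng.permutation(len(lines))])
    # near-even split of lines over trials
    n_t = design.n_trials_per_env
    base, extra = divmod(len(order), n_t)
    trial_entries: list[list[str]] = []
    pos = 0
    for t in range(n_t):
        size = base + (1 if t < extra else 0)
        if size > design.entries_per_trial:
            raise ValueError("entries_per_trial too small for the line count")
        trial_entries.append(order[pos:pos + size])
        pos += size

    rows_out: list[tuple] = []
    for e in range(design.n_environments):
        env = f"SE{e + 1}"
        for t in range(n_t):
            members = trial_entries[t] + checks
            col_offset = t * design.grid_cols
            cells = [
                (r + 1, col_offset + c + 1)
                for c in range(design.grid_cols)
                for r in range(design.grid_rows)
            ]  # column-major walk through the trial grid
            ci = 0
            for rep in range(1, design.n_replicates + 1):
                perm = rng.permutation(len(members))
                blocks = _partition_blocks(len(members), design.block_size)
                for k, mi in enumerate(perm):
                    r, c = cells[ci]
                    ci += 1
                    rows_out.append(
                        (members[mi], env, year, f"T{t + 1}", rep, blocks[k], r, c, np.nan)
                    )
    return pd.DataFrame(rows_out, columns=PLOT_COLUMNS)


# ---------------------------------------------------------------------------
# Phenotype simulation


def ar1_chol(n: int, rho: float) -> np.ndarray:
    """Cholesky factor of an AR1(rho) correlation matrix (lower)."""
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(n)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def ar1_noise(
    rng: np.random.Generator, n_rows: int, n_cols: int, rho_row: float, rho_col: float
) -> np.ndarray:
    """Unit-variance separable AR1(row) x AR1(col) Gaussian field."""
    z = rng.standard_normal((n_rows, n_cols))
    return ar1_chol(n_rows, rho_row) @ z @ ar1_chol(n_cols, rho_col).T


def _marker_scores(
    rng: np.random.Generator, dosages: np.ndarray, n_qtl: int
) -> np.ndarray:
    """Standardized additive scores from randomly sampled marker effects."""
    n_markers = dosages.shape[1]
    qtl = rng.choice(n_markers, size=min(n_qtl, n_markers), replace=False)
    alpha = rng.standard_normal(len(qtl))
    w = dosages[:, qtl] - dosages[:, qtl].mean(axis=0)
    s = w @ alpha
    sd = s.std()
    if sd < 1e-12:
        raise ValueError("degenerate marker scores (monomorphic QTL sample)")
    return s / sd


def simulate_genetic_values(
    genotypes: GenotypeMatrix,
    arch: GeneticArchitecture,
    seed: int,
    mechanism: str = "marker",
    kinship: KinshipMatrix | None = None,
) -> pd.DataFrame:
    """True line x environment genetic values with covariance
    ``Go = Lambda Lambda' + Psi`` across environments.

    ``mechanism="marker"`` builds each latent factor and each
    environment-specific deviation from ``n_qtl`` sampled marker effects, so
    genomic prediction has a mechanistic target; ``mechanism="mvn"`` draws
    directly from N(0, K x Go) given a kinship matrix (oracle mode).
    """
    arch.validate()
    rng = np.random.default_rng(seed)
    k, m = arch.Lambda_true.shape
    n = genotypes.n_lines
    if mechanism == "marker":
        # successive scores are orthogonalized in-sample (a projection of a
        # marker score is still a marker score), so the realized between-SE
        # covariance of the true values matches Lambda Lambda' + Psi rather
        # than drifting with the family structure of the panel
        n_scores = m + int(np.count_nonzero(arch.Psi_true > 0))
        ortho = n > n_scores + 1
        basis: list[np.ndarray] = []

        def next_score() -> np.ndarray:
            s = _marker_scores(rng, genotypes.dosages, arch.n_qtl)
            if ortho:
                for b in basis:
                    s = s - (s @ b) / (b @ b) * b
                sd = s.std()
                if sd > 1e-12:
                    s = s / sd
            basis.append(s)
            return s

        S = np.column_stack([next_score() for _ in range(m)])
        U = S @ arch.Lambda_true.T
        for e in range(k):
            if arch.Psi_true[e] > 0:
                U[:, e] += math.sqrt(arch.Psi_true[e]) * next_score()
    elif mechanism == "mvn":
        K = kinship if kinship is not None else compute_G(genotypes)
        Lk = np.linalg.cholesky(K.values + 1e-6 * np.eye(n))
        Lg = np.linalg.cholesky(arch.Go_true + 1e-10 * np.eye(k))
        U = Lk @ rng.standard_normal((n, k)) @ Lg.T
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return pd.DataFrame(U, index=genotypes.line_ids, columns=[f"SE{i + 1}" for i in range(k)])


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    layout: pd.DataFrame,
    arch: GeneticArchitecture,
    seed: int,
    mechanism: str = "marker",
    kinship: KinshipMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the ``value`` column of a layout table.

    Returns ``(pheno, true_values)`` where ``true_values`` is the line x SE
    table of simulated genetic effects (the simulation truth used by
    recovery tests).  All lines appearing in the layout must be genotyped.
    """
    arch.validate()
    envs = sorted(layout["env"].unique())
    if len(envs) != arch.n_envs:
        raise ValueError(
            f"architecture has {arch.n_envs} environments but layout has {len(envs)}"
        )
    missing = set(layout["line"]) - set(genotypes.line_ids)
    if missing:
        raise ValueError(f"layout lines without genotypes: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    truth = simulate_genetic_values(
        genotypes, arch, seed=seed + 1, mechanism=mechanism, kinship=kinship
    )
    truth = truth.rename(columns=dict(zip(truth.columns, envs)))

    df = layout.copy()
    env_eff = dict(zip(envs, math.sqrt(arch.env_main_var) * rng.standard_normal(len(envs))))
    value = np.full(len(df), arch.mean)
    value += df["env"].map(env_eff).to_numpy()

    def keyed_effects(cols: list[str], var: float) -> np.ndarray:
        keys = df[cols].apply(tuple, axis=1)
        levels = sorted(keys.unique())
        eff = dict(zip(levels, math.sqrt(var) * rng.standard_normal(len(levels))))
        return keys.map(eff).to_numpy()

    value += keyed_effects(["env", "trial"], arch.trial_var)
    value += keyed_effects(["env", "trial", "rep"], arch.rep_var)
    value += keyed_effects(["env", "trial", "rep", "block"], arch.block_var)

    gi = truth.to_numpy()
    line_pos = {l: i for i, l in enumerate(truth.index)}
    env_pos = {e: j for j, e in enumerate(envs)}
    value += gi[
        df["line"].map(line_pos).to_numpy(), df["env"].map(env_pos).to_numpy()
    ]

    for j, env in enumerate(envs):
        mask = (df["env"] == env).to_numpy()
        rows = df.loc[mask, "row"].to_numpy()
        cols = df.loc[mask, "col"].to_numpy()
        r0, c0 = rows.min(), cols.min()
        field_arr = ar1_noise(
            rng, rows.max() - r0 + 1, cols.max() - c0 + 1,
            arch.spatial_rho_row, arch.spatial_rho_col,
        )
        value[mask] += math.sqrt(arch.resid_var_per_env[j]) * field_arr[rows - r0, cols - c0]

    df["value"] = value
    return df, truth
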