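"""Single- and multi-environment linear mixed models for yield trials.

Three model variants are supported, mirroring the analysis of a staged
yield-testing programme:

* ``eq1_multi_env`` — multi-environment model: fixed replicate, random SE
  main effect, random line-by-SE genetic effect with covariance
  ``(Lambda Lambda' + Psi) (x) K`` (factor-analytic between SEs, genomic or
  pedigree kinship between lines), random trial, replicate-within-SE-trial
  and incomplete-block effects, and per-SE residuals with optional
  AR1(col) (x) AR1(row) spatial correlation.
* ``eq2_multi_env_multi_year`` — the same, for data pooled over years:
  historical SEs enter as distinct correlated environments and the
  replicate/block nesting keys gain the year label.
* ``eq3_single_env`` — single-SE model with a kinship-structured line main
  effect (used for stage-1 analysis and GBLUP-vs-BLUE comparisons).

BLUEs are obtained from the same machinery by switching the line effects
from random to fixed; predictions for untested (line, SE) cells come from
the conditional mean under the fitted covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._reml import (
    REMLEngine,
    REMLOptions,
    _ResidGroup,
    _Term,
    ar1_correlation,
    canonicalize_loadings,
    fa_covariance,
)
from .genotypes import KinshipMatrix

__all__ = [
    "ModelSpec",
    "DesignStructures",
    "VarianceComponents",
    "FitResult",
    "BlueTable",
    "build_design",
    "reml_fit",
    "predict_gblup",
    "compute_blues",
    "plot_heritability",
    "genetic_correlations",
    "ar1_correlation",
    "fa_covariance",
    "REMLOptions",
]

FORMULAS = ("eq1_multi_env", "eq2_multi_env_multi_year", "eq3_single_env")


@dataclass
class ModelSpec:
    """Which model variant to fit and with what genetic covariance."""

    formula_kind: str = "eq1_multi_env"
    fa_order: int = 1
    kinship_kind: str = "genomic"
    spatial: bool = False
    line_effects: str = "random"        # "fixed" gives the BLUE model
    exclude_genetic_lines: tuple = ()   # e.g. checks, modelled iid instead

    def validate(self) -> None:
        if self.formula_kind not in FORMULAS:
            raise ValueError(f"formula_kind must be one of {FORMULAS}")
        if self.fa_order < 1:
            raise ValueError("fa_order must be >= 1")
        if self.line_effects not in ("random", "fixed"):
            raise ValueError("line_effects must be 'random' or 'fixed'")


@dataclass
class DesignStructures:
    """Incidence structures with recorded level orderings.

    Plots are sorted within environment by (column, row) so that each
    environment is a contiguous slice with a well-defined spatial order.
    """

    df: pd.DataFrame
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    term_levels: dict[str, list]           # term name -> ordered level keys
    term_plot_level: dict[str, np.ndarray]
    term_kind: dict[str, str]              # iid | kinship | fa
    envs: list[str]
    env_slices: list[np.ndarray]
    spec: ModelSpec
    genetic_lines: list[str]               # lines entering the genetic term
    cells: list[tuple[str, str]] | None = None  # BLUE model: fixed cells
    rep_levels: list = field(default_factory=list)

    @property
    def n_plots(self) -> int:
        return len(self.y)

    def gxe_cells(self) -> list[tuple[str, str]]:
        """Observed (line, SE) cells entering the genetic interaction term."""
        excl = set(map(str, self.spec.exclude_genetic_lines))
        return sorted(
            set(
                (l, e)
                for l, e in zip(self.df["line"], self.df["env"])
                if l not in excl
            )
        )


@dataclass
class VarianceComponents:
    """Fitted covariance parameters of one model."""

    sigma2: dict[str, float]
    resid: dict[str, float]
    Lambda: np.ndarray | None = None
    Psi: np.ndarray | None = None
    Go: np.ndarray | None = None
    env_order: list[str] = field(default_factory=list)
    spatial_rho: dict[str, tuple[float, float]] = field(default_factory=dict)
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    boundary: tuple = ()
    # mean diagonal of the kinship used at fit time: genetic variances are
    # expressed per unit kinship, so the line-scale variance is Go_kk times
    # this factor (1 for a unit-diagonal kinship; ~1+F for inbred panels)
    kinship_diag_mean: float = 1.0

    def genetic_variance(self, env: str) -> float:
        if self.Go is not None:
            k = self.env_order.index(env)
            return float(self.Go[k, k]) * self.kinship_diag_mean
        return float(self.sigma2.get("genetic", 0.0)) * self.kinship_diag_mean


@dataclass
class FitResult:
    varcomp: VarianceComponents
    gblups: pd.DataFrame               # long: line, env, gblup (all kinship lines)
    fixed_estimates: dict[str, float]
    converged: bool
    n_iter: int
    mme_residual_norm: float

    def gblup_matrix(self) -> pd.DataFrame:
        return self.gblups.pivot(index="line", columns="env", values="gblup")


@dataclass
class BlueTable:
    values: pd.DataFrame               # long: line, env, blue, se
    varcomp: VarianceComponents

    def blue_matrix(self) -> pd.DataFrame:
        return self.values.pivot(index="line", columns="env", values="blue")


# ---------------------------------------------------------------------------
# design construction

_REQUIRED = {
    "eq1_multi_env": {"line": "u2", "env": "u1", "trial": "u3", "rep": "b1", "block": "u5"},
    "eq2_multi_env_multi_year": {
        "line": "u2", "env": "u1", "trial": "u3", "rep": "b1", "block": "u5.1", "year": "u4.1",
    },
    "eq3_single_env": {"line": "u1.1", "trial": "u3", "rep": "b1", "block": "u4.2"},
}


def _keyed(df: pd.DataFrame, cols: list[str]) -> tuple[list, np.ndarray]:
    keys = list(df[cols].itertuples(index=False, name=None))
    levels = sorted(set(keys))
    pos = {k: i for i, k in enumerate(levels)}
    return levels, np.array([pos[k] for k in keys], dtype=int)


def build_design(pheno: pd.DataFrame, spec: ModelSpec) -> DesignStructures:
    """Incidence structures for every model term, with stable lexicographic
    level orderings; plots sorted within environment by (column, row)."""
    spec.validate()
    need = _REQUIRED[spec.formula_kind]
    if "env" not in pheno.columns:
        raise ValueError("phenotype table requires column 'env'")
    for col, term in need.items():
        if col not in pheno.columns:
            raise ValueError(f"term {term} requires column '{col}' in the phenotype table")
    has_grid = {"row", "col"}.issubset(pheno.columns)
    if spec.spatial and not has_grid:
        raise ValueError("spatial residuals require columns 'row' and 'col'")
    envs = sorted(pheno["env"].astype(str).unique())
    if spec.formula_kind == "eq3_single_env" and len(envs) != 1:
        raise ValueError(f"eq3_single_env expects a single environment, found {len(envs)}")
    if spec.formula_kind != "eq3_single_env" and len(envs) < 2:
        raise ValueError(f"{spec.formula_kind} expects at least 2 environments")

    df = pheno.copy()
    df["env"] = df["env"].astype(str)
    df["line"] = df["line"].astype(str)
    sort_cols = ["env", "col", "row"] if has_grid else ["env"]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    if df["value"].isna().any():
        raise ValueError("phenotype values contain missing entries")
    y = df["value"].to_numpy(float)
    env_slices = [np.flatnonzero((df["env"] == e).to_numpy()) for e in envs]

    rep_levels = sorted(df["rep"].unique())
    term_levels: dict[str, list] = {}
    term_plot_level: dict[str, np.ndarray] = {}
    term_kind: dict[str, str] = {}

    def add_iid(name: str, cols: list[str], min_levels: int = 2) -> None:
        levels, plot_level = _keyed(df, cols)
        if len(levels) < min_levels:
            warnings.warn(
                f"dropping term '{name}': fewer than {min_levels} levels",
                UserWarning, stacklevel=3,
            )
            return
        term_levels[name] = levels
        term_plot_level[name] = plot_level
        term_kind[name] = "iid"

    fixed_line = spec.line_effects == "fixed"
    eq = spec.formula_kind
    year_in_keys = eq == "eq2_multi_env_multi_year"
    # in the BLUE model every line (checks included) gets a fixed cell
    excl = set() if fixed_line else set(map(str, spec.exclude_genetic_lines))
    gen_mask = ~df["line"].isin(excl).to_numpy()
    genetic_lines = sorted(df.loc[gen_mask, "line"].unique())

    cells = None
    if eq == "eq3_single_env":
        if fixed_line:
            cells = [(l, envs[0]) for l in genetic_lines]
        else:
            term_levels["genetic"] = genetic_lines
            term_plot_level["genetic"] = np.full(len(df), -1)
            term_kind["genetic"] = "kinship"
        trials = sorted(df["trial"].unique())
        if len(trials) > 1:
            multi_trial_lines = df.groupby("line")["trial"].nunique().gt(1).any()
            if not fixed_line or multi_trial_lines:
                add_iid("trial", ["trial"])
            add_iid("rep_nested", ["trial", "rep"])
        add_iid("block", ["trial", "rep", "block"])
    else:
        if fixed_line:
            cells = sorted(
                set(zip(df.loc[gen_mask, "line"], df.loc[gen_mask, "env"]))
            )
        else:
            add_iid("env", ["env"])
            term_levels["gxe"] = []
            term_plot_level["gxe"] = np.full(len(df), -1)
            term_kind["gxe"] = "fa"
        n_env_trial = len(set(zip(df["env"], df["trial"])))
        if fixed_line:
            keep_trial = (
                df.groupby(["env", "line"])["trial"].nunique().gt(1).any()
            )
        else:
            keep_trial = n_env_trial > len(envs)
            if not keep_trial and n_env_trial >= 2:
                warnings.warn(
                    "dropping term 'trial': one trial per environment "
                    "(incidence identical to the SE main effect)",
                    UserWarning, stacklevel=2,
                )
        if keep_trial and n_env_trial >= 2:
            add_iid("trial", ["env", "trial"])
        rep_cols = ["env", "trial", "rep"] + (["year"] if year_in_keys else [])
        blk_cols = ["env", "trial", "rep", "block"] + (["year"] if year_in_keys else [])
        add_iid("rep_nested", rep_cols)
        add_iid("block", blk_cols)

    if excl and (~gen_mask).any():
        # excluded lines (e.g. checks) get their own iid line effect
        levels = sorted(df.loc[~gen_mask, "line"].unique())
        pos = {k: i for i, k in enumerate(levels)}
        pl = np.array([pos.get(v, -1) for v in df["line"]], dtype=int)
        term_levels["check_line"] = levels
        term_plot_level["check_line"] = pl
        term_kind["check_line"] = "iid"

    # fixed part
    if fixed_line:
        cell_pos = {c: i for i, c in enumerate(cells)}
        Xc = np.zeros((len(df), len(cells)))
        plot_cell = [
            cell_pos.get((l, e), -1) for l, e in zip(df["line"], df["env"])
        ]
        for i, c in enumerate(plot_cell):
            if c >= 0:
                Xc[i, c] = 1.0
        x_names = [f"cell:{l}|{e}" for l, e in cells]
        Xr = np.zeros((len(df), max(len(rep_levels) - 1, 0)))
        for j, r in enumerate(rep_levels[1:]):
            Xr[(df["rep"] == r).to_numpy(), j] = 1.0
        x_names += [f"rep:{r}" for r in rep_levels[1:]]
        X = np.hstack([Xc, Xr])
    else:
        X = np.ones((len(df), 1))
        x_names = ["mu"]
        if len(rep_levels) > 1:
            Xr = np.zeros((len(df), len(rep_levels) - 1))
            for j, r in enumerate(rep_levels[1:]):
                Xr[(df["rep"] == r).to_numpy(), j] = 1.0
            X = np.hstack([X, Xr])
            x_names += [f"rep:{r}" for r in rep_levels[1:]]

    return DesignStructures(
        df=df, y=y, X=X, x_names=x_names,
        term_levels=term_levels, term_plot_level=term_plot_level,
        term_kind=term_kind, envs=envs, env_slices=env_slices, spec=spec,
        genetic_lines=genetic_lines, cells=cells, rep_levels=rep_levels,
    )


# ---------------------------------------------------------------------------
# fitting


def _make_groups(design: DesignStructures) -> list[_ResidGroup]:
    groups = []
    has_grid = {"row", "col"}.issubset(design.df.columns)
    for env, idx in zip(design.envs, design.env_slices):
        sub = design.df.iloc[idx]
        rows = sub["row"].to_numpy(float) if has_grid else np.zeros(len(idx))
        cols = sub["col"].to_numpy(float) if has_grid else np.zeros(len(idx))
        groups.append(_ResidGroup(env=env, idx=idx, rows=rows, cols=cols))
    return groups


def _make_engine(
    design: DesignStructures,
    kinship: KinshipMatrix | None,
    opts: REMLOptions,
) -> tuple[REMLEngine, dict]:
    spec = design.spec
    terms: list[_Term] = []
    fa_dims = None
    K = None
    meta: dict = {}
    if kinship is not None:
        K = kinship.stabilized().values

    for name, kind in design.term_kind.items():
        if kind == "iid":
            levels = design.term_levels[name]
            terms.append(_Term(name, "iid", design.term_plot_level[name],
                               q=len(levels), keys=levels))
        elif kind == "kinship":
            if kinship is None:
                raise ValueError("the genetic term requires a kinship matrix")
            line_idx = {l: i for i, l in enumerate(kinship.line_ids)}
            missing = [l for l in design.genetic_lines if l not in line_idx]
            if missing:
                raise KeyError(f"lines missing from kinship: {missing[:5]}")
            pl = np.array(
                [line_idx.get(l, -1) for l in design.df["line"]], dtype=int
            )
            excl = set(map(str, spec.exclude_genetic_lines))
            pl[design.df["line"].isin(excl).to_numpy()] = -1
            terms.append(_Term(name, "kinship", pl, q=kinship.n_lines,
                               keys=list(kinship.line_ids)))
            meta["genetic_lines_all"] = list(kinship.line_ids)
        else:  # fa
            if kinship is None:
                raise ValueError("the genetic term requires a kinship matrix")
            line_idx = {l: i for i, l in enumerate(kinship.line_ids)}
            missing = [l for l in design.genetic_lines if l not in line_idx]
            if missing:
                raise KeyError(f"lines missing from kinship: {missing[:5]}")
            env_pos = {e: i for i, e in enumerate(design.envs)}
            excl = set(map(str, spec.exclude_genetic_lines))
            obs = sorted(
                set(
                    (l, e)
                    for l, e in zip(design.df["line"], design.df["env"])
                    if l not in excl
                )
            )
            obs_lines = sorted(set(l for l, _ in obs))
            kron = len(obs) == len(obs_lines) * len(design.envs)
            if kron:
                cells = [(l, e) for l in obs_lines for e in design.envs]
            else:
                cells = obs
            cpos = {c: i for i, c in enumerate(cells)}
            pl = np.array(
                [
                    cpos.get((l, e), -1)
                    for l, e in zip(design.df["line"], design.df["env"])
                ],
                dtype=int,
            )
            cell_line = np.array([line_idx[l] for l, _ in cells], dtype=int)
            cell_env = np.array([env_pos[e] for _, e in cells], dtype=int)
            fa_dims = (len(design.envs), min(spec.fa_order, len(design.envs)))
            terms.append(
                _Term(
                    name, "fa", pl, q=len(cells), keys=cells,
                    cell_line=cell_line, cell_env=cell_env, kron=kron,
                    kron_lines=np.array([line_idx[l] for l in obs_lines], dtype=int)
                    if kron else None,
                )
            )
    groups = _make_groups(design)
    engine = REMLEngine(
        y=design.y, X=design.X, terms=terms, groups=groups, K=K,
        fa_dims=fa_dims, spatial=spec.spatial, opts=opts,
    )
    return engine, meta


def reml_fit(
    design: DesignStructures,
    kinship: KinshipMatrix | None,
    opts: REMLOptions | None = None,
    init: dict | None = None,
) -> FitResult:
    """Fit the model by REML and return variance components plus BLUP
    solutions, including predictions for every (kinship line, SE) cell."""
    opts = opts or REMLOptions()
    engine, _ = _make_engine(design, kinship, opts)
    engine.fit(init=init)
    spec = design.spec

    sigma2 = {n: float(v) for n, v in engine.sigma2.items()}
    resid = {e: float(engine.resid[i]) for i, e in enumerate(design.envs)}
    rho = {
        g.env: (float(g.rho[0]), float(g.rho[1]))
        for g in engine.groups
        if spec.spatial
    }
    Lambda = Psi = Go = None
    if engine.fa_term is not None:
        Lambda = canonicalize_loadings(engine.Lambda)
        Psi = engine.Psi.copy()
        Go = engine.Go
    kd = 1.0
    if kinship is not None and ("gxe" in design.term_kind or "genetic" in design.term_kind):
        gl = [l for l in design.genetic_lines if l in set(kinship.line_ids)]
        ix = kinship.index_of(gl) if gl else np.arange(kinship.n_lines)
        kd = float(np.mean(np.diag(kinship.values)[ix]))
    vc = VarianceComponents(
        sigma2=sigma2, resid=resid, Lambda=Lambda, Psi=Psi, Go=Go,
        env_order=list(design.envs), spatial_rho=rho,
        loglik=float(engine.loglik_final()), n_iter=engine.n_iter,
        converged=engine.converged, boundary=tuple(sorted(engine.boundary_terms)),
        kinship_diag_mean=kd,
    )

    rows = []
    if engine.fa_term is not None and kinship is not None:
        U = engine.fa_full_predictions(kinship.n_lines)
        for i, line in enumerate(kinship.line_ids):
            for j, env in enumerate(design.envs):
                rows.append((line, env, float(U[i, j])))
    elif "genetic" in design.term_kind and kinship is not None:
        u = engine.term_solution("genetic")
        env = design.envs[0]
        for line, val in zip(kinship.line_ids, u):
            rows.append((line, env, float(val)))
    gblups = pd.DataFrame(rows, columns=["line", "env", "gblup"])

    fixed = {n: float(v) for n, v in zip(design.x_names, engine.fixed_effects())}
    return FitResult(
        varcomp=vc, gblups=gblups, fixed_estimates=fixed,
        converged=engine.converged, n_iter=engine.n_iter,
        mme_residual_norm=float(engine.mme_residual()),
    )


def predict_gblup(fit: FitResult, line_ids, env_ids) -> pd.DataFrame:
    """Predicted genetic effects for the requested (line, SE) cells."""
    mat = fit.gblup_matrix()
    missing = [l for l in line_ids if l not in mat.index]
    if missing:
        raise KeyError(f"unknown lines: {missing[:5]}")
    missing_env = [e for e in env_ids if e not in mat.columns]
    if missing_env:
        raise KeyError(f"unknown environments: {missing_env}")
    sub = mat.loc[list(line_ids), list(env_ids)]
    return sub.reset_index().melt(
        id_vars="line", var_name="env", value_name="gblup"
    )


def compute_blues(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    opts: REMLOptions | None = None,
) -> BlueTable:
    """Best linear unbiased estimates with line(-by-SE) effects fixed.

    The non-genetic random terms keep the structure of the parent model;
    terms whose incidence lies in the span of the fixed line effects (SE
    main effect, trial when no line repeats over trials) are dropped, as
    their variances are not identifiable from error contrasts.  Estimates
    are reported on the plot scale: cell effect plus the average replicate
    effect, so the mean BLUE matches the overall mean.
    """
    bspec = replace(spec, line_effects="fixed", spatial=spec.spatial)
    design = build_design(pheno, bspec)
    opts = opts or REMLOptions()
    engine, _ = _make_engine(design, None, opts)
    engine.fit()
    beta = engine.fixed_effects()
    cov = engine.fixed_cov()
    n_cells = len(design.cells)
    n_rep = len(design.rep_levels)
    rep_effects = np.concatenate([[0.0], beta[n_cells:]]) if n_rep > 1 else np.zeros(1)
    rep_mean = float(rep_effects.mean())
    rows = []
    for i, (line, env) in enumerate(design.cells):
        rows.append((line, env, float(beta[i] + rep_mean), float(math.sqrt(max(cov[i, i], 0.0)))))
    values = pd.DataFrame(rows, columns=["line", "env", "blue", "se"])
    vc = VarianceComponents(
        sigma2={n: float(v) for n, v in engine.sigma2.items()},
        resid={e: float(engine.resid[i]) for i, e in enumerate(design.envs)},
        env_order=list(design.envs),
        spatial_rho={g.env: g.rho for g in engine.groups} if bspec.spatial else {},
        loglik=float(engine.loglik_final()), n_iter=engine.n_iter,
        converged=engine.converged, boundary=tuple(sorted(engine.boundary_terms)),
    )
    return BlueTable(values=values, varcomp=vc)


# ---------------------------------------------------------------------------
# derived quantities


def plot_heritability(varcomp: VarianceComponents, env: str) -> float:
    """Plot-level heritability h2_k = s2_g(k) / (s2_g(k) + s2_e(k))."""
    if env not in varcomp.resid:
        raise KeyError(f"environment {env!r} was not fitted")
    g = varcomp.genetic_variance(env)
    e = varcomp.resid[env]
    denom = g + e
    if denom <= 0:
        warnings.warn("zero total variance; heritability defined as 0", UserWarning,
                      stacklevel=2)
        return 0.0
    return float(g / denom)


def genetic_correlations(Go: np.ndarray) -> np.ndarray:
    """Between-SE genetic correlation matrix r_ij = Go_ij / sqrt(Go_ii Go_jj)."""
    Go = np.asarray(Go, float)
    d = np.diag(Go)
    if np.any(d <= 0):
        raise ValueError("Go has a non-positive diagonal entry")
    s = np.sqrt(d)
    R = Go / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)
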