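"""Brute-force reference computations used to validate the REML engine.

These implementations build the full dense phenotypic covariance matrix
``V`` and work directly with the error-contrast normal likelihood

    l_R = -1/2 [ (n - p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

optimized by generic derivative-free methods over an unstructured 2x2
genetic covariance.  They are deliberately slow and independent of the
mixed-model-equation path in :mod:`sparsegp._reml`: agreement between the
two maximizations on small instances is a strong end-to-end check of both
the objective and the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import KinshipMatrix
from .me_mixed_model import DesignStructures

__all__ = [
    "make_tiny_multi_env",
    "dense_reml_loglik",
    "maximize_dense_reml_2env",
    "gls_blue",
]


def make_tiny_multi_env(
    seed: int, n_lines: int = 12, n_reps: int = 2
) -> tuple[pd.DataFrame, KinshipMatrix]:
    """Small two-SE dataset with known generating variances.

    Lines share a random positive-definite kinship; two incomplete blocks
    per replicate; genetic covariance Go = [[1, .6], [.6, 1.3]], SE/rep/
    block variances (.5, .3, .2) and residuals (.5, .8).
    """
    rng = np.random.default_rng(seed)
    lines = [f"L{i}" for i in range(n_lines)]
    rows = []
    for e in ("SE1", "SE2"):
        i = 0
        for rep in range(1, n_reps + 1):
            perm = rng.permutation(n_lines)
            for j, li in enumerate(perm):
                block = 1 + j // (n_lines // 2)
                rows.append((lines[li], e, 1, "T1", rep, block, 1, i + 1, np.nan))
                i += 1
    df = pd.DataFrame(
        rows, columns=["line", "env", "year", "trial", "rep", "block", "row", "col", "value"]
    )
    A = rng.standard_normal((n_lines, n_lines))
    K = A @ A.T / n_lines
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    K = 0.5 * K + 0.5 * np.eye(n_lines)
    kin = KinshipMatrix(lines, K, "genomic")

    Go = np.array([[1.0, 0.6], [0.6, 1.3]])
    U = np.linalg.cholesky(K) @ rng.standard_normal((n_lines, 2)) @ np.linalg.cholesky(Go).T
    li = {l: i for i, l in enumerate(lines)}
    em = {"SE1": 0, "SE2": 1}
    v = 5.0 + np.array([U[li[l], em[e]] for l, e in zip(df.line, df.env)])

    def keyed(cols, sd):
        keys = list(df[cols].itertuples(index=False, name=None))
        lv = sorted(set(keys))
        eff = dict(zip(lv, sd * rng.standard_normal(len(lv))))
        return np.array([eff[k] for k in keys])

    v += keyed(["env"], math.sqrt(0.5))
    v += keyed(["env", "trial", "rep"], math.sqrt(0.3))
    v += keyed(["env", "trial", "rep", "block"], math.sqrt(0.2))
    v += np.where(df.env == "SE1", math.sqrt(0.5), math.sqrt(0.8)) * rng.standard_normal(len(df))
    v += 0.3 * (df["rep"] == 2)
    df["value"] = v
    return df, kin


@dataclass
class _DenseParts:
    X: np.ndarray
    y: np.ndarray
    Z: dict[str, np.ndarray]
    Z2: np.ndarray
    Kc: np.ndarray            # kinship restricted to the gxe cells
    cell_env: np.ndarray
    env_of: np.ndarray
    n_envs: int


def _dense_parts(design: DesignStructures, kin: KinshipMatrix) -> _DenseParts:
    d = design.df
    n = len(d)
    Ks = kin.stabilized().values

    def zmat(cols):
        keys = list(d[cols].itertuples(index=False, name=None))
        lv = sorted(set(keys))
        pos = {k: i for i, k in enumerate(lv)}
        Z = np.zeros((n, len(lv)))
        for i, k in enumerate(keys):
            Z[i, pos[k]] = 1.0
        return Z

    Z = {
        "env": zmat(["env"]),
        "rep_nested": zmat(["env", "trial", "rep"]),
        "block": zmat(["env", "trial", "rep", "block"]),
    }
    cells = design.gxe_cells()
    cpos = {c: i for i, c in enumerate(cells)}
    Z2 = np.zeros((n, len(cells)))
    for i, (l, e) in enumerate(zip(d.line, d.env)):
        Z2[i, cpos[(l, e)]] = 1.0
    li = {l: i for i, l in enumerate(kin.line_ids)}
    Kc = np.array([[Ks[li[la], li[lb]] for lb, _ in cells] for la, _ in cells])
    envs = design.envs
    cell_env = np.array([envs.index(e) for _, e in cells])
    env_of = np.array([envs.index(e) for e in d.env])
    return _DenseParts(design.X, design.y, Z, Z2, Kc, cell_env, env_of, len(envs))


def dense_reml_loglik(
    design: DesignStructures,
    kin: KinshipMatrix,
    sigma2: dict[str, float],
    Go: np.ndarray,
    resid: np.ndarray,
) -> float:
    """Error-contrast log-likelihood from the dense covariance matrix."""
    p = _dense_parts(design, kin)
    n = len(p.y)
    V = np.zeros((n, n))
    for name, s2 in sigma2.items():
        V += s2 * p.Z[name] @ p.Z[name].T
    V += p.Z2 @ (p.Kc * np.asarray(Go)[np.ix_(p.cell_env, p.cell_env)]) @ p.Z2.T
    V += np.diag(np.asarray(resid)[p.env_of])
    sign, ld = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XVX = p.X.T @ Vi @ p.X
    s2_, ld2 = np.linalg.slogdet(XVX)
    XVy = p.X.T @ Vi @ p.y
    beta = np.linalg.solve(XVX, XVy)
    yPy = p.y @ Vi @ p.y - XVy @ beta
    return -0.5 * ((n - p.X.shape[1]) * math.log(2 * math.pi) + ld + ld2 + yPy)


def maximize_dense_reml_2env(
    design: DesignStructures, kin: KinshipMatrix, n_starts: int = 4
) -> tuple[float, dict]:
    """Generic-optimizer REML maximization for the two-SE model with an
    unstructured 2x2 genetic covariance (log variances, atanh correlation).
    Multiple Nelder-Mead starts, each refined by Powell."""
    p = _dense_parts(design, kin)
    n = len(p.y)

    def neg_ll(x):
        se, sr, sb = np.exp(x[0]), np.exp(x[1]), np.exp(x[2])
        g11, g22 = np.exp(x[3]), np.exp(x[4])
        r = np.tanh(x[5])
        r1, r2 = np.exp(x[6]), np.exp(x[7])
        Go = np.array(
            [[g11, r * math.sqrt(g11 * g22)], [r * math.sqrt(g11 * g22), g22]]
        )
        V = (
            se * p.Z["env"] @ p.Z["env"].T
            + sr * p.Z["rep_nested"] @ p.Z["rep_nested"].T
            + sb * p.Z["block"] @ p.Z["block"].T
        )
        V += p.Z2 @ (p.Kc * Go[np.ix_(p.cell_env, p.cell_env)]) @ p.Z2.T
        V += np.diag(np.where(p.env_of == 0, r1, r2))
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e10
        Vi = np.linalg.inv(V)
        XVX = p.X.T @ Vi @ p.X
        s2_, ld2 = np.linalg.slogdet(XVX)
        if s2_ <= 0:
            return 1e10
        XVy = p.X.T @ Vi @ p.y
        beta = np.linalg.solve(XVX, XVy)
        yPy = p.y @ Vi @ p.y - XVy @ beta
        return 0.5 * ((n - p.X.shape[1]) * math.log(2 * math.pi) + ld + ld2 + yPy)

    rng = np.random.default_rng(987654321)
    base = np.array([-1.0, -1.0, -1.0, 0.0, 0.0, 0.5, -0.5, -0.5])
    starts = [base] + [base + rng.normal(0, 0.7, 8) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-10, "fatol": 1e-12},
        )
        res = optimize.minimize(
            neg_ll, res.x, method="Powell",
            options={"maxiter": 4000, "xtol": 1e-10, "ftol": 1e-13},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    g11, g22, r = np.exp(x[3]), np.exp(x[4]), np.tanh(x[5])
    Go = np.array([[g11, r * math.sqrt(g11 * g22)], [r * math.sqrt(g11 * g22), g22]])
    pars = {
        "env": float(np.exp(x[0])),
        "rep_nested": float(np.exp(x[1])),
        "block": float(np.exp(x[2])),
        "Go": Go,
        "resid": np.array([np.exp(x[6]), np.exp(x[7])]),
    }
    return -float(best.fun), pars


def gls_blue(
    y: np.ndarray, X: np.ndarray, Zb: np.ndarray, s2_block: float, s2_resid: float
) -> np.ndarray:
    """Direct generalized-least-squares solution beta = (X'V^-1X)^-1 X'V^-1 y
    for a one-random-term model (reference for the BLUE computation)."""
    V = s2_block * Zb @ Zb.T + s2_resid * np.eye(len(y))
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
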