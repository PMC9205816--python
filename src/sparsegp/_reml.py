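"""Dense REML engine for the multi-environment mixed models.

The engine maximizes the restricted likelihood of

    y = X b + sum_t Z_t u_t + e

where each random term is one of

* ``iid``      u ~ N(0, sigma2 I)                (design terms),
* ``kinship``  u ~ N(0, sigma2 K)                (single-SE genetic effect),
* ``fa``       u ~ N(0, (K (x) Go)[cells])       (line-by-SE genetic effect,
               Go = Lambda Lambda' + diag(Psi), restricted to the observed
               (line, SE) cells),

and the residual is independent between SEs with per-SE variance and an
optional separable AR1(col) (x) AR1(row) correlation over the field grid.

Strategy: a few EM-REML iterations for stability, then average-information
(AI) Newton steps on transformed parameters (log variances, raw loadings)
with step halving against the restricted likelihood, optional profiling of
the spatial correlations on a grid plus golden-section refinement, and a
derivative-free polish on small problems.  All solves go through a single
Cholesky factorization of the mixed-model-equation (MME) matrix per
evaluation; the identity

    -2 l_R = (n - p) log 2pi + log|R| + log|Sigma| + log|C| + y' P y

ties the engine's objective to the error-contrast normal likelihood, which
the test suite checks against a direct dense-covariance evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

__all__ = [
    "REMLOptions",
    "REMLEngine",
    "fit_fa_structure",
    "canonicalize_loadings",
    "ar1_correlation",
    "fa_covariance",
]

_LOG2PI = math.log(2.0 * math.pi)


def _gather(vec: np.ndarray, plot_col: np.ndarray) -> np.ndarray:
    """vec[plot_col] with zero for plots that have no incidence (-1)."""
    out = vec[np.clip(plot_col, 0, None)]
    out[plot_col < 0] = 0.0
    return out


@dataclass
class REMLOptions:
    max_iter: int = 200
    tol: float = 1e-6
    em_iters: int = 3
    use_ai: bool = True
    polish: str | bool = "auto"  # True / False / "auto" (small problems only)
    polish_max_dim: int = 100
    rho_every: int = 4
    ridge: float = 1e-8
    max_step: float = 1.5
    variance_floor_rel: float = 1e-10
    psi_floor_rel: float = 1e-8
    estimate: bool = True
    track: bool = False
    seed_for_init: int = 0


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix, entry (i, j) = rho^|i-j| (positive definite)."""
    if not -1 < rho < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(int(n))
    return rho ** np.abs(idx[:, None] - idx[None, :])


def fa_covariance(Lambda: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    """Factor-analytic covariance Go = Lambda Lambda' + diag(Psi)."""
    Lambda = np.atleast_2d(np.asarray(Lambda, float))
    Psi = np.asarray(Psi, float)
    if Psi.ndim != 1 or Psi.shape[0] != Lambda.shape[0]:
        raise ValueError("Psi must be a vector with one entry per environment")
    if np.any(Psi < 0):
        raise ValueError("specific variances must be non-negative")
    return Lambda @ Lambda.T + np.diag(Psi)


def canonicalize_loadings(Lambda: np.ndarray) -> np.ndarray:
    """Rotate/reflect loadings to the identified form: zero upper triangle,
    leading nonzero loading of each factor positive."""
    L = np.atleast_2d(np.array(Lambda, float))
    k, m = L.shape
    if m > 1:
        from scipy.linalg import qr

        q, _ = qr(L[:m, :].T)
        L = L @ q
        for i in range(m):
            L[i, i + 1:] = 0.0
    for j in range(m):
        nz = np.nonzero(np.abs(L[:, j]) > 1e-12)[0]
        if nz.size and L[nz[0], j] < 0:
            L[:, j] = -L[:, j]
    return L


def fit_fa_structure(
    S: np.ndarray,
    m: int,
    Lambda0: np.ndarray | None = None,
    Psi0: np.ndarray | None = None,
    psi_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood factor-analytic fit to a covariance matrix.

    Minimizes log|Go| + tr(Go^-1 S) over Go = Lambda Lambda' + diag(Psi)
    with an analytic gradient; used as the M-step of the EM iteration for
    the genotype-by-environment covariance.
    """
    S = np.asarray(S, float)
    k = S.shape[0]
    scale = max(float(np.trace(S)) / k, psi_floor)
    if Lambda0 is None:
        ev, evec = np.linalg.eigh(S)
        Lambda0 = evec[:, -m:][:, ::-1] * np.sqrt(np.maximum(ev[-m:][::-1], 0.1 * scale))
    if Psi0 is None:
        Psi0 = np.maximum(np.diag(S) - np.sum(np.atleast_2d(Lambda0) ** 2, axis=1), 0.1 * scale)
    lo = math.log(max(psi_floor, 1e-12 * scale))

    def unpack(x):
        lam = x[: k * m].reshape(k, m)
        psi = np.exp(np.clip(x[k * m:], lo, 50.0))
        return lam, psi

    def fun(x):
        lam, psi = unpack(x)
        Go = lam @ lam.T + np.diag(psi)
        try:
            c = np.linalg.cholesky(Go)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Goinv = cho_solve((c, True), np.eye(k))
        f = logdet + float(np.sum(Goinv * S))
        Gdiff = Goinv - Goinv @ S @ Goinv
        glam = 2.0 * Gdiff @ lam
        gpsi = np.diag(Gdiff) * psi
        return f, np.concatenate([glam.ravel(), gpsi])

    x0 = np.concatenate([
        np.atleast_2d(np.asarray(Lambda0, float)).ravel(),
        np.log(np.maximum(np.asarray(Psi0, float), psi_floor)),
    ])
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam, psi = unpack(res.x)
    return lam, psi


# ---------------------------------------------------------------------------


@dataclass
class _Term:
    """One random term as seen by the engine."""

    name: str
    kind: str                      # iid | kinship | fa
    plot_col: np.ndarray           # plot -> local column index
    q: int
    keys: list = field(default_factory=list)
    # fa bookkeeping (cell c corresponds to local column c)
    cell_line: np.ndarray | None = None   # cell -> kinship line index
    cell_env: np.ndarray | None = None    # cell -> env index
    kron: bool = False
    kron_lines: np.ndarray | None = None  # kinship line indices, kron row order
    offset: int = 0                # column offset inside W


@dataclass
class _ResidGroup:
    env: str
    idx: np.ndarray                # plot indices (contiguous slice)
    rows: np.ndarray
    cols: np.ndarray
    omega_inv: np.ndarray | None = None   # None means identity correlation
    logdet_omega: float = 0.0
    rho: tuple[float, float] = (0.0, 0.0)  # (rho_col, rho_row)

    def correlation(self) -> np.ndarray:
        rc, rr = self.rho
        return (rc ** np.abs(self.cols[:, None] - self.cols[None, :])) * (
            rr ** np.abs(self.rows[:, None] - self.rows[None, :])
        )


class REMLEngine:
    """Stateful fitter; one instance per model fit."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        terms: list[_Term],
        groups: list[_ResidGroup],
        K: np.ndarray | None,
        fa_dims: tuple[int, int] | None,
        spatial: bool,
        opts: REMLOptions,
    ) -> None:
        self.y = np.asarray(y, float)
        self.n = len(self.y)
        self.X = np.asarray(X, float).reshape(self.n, -1)
        self.p = self.X.shape[1]
        self.terms = terms
        self.groups = groups
        self.spatial = spatial
        self.opts = opts
        self.trace: list[float] = []
        self.boundary_terms: set[str] = set()
        self.converged = False
        self.n_iter = 0

        off = self.p
        for t in terms:
            t.offset = off
            off += t.q
        self.dim = off
        self.q_total = off - self.p

        self.K = K
        if K is not None:
            c = np.linalg.cholesky(K)
            self.K_logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            self.K_inv = cho_solve((c, True), np.eye(K.shape[0]))
        self.fa_dims = fa_dims
        self.fa_term = next((t for t in terms if t.kind == "fa"), None)
        if self.fa_term is not None:
            if self.fa_term.kron:
                ix = self.fa_term.kron_lines
                self.Ksub = K[np.ix_(ix, ix)]
                c = np.linalg.cholesky(self.Ksub)
                self.Ksub_logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
                self.Ksub_inv = cho_solve((c, True), np.eye(len(ix)))
            else:
                cl = self.fa_term.cell_line
                self.Kcells = K[np.ix_(cl, cl)]

        W = np.zeros((self.n, self.dim))
        W[:, : self.p] = self.X
        rows = np.arange(self.n)
        for t in terms:
            mask = t.plot_col >= 0  # plots without incidence in this term
            W[rows[mask], t.offset + t.plot_col[mask]] = 1.0
        self.W = W

        self._grams_dirty = True
        self._grams: list[np.ndarray] = []
        self._wr: list[np.ndarray] = []
        self._ss: list[float] = []
        self._cached_ll: float | None = None

        self.sigma2: dict[str, float] = {}
        self.resid: np.ndarray = np.ones(len(groups))
        self.Lambda: np.ndarray | None = None
        self.Psi: np.ndarray | None = None

        vy = float(np.var(self.y)) if self.n > 1 else 1.0
        self.vy = max(vy, 1e-12)
        self.var_floor = opts.variance_floor_rel * self.vy
        self.psi_floor = opts.psi_floor_rel * self.vy

    # -- parameters -----------------------------------------------------------

    def init_params(self, init: dict | None = None) -> None:
        init = init or {}
        for t in self.terms:
            if t.kind == "fa":
                continue
            default = 0.3 * self.vy if t.kind == "kinship" else 0.05 * self.vy
            self.sigma2[t.name] = float(init.get("sigma2", {}).get(t.name, default))
        self.resid = np.asarray(
            init.get("resid", np.full(len(self.groups), 0.5 * self.vy)), float
        ).copy()
        if self.fa_term is not None:
            k, m = self.fa_dims
            if "Lambda" in init:
                self.Lambda = np.atleast_2d(np.asarray(init["Lambda"], float)).copy()
                self.Psi = np.asarray(init["Psi"], float).copy()
            else:
                lam = np.full((k, m), 0.05 * math.sqrt(self.vy))
                lam[:, 0] = math.sqrt(0.2 * self.vy)
                self.Lambda = lam
                self.Psi = np.full(k, 0.1 * self.vy)
            self.Psi = np.maximum(self.Psi, self.psi_floor)
        if self.spatial:
            for g, r in zip(self.groups, init.get("rho", [g.rho for g in self.groups])):
                g.rho = tuple(r)
                self._set_group_omega(g)

    @property
    def Go(self) -> np.ndarray | None:
        if self.fa_term is None:
            return None
        return self.Lambda @ self.Lambda.T + np.diag(self.Psi)

    # -- residual correlation ---------------------------------------------------

    def _set_group_omega(self, g: _ResidGroup) -> None:
        rc, rr = g.rho
        if abs(rc) < 1e-12 and abs(rr) < 1e-12:
            g.omega_inv, g.logdet_omega = None, 0.0
        else:
            corr = g.correlation()
            c = np.linalg.cholesky(corr)
            g.logdet_omega = 2.0 * float(np.sum(np.log(np.diag(c))))
            g.omega_inv = cho_solve((c, True), np.eye(len(g.idx)))
        self._grams_dirty = True

    # -- building blocks ----------------------------------------------------------

    def _compute_grams(self) -> None:
        self._grams, self._wr, self._ss = [], [], []
        for g in self.groups:
            Wg = self.W[g.idx]
            yg = self.y[g.idx]
            if g.omega_inv is None:
                self._grams.append(Wg.T @ Wg)
                self._wr.append(Wg.T @ yg)
                self._ss.append(float(yg @ yg))
            else:
                OWg = g.omega_inv @ Wg
                self._grams.append(Wg.T @ OWg)
                self._wr.append(OWg.T @ yg)
                self._ss.append(float(yg @ (g.omega_inv @ yg)))
        self._grams_dirty = False

    def _sigma_inv_and_logdet(self):
        blocks = []
        logdet = 0.0
        extras: dict = {}
        for t in self.terms:
            sl = slice(t.offset, t.offset + t.q)
            if t.kind == "iid":
                s2 = self.sigma2[t.name]
                blocks.append((sl, 1.0 / s2))
                logdet += t.q * math.log(s2)
            elif t.kind == "kinship":
                s2 = self.sigma2[t.name]
                blocks.append((sl, self.K_inv / s2))
                logdet += t.q * math.log(s2) + self.K_logdet
            else:  # fa
                k, m = self.fa_dims
                Go = self.Go
                cg = np.linalg.cholesky(Go)
                Go_logdet = 2.0 * float(np.sum(np.log(np.diag(cg))))
                Go_inv = cho_solve((cg, True), np.eye(k))
                extras["Go_inv"] = Go_inv
                if t.kron:
                    nl = len(t.kron_lines)
                    Sinv = (
                        self.Ksub_inv[:, None, :, None] * Go_inv[None, :, None, :]
                    ).reshape(t.q, t.q)
                    logdet += k * self.Ksub_logdet + nl * Go_logdet
                else:
                    Sig = self.Kcells * Go[np.ix_(t.cell_env, t.cell_env)]
                    c = cho_factor(Sig, lower=True)
                    logdet += 2.0 * float(np.sum(np.log(np.diag(c[0]))))
                    Sinv, _ = dpotri(c[0], lower=1)
                    Sinv = np.tril(Sinv) + np.tril(Sinv, -1).T
                extras["Sigma_inv"] = Sinv
                blocks.append((sl, Sinv))
        return blocks, logdet, extras

    def _assemble(self, want_inverse: bool = False):
        if self._grams_dirty:
            self._compute_grams()
        C = np.zeros((self.dim, self.dim))
        rhs = np.zeros(self.dim)
        s_tot = 0.0
        logdet_R = 0.0
        for i, g in enumerate(self.groups):
            s2 = self.resid[i]
            C += self._grams[i] / s2
            rhs += self._wr[i] / s2
            s_tot += self._ss[i] / s2
            logdet_R += len(g.idx) * math.log(s2) + g.logdet_omega
        blocks, logdet_S, extras = self._sigma_inv_and_logdet()
        for sl, b in blocks:
            if np.isscalar(b):
                idx = np.arange(sl.start, sl.stop)
                C[idx, idx] += b
            else:
                C[sl, sl] += b
        try:
            cfac = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cfac[0]))))
        a = cho_solve(cfac, rhs)
        yPy = s_tot - float(a @ rhs)
        ll = -0.5 * ((self.n - self.p) * _LOG2PI + logdet_R + logdet_S + logdet_C + yPy)
        state = {"C": C, "cfac": cfac, "a": a, "ll": ll, "rhs": rhs,
                 "extras": extras, "yPy": yPy}
        if want_inverse:
            inv, _ = dpotri(cfac[0], lower=1)
            state["Cinv"] = np.tril(inv) + np.tril(inv, -1).T
        self._cached_ll = ll
        return state

    def loglik(self) -> float:
        st = self._assemble()
        return -np.inf if st is None else st["ll"]

    # -- EM ------------------------------------------------------------------------

    def _em_step(self, st) -> None:
        Cinv = st["Cinv"]
        a = st["a"]
        for t in self.terms:
            sl = slice(t.offset, t.offset + t.q)
            u = a[sl]
            if t.name in self.boundary_terms:
                continue
            if t.kind == "iid":
                s2 = (float(u @ u) + float(np.trace(Cinv[sl, sl]))) / t.q
                self.sigma2[t.name] = max(s2, self.var_floor)
            elif t.kind == "kinship":
                s2 = (
                    float(u @ self.K_inv @ u) + float(np.sum(self.K_inv * Cinv[sl, sl]))
                ) / t.q
                self.sigma2[t.name] = max(s2, self.var_floor)
            elif t.kind == "fa" and t.kron:
                k, m = self.fa_dims
                nl = len(t.kron_lines)
                U = u.reshape(nl, k)
                R4 = Cinv[sl, sl].reshape(nl, k, nl, k)
                T = np.einsum("ij,iajb->ab", self.Ksub_inv, R4, optimize=True)
                S = U.T @ self.Ksub_inv @ U + T
                lam, psi = fit_fa_structure(S / nl, m, self.Lambda, self.Psi, self.psi_floor)
                self.Lambda, self.Psi = lam, np.maximum(psi, self.psi_floor)
        e = self.y - self.W @ a
        for i, g in enumerate(self.groups):
            eg = e[g.idx]
            quad = float(eg @ eg) if g.omega_inv is None else float(eg @ g.omega_inv @ eg)
            tr = float(np.sum(Cinv * self._grams[i]))
            self.resid[i] = max((quad + tr) / len(g.idx), self.var_floor)

    # -- AI ---------------------------------------------------------------------------

    def _param_vector(self):
        names, vals = [], []
        for t in self.terms:
            if t.kind == "fa" or t.name in self.boundary_terms:
                continue
            names.append(("sigma2", t.name))
            vals.append(math.log(self.sigma2[t.name]))
        if self.fa_term is not None:
            k, m = self.fa_dims
            for j in range(m):
                for i in range(j, k):
                    names.append(("lam", (i, j)))
                    vals.append(self.Lambda[i, j])
            for i in range(k):
                names.append(("psi", i))
                vals.append(math.log(max(self.Psi[i], self.psi_floor)))
        for i in range(len(self.groups)):
            names.append(("resid", i))
            vals.append(math.log(self.resid[i]))
        return names, np.array(vals)

    def _set_params(self, names, vals) -> None:
        for (kind, key), v in zip(names, vals):
            if kind == "sigma2":
                self.sigma2[key] = max(math.exp(min(v, 50.0)), self.var_floor)
            elif kind == "lam":
                self.Lambda[key] = v
            elif kind == "psi":
                self.Psi[key] = max(math.exp(min(v, 50.0)), self.psi_floor)
            elif kind == "resid":
                self.resid[key] = max(math.exp(min(v, 50.0)), self.var_floor)

    def _fa_dots(self) -> dict:
        """d Go / d theta on the transformed scale, keyed like _param_vector."""
        k, m = self.fa_dims
        dots = {}
        for j in range(m):
            for i in range(j, k):
                D = np.zeros((k, k))
                D[i, :] += self.Lambda[:, j]
                D[:, i] += self.Lambda[:, j]
                dots[("lam", (i, j))] = D
        for i in range(k):
            D = np.zeros((k, k))
            D[i, i] = self.Psi[i]  # includes d psi / d log psi
            dots[("psi", i)] = D
        return dots

    def _ai_step(self, st) -> bool:
        names, theta = self._param_vector()
        npar = len(names)
        if npar == 0:
            return True
        Cinv = st["Cinv"]
        a = st["a"]
        e = self.y - self.W @ a
        r = np.empty(self.n)
        for i, g in enumerate(self.groups):
            if g.omega_inv is None:
                r[g.idx] = e[g.idx] / self.resid[i]
            else:
                r[g.idx] = (g.omega_inv @ e[g.idx]) / self.resid[i]
        wr = self.W.T @ r

        fa = self.fa_term
        if fa is not None:
            dots = self._fa_dots()
            slf = slice(fa.offset, fa.offset + fa.q)
            Go_inv = st["extras"]["Go_inv"]
            t2 = wr[slf]
            k, m = self.fa_dims
            if fa.kron:
                nl = len(fa.kron_lines)
                R4 = Cinv[slf, slf].reshape(nl, k, nl, k)
                Dmat = np.einsum("iajb,ij->ab", R4, self.Ksub_inv, optimize=True)
                Tm = t2.reshape(nl, k)
                Q = Tm.T @ (self.Ksub @ Tm)
            else:
                Sinv = st["extras"]["Sigma_inv"]
                B = Sinv @ Cinv[slf, slf] @ Sinv
                E = np.zeros((fa.q, k))
                E[np.arange(fa.q), fa.cell_env] = 1.0
                M1 = E.T @ (self.Kcells * Sinv) @ E
                M2 = E.T @ (self.Kcells * B) @ E
                Q = E.T @ (self.Kcells * np.outer(t2, t2)) @ E

        grad = np.zeros(npar)
        F = np.zeros((self.n, npar))
        for pi, (kind, key) in enumerate(names):
            if kind == "sigma2":
                t = next(t for t in self.terms if t.name == key)
                sl = slice(t.offset, t.offset + t.q)
                s2 = self.sigma2[key]
                zr = wr[sl]
                if t.kind == "iid":
                    trPV = (t.q - float(np.trace(Cinv[sl, sl])) / s2) / s2
                    quad = float(zr @ zr)
                    fvec = _gather(zr, t.plot_col)
                else:  # kinship
                    trPV = (t.q - float(np.sum(self.K_inv * Cinv[sl, sl])) / s2) / s2
                    Kzr = self.K @ zr
                    quad = float(zr @ Kzr)
                    fvec = _gather(Kzr, t.plot_col)
                grad[pi] = -0.5 * (trPV - quad) * s2  # d l / d log sigma2
                F[:, pi] = fvec * s2
            elif kind in ("lam", "psi"):
                Dm = dots[(kind, key)]
                if fa.kron:
                    GD = Go_inv @ Dm @ Go_inv
                    trPV = nl * float(np.sum(Go_inv * Dm)) - float(np.sum(Dmat * GD))
                    quad = float(np.sum(Q * Dm))
                    svec = self.Ksub @ (Tm @ Dm)
                    fvec = _gather(svec.reshape(-1), fa.plot_col)
                else:
                    trPV = float(np.sum(M1 * Dm)) - float(np.sum(M2 * Dm))
                    quad = float(np.sum(Q * Dm))
                    Sdot = self.Kcells * Dm[np.ix_(fa.cell_env, fa.cell_env)]
                    fvec = _gather(Sdot @ t2, fa.plot_col)
                grad[pi] = -0.5 * (trPV - quad)
                F[:, pi] = fvec
            else:  # resid
                i = key
                g = self.groups[i]
                s2 = self.resid[i]
                trPV = len(g.idx) / s2 - float(np.sum(Cinv * self._grams[i])) / s2**2
                rg = r[g.idx]
                if g.omega_inv is None:
                    fg = rg
                else:
                    fg = g.correlation() @ rg
                quad = float(rg @ fg)
                grad[pi] = -0.5 * (trPV - quad) * s2
                F[g.idx, pi] = fg * s2

        RF = np.empty_like(F)
        for i, g in enumerate(self.groups):
            if g.omega_inv is None:
                RF[g.idx] = F[g.idx] / self.resid[i]
            else:
                RF[g.idx] = (g.omega_inv @ F[g.idx]) / self.resid[i]
        sol = cho_solve(st["cfac"], self.W.T @ RF)
        WS = self.W @ sol
        PF = RF.copy()
        for i, g in enumerate(self.groups):
            if g.omega_inv is None:
                PF[g.idx] -= WS[g.idx] / self.resid[i]
            else:
                PF[g.idx] -= (g.omega_inv @ WS[g.idx]) / self.resid[i]
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)

        ridge = self.opts.ridge * (1.0 + abs(float(np.trace(AI))) / max(npar, 1))
        step = None
        for _ in range(8):
            try:
                step = np.linalg.solve(AI + ridge * np.eye(npar), grad)
                break
            except np.linalg.LinAlgError:
                ridge *= 10.0
        if step is None:
            return False
        step = np.clip(step, -self.opts.max_step, self.opts.max_step)

        ll0 = st["ll"]
        state0 = self._snapshot()
        frac = 1.0
        for _ in range(10):
            self._set_params(names, theta + frac * step)
            if self.loglik() > ll0 - 1e-10:
                return True
            frac *= 0.5
        self._restore(state0)
        return False

    def _snapshot(self):
        return (
            dict(self.sigma2),
            self.resid.copy(),
            None if self.Lambda is None else self.Lambda.copy(),
            None if self.Psi is None else self.Psi.copy(),
        )

    def _restore(self, snap) -> None:
        self.sigma2, self.resid = dict(snap[0]), snap[1].copy()
        self.Lambda = None if snap[2] is None else snap[2].copy()
        self.Psi = None if snap[3] is None else snap[3].copy()
        self._cached_ll = None

    # -- spatial profiling ---------------------------------------------------------

    def _profile_rho(self) -> None:
        """Grid search plus golden-section refinement of (rho_col, rho_row)
        per environment, holding variance parameters fixed."""
        gold = (math.sqrt(5.0) - 1.0) / 2.0
        for g in self.groups:
            for axis in (0, 1):

                def ll_at(rv: float) -> float:
                    rho = list(g.rho)
                    rho[axis] = rv
                    g.rho = tuple(rho)
                    self._set_group_omega(g)
                    return self.loglik()

                grid = np.arange(-0.9, 0.91, 0.1)
                vals = [ll_at(rv) for rv in grid]
                ibest = int(np.argmax(vals))
                a_ = grid[max(ibest - 1, 0)]
                b_ = grid[min(ibest + 1, len(grid) - 1)]
                c_ = b_ - gold * (b_ - a_)
                d_ = a_ + gold * (b_ - a_)
                fc, fd = ll_at(c_), ll_at(d_)
                for _ in range(15):
                    if fc >= fd:
                        b_, d_, fd = d_, c_, fc
                        c_ = b_ - gold * (b_ - a_)
                        fc = ll_at(c_)
                    else:
                        a_, c_, fc = c_, d_, fd
                        d_ = a_ + gold * (b_ - a_)
                        fd = ll_at(d_)
                ll_at(c_ if fc >= fd else d_)

    # -- main loop --------------------------------------------------------------------

    def fit(self, init: dict | None = None) -> None:
        self.init_params(init)
        if not self.opts.estimate:
            self.final = self._assemble(want_inverse=True)
            if self.final is None:
                raise np.linalg.LinAlgError("mixed-model equations not positive definite")
            self.converged = True
            return
        ll_old = -np.inf
        _, theta_old = self._param_vector()
        dll = np.inf
        if self.spatial:
            self._profile_rho()
        for it in range(1, self.opts.max_iter + 1):
            self.n_iter = it
            st = self._assemble(want_inverse=True)
            if st is None:
                raise np.linalg.LinAlgError("mixed-model equations not positive definite")
            if self.opts.track:
                self.trace.append(st["ll"])
            use_ai = self.opts.use_ai and it > self.opts.em_iters
            if use_ai:
                if not self._ai_step(st):
                    self._em_step(st)
                    self._cached_ll = None
            else:
                self._em_step(st)
                self._cached_ll = None
            if self.spatial and it % self.opts.rho_every == 0:
                self._profile_rho()
            self._flag_boundaries()
            ll_new = self._cached_ll if self._cached_ll is not None else self.loglik()
            names, theta_new = self._param_vector()
            dll = abs(ll_new - ll_old) / (1.0 + abs(ll_new))
            dth = (
                float(np.max(np.abs(theta_new - theta_old)))
                if len(theta_new) == len(theta_old) and len(theta_new)
                else 0.0
            )
            ll_old, theta_old = ll_new, theta_new
            if it > self.opts.em_iters and dll < self.opts.tol and dth < 100 * self.opts.tol:
                self.converged = True
                break
        if not self.converged:
            warnings.warn(
                f"REML did not converge in {self.opts.max_iter} iterations "
                f"(last relative log-likelihood change {dll:.2e})",
                UserWarning,
                stacklevel=2,
            )
        if self.opts.polish is True or (
            self.opts.polish == "auto" and self.dim <= self.opts.polish_max_dim
        ):
            self._polish()
        self.final = self._assemble(want_inverse=True)

    def _flag_boundaries(self) -> None:
        # pin variances that collapsed toward the floor: the likelihood is
        # flat there and log-scale wandering would stall the convergence test
        for t in self.terms:
            if t.kind == "fa":
                continue
            if self.sigma2[t.name] <= 100.0 * self.var_floor:
                self.boundary_terms.add(t.name)
                self.sigma2[t.name] = self.var_floor

    def _polish(self) -> None:
        """Derivative-free refinement of all free parameters (small problems)."""
        names, theta0 = self._param_vector()
        if not len(names):
            return

        def neg_ll(x):
            self._set_params(names, x)
            return -self.loglik()

        f0 = neg_ll(theta0)
        res = optimize.minimize(
            neg_ll, theta0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        x_best, f_best = (res.x, res.fun) if res.fun < f0 else (theta0, f0)
        res2 = optimize.minimize(
            neg_ll, x_best, method="Powell",
            options={"maxiter": 2000, "xtol": 1e-10, "ftol": 1e-13},
        )
        if res2.fun < f_best:
            x_best = res2.x
        self._set_params(names, x_best)
        self.converged = True

    # -- post-fit accessors ---------------------------------------------------------

    def solutions(self) -> np.ndarray:
        return self.final["a"]

    def loglik_final(self) -> float:
        return self.final["ll"]

    def mme_residual(self) -> float:
        st = self.final
        resid = st["C"] @ st["a"] - st["rhs"]
        denom = float(np.linalg.norm(st["rhs"])) or 1.0
        return float(np.linalg.norm(resid)) / denom

    def fixed_effects(self) -> np.ndarray:
        return self.final["a"][: self.p]

    def fixed_cov(self) -> np.ndarray:
        return self.final["Cinv"][: self.p, : self.p]

    def term_solution(self, name: str) -> np.ndarray:
        t = next(t for t in self.terms if t.name == name)
        return self.final["a"][t.offset: t.offset + t.q]

    def fa_full_predictions(self, n_kin: int) -> np.ndarray:
        """Conditional-mean extension of the genetic effects to every
        (kinship line, environment) pair:
        u_all = Cov(all, obs) Sigma_obs^-1 u_obs."""
        fa = self.fa_term
        k, _ = self.fa_dims
        u = self.term_solution(fa.name)
        Sinv = self.final["extras"]["Sigma_inv"]
        V = Sinv @ u
        H = np.zeros((n_kin, k))
        if fa.kron:
            Vm = V.reshape(len(fa.kron_lines), k)
            np.add.at(H, fa.kron_lines, Vm)
        else:
            np.add.at(H, (fa.cell_line, fa.cell_env), V)
        return self.K @ H @ self.Go
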