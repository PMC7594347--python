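"""Trivariate lab-as-trait REML for between-laboratory genetic correlations.

The same ultrasound trait interpreted by each of the three imaging
laboratories is treated as a distinct trait.  Stacked model:

    [y1; y2; y3] = [1 mu1; 1 mu2; 1 mu3] + Z_t t + Z_c c + Z_u u + e

Technician, contemporary-group and residual (co)variance blocks are
diagonal across laboratories (no technician, CG or animal record spans
labs), while the additive-genetic block is A (x) G0 with G0 the 3x3
genetic covariance among the lab-traits.  G0 is parameterized by its
Cholesky factor so it stays positive semidefinite throughout the simplex
search, which uses the same convergence rule as the univariate fits.
Genetic correlations are read off G0; each is tested against 1 with a
z-test whose standard error comes from the accuracy-based formula in
:mod:`ultravar.stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._optim import nelder_mead_restarted
from .pedigree import Pedigree, build_A_inverse
from .phenotypes import StudyDataset
from .reml import (
    FitOptions,
    InvalidComponentsError,
    UnivariateFit,
    VarianceComponents,
    _factor,
    _logdet_from_lu,
)

Z_CRIT_95 = 1.959964  # two-sided 5% normal quantile


@dataclass
class MultiTraitComponents:
    """Per-lab nuisance variances plus the 3x3 genetic covariance G0."""

    sigma2_t: np.ndarray  # technician variance per lab
    sigma2_c: np.ndarray  # CG-within-technician variance per lab
    sigma2_e: np.ndarray  # residual variance per lab
    G0: np.ndarray  # genetic covariance among lab-traits

    def genetic_variances(self) -> np.ndarray:
        return np.diag(self.G0)


@dataclass
class TrivariateFit:
    components: MultiTraitComponents
    neg2_logL: float
    mu: np.ndarray  # fitted mean per lab
    rg: np.ndarray  # 3x3 genetic correlation matrix
    converged: bool
    nfev: int
    unidentifiable_pairs: list[tuple[int, int]] = field(default_factory=list)
    restart_neg2_logL: list[float] = field(default_factory=list)
    n_restarts_agreeing: int = 0


class TrivariateDesign:
    """Preassembled stacked design for one trait across the three labs.

    Layout of the coefficient matrix:
    [mu (one per lab) | technicians | CGs | animal block lab 1 | lab 2 | lab 3].
    """

    def __init__(self, ds: StudyDataset, trait, Ainv: sp.spmatrix | None = None) -> None:
        self.pedigree: Pedigree = ds.pedigree
        self.Ainv = (Ainv if Ainv is not None else build_A_inverse(ds.pedigree)).tocsr()
        self.labs = ds.labs
        if len(self.labs) != 3:
            raise ValueError(f"expected records from 3 labs, found {self.labs}")
        self.n_A = self.pedigree.n
        dfs = [ds.subset(trait, lab) for lab in self.labs]
        self.n_per_lab = np.array([len(d) for d in dfs])
        self.tech_ids = [sorted(d["technician"].unique()) for d in dfs]
        self.cg_ids = [sorted(d["cg"].unique()) for d in dfs]
        self.q_t = np.array([len(t) for t in self.tech_ids])
        self.q_c = np.array([len(c) for c in self.cg_ids])
        n_mu = 3
        self.tech_offset = n_mu
        self.cg_offset = n_mu + int(self.q_t.sum())
        self.u_offset = self.cg_offset + int(self.q_c.sum())
        self.dim = self.u_offset + 3 * self.n_A
        # per-effect lab membership for the diagonal ridge
        self.tech_lab = np.repeat(np.arange(3), self.q_t)
        self.cg_lab = np.repeat(np.arange(3), self.q_c)

        self.WtW: list[sp.csc_matrix] = []
        self.Wty: list[np.ndarray] = []
        self.yty: list[float] = []
        self.sires_per_lab: list[set[str]] = []
        t_base = np.concatenate([[0], np.cumsum(self.q_t)])[:3] + self.tech_offset
        c_base = np.concatenate([[0], np.cumsum(self.q_c)])[:3] + self.cg_offset
        for l, df in enumerate(dfs):
            y = df["value"].to_numpy(dtype=float)
            n = len(df)
            t_idx = {t: i for i, t in enumerate(self.tech_ids[l])}
            c_idx = {c: i for i, c in enumerate(self.cg_ids[l])}
            rows = np.repeat(np.arange(n), 4)
            cols = np.empty(4 * n, dtype=int)
            cols[0::4] = l
            cols[1::4] = t_base[l] + np.array([t_idx[t] for t in df["technician"]])
            cols[2::4] = c_base[l] + np.array([c_idx[c] for c in df["cg"]])
            cols[3::4] = (
                self.u_offset
                + l * self.n_A
                + np.array([self.pedigree.index[a] for a in df["animal"]])
            )
            W = sp.coo_matrix((np.ones(4 * n), (rows, cols)), shape=(n, self.dim)).tocsr()
            self.WtW.append((W.T @ W).tocsc())
            self.Wty.append(W.T @ y)
            self.yty.append(float(y @ y))
            sires = {
                self.pedigree.parent1[self.pedigree.index[a]] for a in df["animal"]
            }
            self.sires_per_lab.append({s for s in sires if s is not None})
        self.var_y = float(np.var(np.concatenate([d["value"].to_numpy() for d in dfs])))

    def unlinked_lab_pairs(self) -> list[tuple[int, int]]:
        """Lab pairs with no common sire among recorded animals.

        For such pairs the genetic covariance is structurally unidentifiable.
        """
        pairs = []
        for i in range(3):
            for j in range(i + 1, 3):
                if not (self.sires_per_lab[i] & self.sires_per_lab[j]):
                    pairs.append((self.labs[i], self.labs[j]))
        return pairs

    def coefficient_matrix(
        self, comp: MultiTraitComponents
    ) -> tuple[sp.csc_matrix, np.ndarray]:
        """Unscaled MME: C = sum_l W_l' W_l / se2_l + G^-1, rhs likewise."""
        C = sum(
            (self.WtW[l] / comp.sigma2_e[l] for l in range(3)),
            start=sp.csc_matrix((self.dim, self.dim)),
        )
        rhs = sum(self.Wty[l] / comp.sigma2_e[l] for l in range(3))
        diag = np.zeros(self.dim)
        diag[self.tech_offset : self.cg_offset] = 1.0 / comp.sigma2_t[self.tech_lab]
        diag[self.cg_offset : self.u_offset] = 1.0 / comp.sigma2_c[self.cg_lab]
        G0inv = np.linalg.inv(comp.G0)
        Gblock = sp.kron(sp.csr_matrix(G0inv), self.Ainv).tocoo()
        Gfull = sp.coo_matrix(
            (Gblock.data, (Gblock.row + self.u_offset, Gblock.col + self.u_offset)),
            shape=(self.dim, self.dim),
        )
        return (C + sp.diags(diag) + Gfull).tocsc(), rhs


def _pack(comp: MultiTraitComponents) -> np.ndarray:
    L = np.linalg.cholesky(comp.G0)
    return np.concatenate(
        [
            np.log(comp.sigma2_t),
            np.log(comp.sigma2_c),
            np.log(comp.sigma2_e),
            [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), L[2, 0], L[2, 1], np.log(L[2, 2])],
        ]
    )


def _unpack(x: np.ndarray, floor: float) -> MultiTraitComponents:
    v = np.exp(np.maximum(x[:9], np.log(floor)))
    g = x[9:]
    L = np.array(
        [
            [np.exp(g[0]), 0.0, 0.0],
            [g[1], np.exp(g[2]), 0.0],
            [g[3], g[4], np.exp(g[5])],
        ]
    )
    # keep diagonal of the factor floored so G0 stays invertible
    L[np.diag_indices(3)] = np.maximum(np.diag(L), np.sqrt(floor))
    return MultiTraitComponents(v[0:3], v[3:6], v[6:9], L @ L.T)


def trivariate_neg2_loglik(
    comp: MultiTraitComponents, design: TrivariateDesign
) -> float:
    """-2 restricted log-likelihood of the stacked model (constant dropped)."""
    if np.any(comp.sigma2_t <= 0) or np.any(comp.sigma2_c <= 0) or np.any(
        comp.sigma2_e <= 0
    ):
        raise InvalidComponentsError("variances must be strictly positive")
    sign, logdet_G0 = np.linalg.slogdet(comp.G0)
    if sign <= 0:
        raise InvalidComponentsError("G0 not positive definite")
    C, rhs = design.coefficient_matrix(comp)
    lu = _factor(C)
    sol = lu.solve(rhs)
    quad = sum(design.yty[l] / comp.sigma2_e[l] for l in range(3)) - float(sol @ rhs)
    if quad <= 0:
        raise InvalidComponentsError("nonpositive residual sum of squares")
    return float(
        np.dot(design.n_per_lab, np.log(comp.sigma2_e))
        + np.dot(design.q_t, np.log(comp.sigma2_t))
        + np.dot(design.q_c, np.log(comp.sigma2_c))
        + design.n_A * logdet_G0
        + _logdet_from_lu(lu)
        + quad
    )


def start_from_univariate(
    fits: list[UnivariateFit] | list[VarianceComponents], rg0: float = 0.5
) -> MultiTraitComponents:
    """Starting components assembled from the three per-lab univariate fits.

    Off-diagonal genetic covariances start at ``rg0`` times the geometric
    mean of the univariate additive variances.
    """
    vcs = [f.components if isinstance(f, UnivariateFit) else f for f in fits]
    sa = np.array([v.sigma2_a for v in vcs])
    G0 = rg0 * np.sqrt(np.outer(sa, sa))
    np.fill_diagonal(G0, sa)
    return MultiTraitComponents(
        np.array([v.sigma2_t for v in vcs]),
        np.array([v.sigma2_c for v in vcs]),
        np.array([v.sigma2_e for v in vcs]),
        G0,
    )


@dataclass
class TrivariateFitOptions(FitOptions):
    maxfev: int = 20000
    n_restarts: int = 1
    restart_scales: tuple[float, ...] = (1.5,)
    #: optimize the G0 factor alone (6 params, nuisance variances fixed at
    #: their univariate starting values) before the full 15-parameter search;
    #: gets the genetic covariances near their optimum cheaply
    staged: bool = True
    stage1_maxfev: int = 800


def fit_trivariate(
    design: TrivariateDesign,
    start: MultiTraitComponents | list[UnivariateFit],
    options: TrivariateFitOptions | None = None,
) -> TrivariateFit:
    """Maximize the stacked restricted likelihood over 15 parameters.

    12 per-lab variances (technician, CG, residual, genetic diagonal) plus 3
    genetic covariances, the latter through the Cholesky factor of G0.
    """
    opts = options or TrivariateFitOptions()
    if isinstance(start, list):
        start = start_from_univariate(start)
    unlinked = design.unlinked_lab_pairs()
    if unlinked:
        warnings.warn(
            f"no common sires between lab pairs {unlinked}; their genetic "
            "covariances are unidentifiable",
            stacklevel=2,
        )
    floor = opts.floor_frac * design.var_y

    def objective(x):
        try:
            return trivariate_neg2_loglik(_unpack(x, floor), design)
        except InvalidComponentsError:
            return np.inf

    x0 = _pack(start)
    nfev_stage1 = 0
    if opts.staged:
        fixed = x0[:9].copy()

        def g_objective(g):
            try:
                return trivariate_neg2_loglik(
                    _unpack(np.concatenate([fixed, g]), floor), design
                )
            except InvalidComponentsError:
                return np.inf

        stage1 = nelder_mead_restarted(
            g_objective,
            x0[9:],
            step=opts.step,
            fvar_tol=opts.fvar_tol,
            maxfev=opts.stage1_maxfev,
            improve_tol=opts.improve_tol,
            max_cycles=opts.max_cycles,
        )
        x0 = np.concatenate([fixed, stage1.x])
        nfev_stage1 = stage1.nfev
    kw = dict(
        step=opts.step,
        fvar_tol=opts.fvar_tol,
        maxfev=opts.maxfev,
        improve_tol=opts.improve_tol,
        max_cycles=opts.max_cycles,
    )
    res = nelder_mead_restarted(objective, x0, **kw)
    best = res
    restart_f: list[float] = []
    for scale in opts.restart_scales[: opts.n_restarts]:
        comp_s = MultiTraitComponents(
            start.sigma2_t * scale,
            start.sigma2_c * scale,
            start.sigma2_e * scale,
            start.G0 * scale,
        )
        res_r = nelder_mead_restarted(objective, _pack(comp_s), **kw)
        restart_f.append(res_r.fun)
        if res_r.fun < best.fun:
            best = res_r
    comp = _unpack(best.x, floor)
    C, rhs = design.coefficient_matrix(comp)
    sol = _factor(C).solve(rhs)
    agree = int(sum(abs(f - best.fun) < opts.agree_tol for f in restart_f))
    return TrivariateFit(
        components=comp,
        neg2_logL=best.fun,
        mu=sol[:3].copy(),
        rg=rg_matrix(comp.G0),
        converged=res.converged,
        nfev=best.nfev + nfev_stage1,
        unidentifiable_pairs=unlinked,
        restart_neg2_logL=restart_f,
        n_restarts_agreeing=agree,
    )


def genetic_correlation(G0: np.ndarray, i: int, j: int) -> float:
    """rg_ij = sigma_a(i,j) / sqrt(sigma2_ai * sigma2_aj); 0-based lab indices."""
    if G0[i, i] <= 0 or G0[j, j] <= 0:
        raise ValueError("zero genetic variance: correlation undefined")
    return float(G0[i, j] / np.sqrt(G0[i, i] * G0[j, j]))


def rg_matrix(G0: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(G0))
    return G0 / np.outer(d, d)


def rg_z_test(rg: float, se: float) -> tuple[float, bool]:
    """z-test of a genetic correlation against 1 (two-sided, alpha = 0.05)."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    if se == 0:
        if rg == 1:
            return 0.0, False
        return float(np.sign(rg - 1) * np.inf), True
    z = (rg - 1.0) / se
    return float(z), bool(abs(z) > Z_CRIT_95)


def solve_trivariate_ebv(
    design: TrivariateDesign,
    comp: MultiTraitComponents,
    animals: list[str] | None = None,
) -> dict[int, pd.DataFrame]:
    """Per-lab-trait EBVs with PEV and accuracy for the requested animals.

    PEV is the corresponding diagonal of the inverse coefficient matrix;
    accuracy uses the lab-trait genetic variance from G0.
    """
    C, rhs = design.coefficient_matrix(comp)
    lu = _factor(C)
    sol = lu.solve(rhs)
    ids = animals if animals is not None else list(design.pedigree.animals)
    idx = np.array([design.pedigree.index[a] for a in ids])
    out: dict[int, pd.DataFrame] = {}
    for l, lab in enumerate(design.labs):
        cols = design.u_offset + l * design.n_A + idx
        E = np.zeros((design.dim, len(cols)))
        E[cols, np.arange(len(cols))] = 1.0
        pev = lu.solve(E)[cols, np.arange(len(cols))]
        sa2 = comp.G0[l, l]
        acc = (
            np.sqrt(np.clip(1.0 - pev / sa2, 0.0, 1.0)) if sa2 > 0 else np.zeros(len(cols))
        )
        out[lab] = pd.DataFrame(
            {"animal": ids, "ebv": sol[cols], "pev": pev, "accuracy": acc}
        )
    return out
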