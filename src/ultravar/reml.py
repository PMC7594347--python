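"""Univariate animal-model REML.

Model for one trait within one interpretation laboratory:

    y = mu + t_i + c_ij + a_ijk + e_ijk

with t ~ N(0, I sigma2_t) (technician), c ~ N(0, I sigma2_c) (contemporary
group nested within technician), a ~ N(0, A sigma2_a) (additive genetic,
A the numerator relationship matrix over the whole pedigree) and
e ~ N(0, I sigma2_e).  The single fixed effect is the overall mean.

The restricted log-likelihood is evaluated through a sparse factorization
of Henderson's mixed-model equations:

    -2 logL = n log se2 + q_t log st2 + q_c log sc2 + n_A log sa2
              + log|C| + y'Py  + const

where C is the (unscaled) MME coefficient matrix and y'Py the weighted
residual sum of squares; constants independent of the variance components
(log|A| and the 2*pi term) are dropped.  The components are estimated by a
derivative-free simplex over log-variances, with convergence declared when
the variance of -2 logL across simplex vertices drops below 1e-10, and
confirmed by restarts from perturbed starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._optim import nelder_mead_restarted
from .pedigree import Pedigree, build_A_inverse
from .phenotypes import StudyDataset


class InvalidComponentsError(ValueError):
    """The mixed-model system is not positive definite at these components."""


@dataclass
class VarianceComponents:
    """(sigma2_t, sigma2_c, sigma2_a, sigma2_e) for one trait-by-lab model."""

    sigma2_t: float
    sigma2_c: float
    sigma2_a: float
    sigma2_e: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_t, self.sigma2_c, self.sigma2_a, self.sigma2_e])

    @classmethod
    def from_array(cls, x) -> "VarianceComponents":
        return cls(*(float(v) for v in x))

    @property
    def total(self) -> float:
        return float(self.as_array().sum())

    def scaled(self, k: float) -> "VarianceComponents":
        return VarianceComponents.from_array(self.as_array() * k)


@dataclass
class MMELayout:
    """Index layout of the MME coefficient matrix: [mu | technicians | CGs | animals]."""

    mu: slice
    tech: slice
    cg: slice
    animal: slice
    tech_ids: list[str]
    cg_ids: list[str]
    animal_ids: list[str]

    @property
    def dim(self) -> int:
        return self.animal.stop


class UnivariateDesign:
    """Preassembled design pieces for one trait-by-lab dataset.

    Caches W'W, W'y and y'y (W = [1 | Z_t | Z_c | Z_a]) so each likelihood
    evaluation only adds the variance-ratio ridge and factorizes.
    """

    def __init__(
        self,
        y: np.ndarray,
        technician: np.ndarray,
        cg: np.ndarray,
        animal: np.ndarray,
        pedigree: Pedigree,
        Ainv: sp.spmatrix | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        self.n = len(y)
        self.tech_ids = sorted(pd.unique(technician))
        self.cg_ids = sorted(pd.unique(cg))
        self.animal_ids = list(pedigree.animals)
        self.pedigree = pedigree
        self.Ainv = (
            Ainv if Ainv is not None else build_A_inverse(pedigree)
        ).tocsr()
        q_t, q_c, n_a = len(self.tech_ids), len(self.cg_ids), len(self.animal_ids)
        self.layout = MMELayout(
            mu=slice(0, 1),
            tech=slice(1, 1 + q_t),
            cg=slice(1 + q_t, 1 + q_t + q_c),
            animal=slice(1 + q_t + q_c, 1 + q_t + q_c + n_a),
            tech_ids=self.tech_ids,
            cg_ids=self.cg_ids,
            animal_ids=self.animal_ids,
        )
        t_idx = {t: i for i, t in enumerate(self.tech_ids)}
        c_idx = {c: i for i, c in enumerate(self.cg_ids)}
        rows = np.repeat(np.arange(self.n), 4)
        cols = np.empty(4 * self.n, dtype=int)
        cols[0::4] = 0
        cols[1::4] = self.layout.tech.start + np.array([t_idx[t] for t in technician])
        cols[2::4] = self.layout.cg.start + np.array([c_idx[c] for c in cg])
        cols[3::4] = self.layout.animal.start + np.array(
            [pedigree.index[a] for a in animal]
        )
        W = sp.coo_matrix(
            (np.ones(4 * self.n), (rows, cols)), shape=(self.n, self.layout.dim)
        ).tocsr()
        self.W = W
        self.WtW = (W.T @ W).tocsc()
        self.Wty = W.T @ y
        self.yty = float(y @ y)
        self.var_y = float(np.var(y))

    @classmethod
    def from_dataset(
        cls,
        ds: StudyDataset,
        trait=None,
        lab=None,
        Ainv: sp.spmatrix | None = None,
    ) -> "UnivariateDesign":
        df = ds.subset(trait, lab)
        if df.empty:
            raise ValueError(f"no records for trait={trait!r}, lab={lab!r}")
        return cls(
            df["value"].to_numpy(),
            df["technician"].to_numpy(),
            df["cg"].to_numpy(),
            df["animal"].to_numpy(),
            ds.pedigree,
            Ainv=Ainv,
        )

    def _ridge(self, vc: VarianceComponents) -> sp.csc_matrix:
        lay = self.layout
        se2 = vc.sigma2_e
        diag = np.zeros(lay.dim)
        diag[lay.tech] = se2 / vc.sigma2_t
        diag[lay.cg] = se2 / vc.sigma2_c
        ridge = sp.diags(diag).tocsc()
        lam_a = se2 / vc.sigma2_a
        Ainv = (self.Ainv * lam_a).tocoo()
        rows = Ainv.row + lay.animal.start
        cols = Ainv.col + lay.animal.start
        ablock = sp.coo_matrix((Ainv.data, (rows, cols)), shape=(lay.dim, lay.dim))
        return (ridge + ablock).tocsc()

    def scaled_mme(self, vc: VarianceComponents) -> tuple[sp.csc_matrix, np.ndarray]:
        """sigma2_e-scaled MME: C* = W'W + ridge, rhs* = W'y."""
        return (self.WtW + self._ridge(vc)).tocsc(), self.Wty


def assemble_mme(
    design: UnivariateDesign, vc: VarianceComponents
) -> tuple[sp.csc_matrix, np.ndarray, MMELayout]:
    """Henderson MME (residual-scaled): coefficient matrix, RHS, layout.

    The coefficient matrix is W'W plus ridge terms lambda_t I, lambda_c I and
    lambda_a A^-1 with lambda_x = sigma2_e / sigma2_x; animals without
    records enter through the A^-1 block.
    """
    C, rhs = design.scaled_mme(vc)
    return C, rhs, design.layout


def _factor(C: sp.csc_matrix):
    # symmetric minimum-degree ordering: the MME are SPD and COLAMD's
    # unsymmetric ordering fills in badly on the dense mean row/column
    try:
        return splu(
            C,
            permc_spec="MMD_AT_PLUS_A",
            options=dict(SymmetricMode=True, DiagPivotThresh=0.01),
        )
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise InvalidComponentsError(str(exc)) from exc


def _logdet_from_lu(lu) -> float:
    diag = lu.U.diagonal()
    if np.any(diag == 0):
        raise InvalidComponentsError("singular MME coefficient matrix")
    return float(np.sum(np.log(np.abs(diag))))


def reml_neg2_loglik(vc: VarianceComponents, design: UnivariateDesign) -> float:
    """-2 x restricted log-likelihood, up to a components-independent constant."""
    arr = vc.as_array()
    if np.any(arr <= 0):
        raise InvalidComponentsError("variance components must be strictly positive")
    lay = design.layout
    C, rhs = design.scaled_mme(vc)
    lu = _factor(C)
    sol = lu.solve(rhs)
    se2 = vc.sigma2_e
    q_t = lay.tech.stop - lay.tech.start
    q_c = lay.cg.stop - lay.cg.start
    n_a = lay.animal.stop - lay.animal.start
    # log|C_unscaled| = log|C*| - dim log se2
    logdet_C = _logdet_from_lu(lu) - lay.dim * np.log(se2)
    ypy = (design.yty - float(sol @ rhs)) / se2
    if ypy <= 0:
        raise InvalidComponentsError("nonpositive residual sum of squares")
    return (
        design.n * np.log(se2)
        + q_t * np.log(vc.sigma2_t)
        + q_c * np.log(vc.sigma2_c)
        + n_a * np.log(vc.sigma2_a)
        + logdet_C
        + ypy
    )


@dataclass
class FitOptions:
    """Tunables of the derivative-free REML search."""

    fvar_tol: float = 1e-10  # variance of -2logL over simplex vertices
    maxfev: int = 5000
    improve_tol: float = 1e-8  # stop re-inflating the simplex below this gain
    max_cycles: int = 25
    n_restarts: int = 2
    restart_scales: tuple[float, ...] = (0.5, 2.0)
    # restarts "agree" when their -2logL differ by less; the default f-variance
    # stopping rule localizes the optimum to ~1e-5, so 1e-4 means "same optimum"
    agree_tol: float = 1e-4
    floor_frac: float = 1e-8  # variance floor as a fraction of var(y)
    step: float = 0.3  # initial simplex step in log-variance space
    compute_ebv: bool = True


@dataclass
class UnivariateFit:
    components: VarianceComponents
    neg2_logL: float
    mu_hat: float
    converged: bool
    n_restarts_agreeing: int
    restart_neg2_logL: list[float] = field(default_factory=list)
    nfev: int = 0
    ebv: pd.DataFrame | None = None  # columns: animal, ebv, pev, accuracy


def _auto_start(design: UnivariateDesign) -> VarianceComponents:
    v = design.var_y
    return VarianceComponents(0.15 * v, 0.30 * v, 0.25 * v, 0.30 * v)


def _minimize(design: UnivariateDesign, start: VarianceComponents, opts: FitOptions):
    floor = opts.floor_frac * design.var_y
    lo = np.log(floor)

    def objective(x):
        vc = VarianceComponents.from_array(np.exp(np.maximum(x, lo)))
        try:
            return reml_neg2_loglik(vc, design)
        except InvalidComponentsError:
            return np.inf

    x0 = np.log(np.maximum(start.as_array(), floor))
    res = nelder_mead_restarted(
        objective,
        x0,
        step=opts.step,
        fvar_tol=opts.fvar_tol,
        maxfev=opts.maxfev,
        improve_tol=opts.improve_tol,
        max_cycles=opts.max_cycles,
    )
    vc = VarianceComponents.from_array(np.exp(np.maximum(res.x, lo)))
    return vc, res


def fit_univariate(
    design: UnivariateDesign,
    start: VarianceComponents | str = "auto",
    options: FitOptions | None = None,
) -> UnivariateFit:
    """Estimate variance components by derivative-free REML.

    The search runs from ``start`` (or an automatic partition of the
    phenotypic variance) and is repeated from perturbed starting values;
    the best run is kept and agreement of the restarts in -2 logL is
    recorded as evidence of convergence to a global maximum.
    """
    opts = options or FitOptions()
    if isinstance(start, str):
        start = _auto_start(design)
    vc_best, res_best = _minimize(design, start, opts)
    restart_f: list[float] = []
    for scale in opts.restart_scales[: opts.n_restarts]:
        vc_r, res_r = _minimize(design, start.scaled(scale), opts)
        restart_f.append(res_r.fun)
        if res_r.fun < res_best.fun:
            vc_best, res_best = vc_r, res_r
    agree = int(sum(abs(f - res_best.fun) < opts.agree_tol for f in restart_f))
    ebv = None
    mu = np.nan
    if opts.compute_ebv:
        mu, ebv = solve_ebv(design, vc_best)
    return UnivariateFit(
        components=vc_best,
        neg2_logL=res_best.fun,
        mu_hat=float(mu),
        converged=res_best.converged,
        n_restarts_agreeing=agree,
        restart_neg2_logL=restart_f,
        nfev=res_best.nfev,
        ebv=ebv,
    )


def solve_ebv(
    design: UnivariateDesign,
    vc: VarianceComponents,
    pev_animals: list[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """BLUP solutions of the MME at fixed components.

    Returns the estimated mean and a table (animal, ebv, pev, accuracy)
    with PEV from the a-block diagonal of the inverse coefficient matrix
    times sigma2_e, and accuracy r = sqrt(1 - PEV / sigma2_a).
    ``pev_animals`` restricts the (dense-column) PEV solves to a subset.
    """
    lay = design.layout
    C, rhs = design.scaled_mme(vc)
    lu = _factor(C)
    sol = lu.solve(rhs)
    mu = sol[0]
    ebv = sol[lay.animal]
    if pev_animals is None:
        idx = np.arange(len(lay.animal_ids))
        ids = lay.animal_ids
    else:
        idx = np.array([design.pedigree.index[a] for a in pev_animals])
        ids = list(pev_animals)
    cols = lay.animal.start + idx
    E = np.zeros((lay.dim, len(cols)))
    E[cols, np.arange(len(cols))] = 1.0
    Cinv_cols = lu.solve(E)
    pev = Cinv_cols[cols, np.arange(len(cols))] * vc.sigma2_e
    if vc.sigma2_a > 0:
        acc = np.sqrt(np.clip(1.0 - pev / vc.sigma2_a, 0.0, 1.0))
    else:
        acc = np.zeros(len(cols))
    table = pd.DataFrame(
        {"animal": ids, "ebv": ebv[idx], "pev": pev, "accuracy": acc}
    )
    return float(mu), table


def component_covariance(
    design: UnivariateDesign, vc: VarianceComponents, rel_step: float = 1e-3
) -> np.ndarray:
    """Asymptotic covariance of the REML estimates.

    Central-difference Hessian of -2 logL at the optimum, inverted and
    doubled (observed-information approximation).  Returns a 4x4 matrix in
    the order (t, c, a, e); NaN-filled if the Hessian is not positive
    definite (flat or boundary likelihood).
    """
    x0 = vc.as_array()
    h = rel_step * x0
    H = np.zeros((4, 4))

    def f(x):
        return reml_neg2_loglik(VarianceComponents.from_array(x), design)

    f0 = f(x0)
    for i in range(4):
        for j in range(i, 4):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += h[[i, j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4 * h[i] * h[j]
                )
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((4, 4), np.nan)
    if np.any(np.diag(cov) < 0):
        return np.full((4, 4), np.nan)
    return cov
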