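"""Nelder–Mead simplex with the derivative-free REML stopping rule.

The restricted likelihood is maximized by direct search; convergence is
declared when the variance of the objective (-2 log L) across the simplex
vertices falls below a threshold (default 1e-10).  That stopping rule is
part of the estimation procedure being replicated, which is why the simplex
is implemented here rather than delegated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SimplexResult:
    x: np.ndarray
    fun: float
    nfev: int
    converged: bool
    fvar: float


def nelder_mead_restarted(
    func,
    x0,
    step: float = 0.3,
    fvar_tol: float = 1e-10,
    maxfev: int = 5000,
    improve_tol: float = 1e-8,
    max_cycles: int = 25,
) -> SimplexResult:
    """Nelder–Mead with simplex re-inflation.

    A collapsed simplex can satisfy the f-variance stopping rule away from
    the optimum, especially in higher dimensions; re-running with a fresh
    simplex centred on the incumbent until -2 logL stops improving guards
    against that (the direct-search analogue of confirming convergence by
    restarting).  ``maxfev`` is the total budget across cycles.
    """
    best = nelder_mead(func, x0, step=step, fvar_tol=fvar_tol, maxfev=maxfev)
    nfev = best.nfev
    for cycle in range(1, max_cycles):
        if nfev >= maxfev:
            break
        # progressively smaller simplexes refine the incumbent locally
        res = nelder_mead(
            func,
            best.x,
            step=max(step * 0.5**cycle, 0.02),
            fvar_tol=fvar_tol,
            maxfev=maxfev - nfev,
        )
        nfev += res.nfev
        improved = best.fun - res.fun
        if res.fun < best.fun:
            best = res
        if improved < improve_tol:
            break
    return SimplexResult(best.x, best.fun, nfev, best.converged, best.fvar)


def nelder_mead(
    func,
    x0,
    step: float = 0.3,
    fvar_tol: float = 1e-10,
    maxfev: int = 5000,
) -> SimplexResult:
    """Minimize ``func`` from ``x0`` with a standard Nelder–Mead simplex.

    Coefficients: reflection 1, expansion 2, contraction 0.5, shrink 0.5.
    Stops when the population variance of the vertex objective values is
    below ``fvar_tol`` or ``maxfev`` evaluations are spent.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    simplex = np.vstack([x0] + [x0 + step * np.eye(n)[i] for i in range(n)])
    nfev = 0

    def f(x):
        nonlocal nfev
        nfev += 1
        return func(x)

    fvals = np.array([f(x) for x in simplex])
    while True:
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        fvar = float(np.var(fvals))
        if fvar < fvar_tol:
            return SimplexResult(simplex[0], fvals[0], nfev, True, fvar)
        if nfev >= maxfev:
            return SimplexResult(simplex[0], fvals[0], nfev, False, fvar)
        centroid = simplex[:-1].mean(axis=0)
        xr = centroid + (centroid - simplex[-1])
        fr = f(xr)
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - simplex[-1])
            fe = f(xe)
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = centroid + 0.5 * (centroid - simplex[-1])
                fc = f(xc)
                better = fc <= fr
            else:  # inside contraction
                xc = centroid - 0.5 * (centroid - simplex[-1])
                fc = f(xc)
                better = fc < fvals[-1]
            if better:
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward best
                for i in range(1, n + 1):
                    simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                    fvals[i] = f(simplex[i])
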