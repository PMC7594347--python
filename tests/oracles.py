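"""Dense generalized-least-squares oracles used to check the sparse REML path.

These rebuild the phenotypic covariance V explicitly from incidence
matrices and the dense relationship matrix, and evaluate the restricted
likelihood and BLUP directly -- an independent route kept deliberately
separate from the package's MME-based implementation.
"""

import numpy as np

from ultravar.pedigree import build_A


def design_matrices(ds, trait, lab):
    df = ds.subset(trait, lab)
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    tech_ids = sorted(df["technician"].unique())
    cg_ids = sorted(df["cg"].unique())
    Zt = np.zeros((n, len(tech_ids)))
    Zc = np.zeros((n, len(cg_ids)))
    Za = np.zeros((n, ds.pedigree.n))
    for r, (t, c, a) in enumerate(zip(df["technician"], df["cg"], df["animal"])):
        Zt[r, tech_ids.index(t)] = 1
        Zc[r, cg_ids.index(c)] = 1
        Za[r, ds.pedigree.index[a]] = 1
    return y, Zt, Zc, Za


def dense_V(ds, trait, lab, vc):
    y, Zt, Zc, Za = design_matrices(ds, trait, lab)
    A = build_A(ds.pedigree, include_inbreeding=False)
    V = (
        vc.sigma2_t * Zt @ Zt.T
        + vc.sigma2_c * Zc @ Zc.T
        + vc.sigma2_a * Za @ A @ Za.T
        + vc.sigma2_e * np.eye(len(y))
    )
    return y, V


def dense_neg2_reml(ds, trait, lab, vc):
    """-2 restricted logL = log|V| + log|X'V^-1 X| + y'Py (constants dropped)."""
    y, V = dense_V(ds, trait, lab, vc)
    n = len(y)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return float(np.linalg.slogdet(V)[1] + np.log(XVX[0, 0]) + y @ P @ y)


def dense_blup(ds, trait, lab, vc):
    """GLS mean and BLUP breeding values for every pedigree animal."""
    y, V = dense_V(ds, trait, lab, vc)
    _, _, _, Za = design_matrices(ds, trait, lab)
    A = build_A(ds.pedigree, include_inbreeding=False)
    n = len(y)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = vc.sigma2_a * A @ Za.T @ Vi @ (y - X @ beta)
    return float(beta[0]), u
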