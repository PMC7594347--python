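"""Downstream statistics of the variance-partitioning study.

Heritability on the within-technician, within-CG scale
(h2 = sa2 / (sa2 + se2)); percentage partitions of phenotypic variance with
delta-method standard errors; between-laboratory dispersion
(range / mean); Bartlett's homogeneity test on CG-mean-corrected residuals
grouped by technician; the accuracy-based standard error of a genetic
correlation; and Spearman rank correlations of sire EBVs between labs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reml import VarianceComponents


def heritability(sigma2_a: float, sigma2_e: float) -> float:
    """h2 = sa2 / (sa2 + se2).

    Technician and contemporary-group variances are excluded from the
    denominator: a single technician scans each CG, so this is the
    within-CG heritability.
    """
    if sigma2_a < 0 or sigma2_e < 0:
        raise ValueError("variances must be nonnegative")
    denom = sigma2_a + sigma2_e
    if denom == 0:
        raise ValueError("sa2 + se2 must be positive")
    return sigma2_a / denom


def variance_percentages(vc: VarianceComponents) -> np.ndarray:
    """Percent of phenotypic variance per component, order (t, c, a, e)."""
    arr = np.array([vc.sigma2_t, vc.sigma2_c, vc.sigma2_a, vc.sigma2_e])
    total = arr.sum()
    if total <= 0:
        raise ValueError("at least one component must be positive")
    return 100.0 * arr / total


def dispersion_range_over_mean(values) -> float:
    """100 * (max - min) / mean, the between-laboratory dispersion percent."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    m = v.mean()
    if m <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * (v.max() - v.min()) / m)


@dataclass
class PartitionSummary:
    """One table row: components, percentage partition (+SE) and h2 (+SE)."""

    components: VarianceComponents
    percents: np.ndarray  # order (t, c, a, e), sums to 100
    percent_se: np.ndarray
    h2: float
    h2_se: float

    @classmethod
    def from_fit(
        cls, vc: VarianceComponents, cov: np.ndarray | None = None
    ) -> "PartitionSummary":
        """Build from estimated components and (optionally) their covariance.

        SEs use the delta method on p_x = 100 v_x / sum(v) and
        h2 = v_a / (v_a + v_e); covariance order is (t, c, a, e).
        """
        arr = np.array([vc.sigma2_t, vc.sigma2_c, vc.sigma2_a, vc.sigma2_e])
        total = arr.sum()
        percents = 100.0 * arr / total
        if cov is None or np.any(np.isnan(cov)):
            pse = np.full(4, np.nan)
            h2se = np.nan
        else:
            J = 100.0 * (np.eye(4) * total - arr[:, None]) / total**2
            pse = np.sqrt(np.clip(np.diag(J @ cov @ J.T), 0, None))
            a, e = arr[2], arr[3]
            g = np.array([0.0, 0.0, e, -a]) / (a + e) ** 2
            h2se = float(np.sqrt(max(g @ cov @ g, 0.0)))
        return cls(vc, percents, pse, heritability(arr[2], arr[3]), h2se)


def residuals_within_technician(
    records: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], int]:
    """CG-mean-corrected residuals grouped by technician.

    Each record's residual is its value minus the mean of its contemporary
    group; CGs with a single record carry no within-CG information and are
    dropped (the dropped count is returned).
    """
    df = records.copy()
    sizes = df.groupby("cg")["value"].transform("size")
    dropped = int((sizes == 1).sum())
    df = df[sizes > 1]
    df["resid"] = df["value"] - df.groupby("cg")["value"].transform("mean")
    groups = {
        tech: g["resid"].to_numpy() for tech, g in df.groupby("technician", sort=True)
    }
    return groups, dropped


@dataclass
class BartlettResult:
    statistic: float
    df: int
    p_value: float
    zero_variance_groups: list[str]


def bartlett_homogeneity(groups: dict[str, np.ndarray]) -> BartlettResult:
    """Bartlett's test of equal variances across groups.

    Classical statistic with the Box correction factor, chi-square
    upper-tail p on k-1 df.  Groups with fewer than 2 observations are
    invalid; a zero-variance group makes the statistic infinite (flagged).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    zero = [name for name, v in groups.items() if np.var(v, ddof=1) == 0]
    k = len(groups)
    if zero:
        return BartlettResult(np.inf, k - 1, 0.0, zero)
    stat, p = sps.bartlett(*groups.values())
    return BartlettResult(float(stat), k - 1, float(p), [])


def se_genetic_correlation(rg: float, r_ik: float, r_jk: float, N: int) -> float:
    """Standard error of a between-lab genetic correlation.

    Uses the mean EBV accuracies (r_ik, r_jk) of the N sires with progeny
    recorded in both labs:

        SE = sqrt([1/(r_ik^2 r_jk^2)
                   + (1 + 0.5 r_ik^4 + 0.5 r_jk^4 - 2 r_ik^2 - 2 r_jk^2) rg^2
                   + rg^4] / (N - 1))

    At unit accuracies this reduces to (1 - rg^2) / sqrt(N - 1), the
    classical correlation standard error.
    """
    if not (0 < r_ik <= 1 and 0 < r_jk <= 1):
        raise ValueError("accuracies must lie in (0, 1]")
    if N < 2:
        raise ValueError("need at least two common sires")
    ri2, rj2 = r_ik**2, r_jk**2
    num = (
        1.0 / (ri2 * rj2)
        + (1.0 + 0.5 * ri2**2 + 0.5 * rj2**2 - 2.0 * ri2 - 2.0 * rj2) * rg**2
        + rg**4
    )
    return float(np.sqrt(num / (N - 1)))


def spearman_ebv_correlation(
    ebv_i: dict[str, float] | pd.Series, ebv_j: dict[str, float] | pd.Series
) -> tuple[float, int]:
    """Spearman rho of sire EBVs over the sires common to two labs.

    Average ranks on ties.  Raises if fewer than 3 sires are shared.
    """
    si = pd.Series(ebv_i)
    sj = pd.Series(ebv_j)
    common = si.index.intersection(sj.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common sires; need at least 3")
    rho, _ = sps.spearmanr(si[common], sj[common])
    return float(rho), len(common)
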