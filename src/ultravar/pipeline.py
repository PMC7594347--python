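"""End-to-end study orchestration.

Reproduces the full design on any dataset: age-window filter, structural
validation, one univariate REML fit per trait-by-lab cell, one trivariate
lab-as-trait fit per trait, and the downstream diagnostics (percentage
partitions with SEs, heritabilities, between-lab dispersion, Bartlett
homogeneity of technician residuals, genetic correlations with
accuracy-based SEs and z-tests against 1, Spearman rank correlations of
sire EBVs).  Sire EBVs and accuracies for the correlation diagnostics come
from the per-lab univariate fits, restricted to sires with at least one
recorded progeny in each lab of a pair.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .multitrait import (
    TrivariateDesign,
    TrivariateFit,
    TrivariateFitOptions,
    fit_trivariate,
    genetic_correlation,
    rg_z_test,
    start_from_univariate,
)
from .pedigree import build_A_inverse, read_pedigree
from .phenotypes import (
    StudyDataset,
    filter_age_window,
    read_records,
    summarize_dataset,
    validate_structure,
)
from .reml import (
    FitOptions,
    UnivariateDesign,
    UnivariateFit,
    component_covariance,
    fit_univariate,
    solve_ebv,
)
from .stats import (
    PartitionSummary,
    bartlett_homogeneity,
    dispersion_range_over_mean,
    residuals_within_technician,
    se_genetic_correlation,
    spearman_ebv_correlation,
)


class ValidationError(RuntimeError):
    """Raised in strict mode when the dataset violates the nesting structure."""


@dataclass
class StudyOptions:
    """Knobs of a full study run."""

    strict: bool = True  # abort on structural violations
    compute_se: bool = True  # Hessian-based SEs for partitions/h2
    rg0: float = 0.5  # starting between-lab genetic correlation
    univariate: FitOptions = field(default_factory=FitOptions)
    trivariate: TrivariateFitOptions = field(default_factory=TrivariateFitOptions)
    min_common_sires: int = 3


@dataclass
class StudyReport:
    """All tables and fit metadata from one study run."""

    summary: pd.DataFrame
    partitions: dict[tuple[str, int], PartitionSummary]
    univariate_fits: dict[tuple[str, int], UnivariateFit]
    trivariate_fits: dict[str, TrivariateFit]
    rg_tables: dict[str, pd.DataFrame]
    bartlett: dict[str, dict]
    dispersion: dict[str, dict[str, float]]
    violations: list[str]
    n_dropped_age: int
    seed: int | None = None

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.univariate_fits.values()) and all(
            f.converged for f in self.trivariate_fits.values()
        )

    def partition_table(self) -> pd.DataFrame:
        rows = []
        for (trait, lab), p in sorted(self.partitions.items()):
            vc = p.components
            rows.append(
                {
                    "trait": trait,
                    "lab": lab,
                    "sigma2_a": vc.sigma2_a,
                    "pct_a": round(p.percents[2]),
                    "sigma2_t": vc.sigma2_t,
                    "pct_t": round(p.percents[0]),
                    "sigma2_c": vc.sigma2_c,
                    "pct_c": round(p.percents[1]),
                    "sigma2_e": vc.sigma2_e,
                    "pct_e": round(p.percents[3]),
                    "h2": round(p.h2, 2),
                    "h2_se": round(p.h2_se, 2) if np.isfinite(p.h2_se) else np.nan,
                    "converged": self.univariate_fits[(trait, lab)].converged,
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["# Study report", ""]
        if self.violations:
            lines += ["## Validation violations", ""]
            lines += [f"- {v}" for v in self.violations] + [""]
        lines += [
            f"Records dropped by age window: {self.n_dropped_age}",
            "",
            "## Data summary",
            "",
            self.summary.to_markdown(index=False),
            "",
            "## Variance partitions and heritability",
            "",
            self.partition_table().to_markdown(index=False),
            "",
        ]
        for trait, table in sorted(self.rg_tables.items()):
            lines += [
                f"## Between-lab genetic correlations: {trait}",
                "",
                table.to_markdown(index=False),
                "",
            ]
        if self.bartlett:
            lines += ["## Bartlett homogeneity of technician residuals", ""]
            for trait, res in sorted(self.bartlett.items()):
                lines.append(
                    f"- {trait}: statistic {res['statistic']:.2f}, "
                    f"df {res['df']}, P {res['p_value']:.3g}"
                )
            lines.append("")
        if self.dispersion:
            lines += ["## Between-lab dispersion (range / mean, %)", ""]
            for trait, d in sorted(self.dispersion.items()):
                lines.append(
                    f"- {trait}: additive {d['sigma2_a']:.1f}%, residual {d['sigma2_e']:.1f}%"
                )
            lines.append("")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "tables").mkdir(parents=True, exist_ok=True)
        (outdir / "fits").mkdir(parents=True, exist_ok=True)
        (outdir / "report.md").write_text(self.to_markdown())
        self.summary.to_csv(outdir / "tables" / "summary.csv", index=False)
        self.partition_table().to_csv(outdir / "tables" / "partitions.csv", index=False)
        for trait, table in self.rg_tables.items():
            table.to_csv(outdir / "tables" / f"rg_{trait}.csv", index=False)
        for (trait, lab), fit in self.univariate_fits.items():
            payload = {
                "trait": trait,
                "lab": lab,
                "components": dataclasses.asdict(fit.components),
                "neg2_logL": fit.neg2_logL,
                "mu_hat": fit.mu_hat,
                "converged": fit.converged,
                "n_restarts_agreeing": fit.n_restarts_agreeing,
                "restart_neg2_logL": fit.restart_neg2_logL,
                "nfev": fit.nfev,
            }
            with open(outdir / "fits" / f"univariate_{trait}_lab{lab}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            if fit.ebv is not None:
                fit.ebv.to_csv(
                    outdir / "fits" / f"ebv_{trait}_lab{lab}.csv", index=False
                )
        for trait, fit in self.trivariate_fits.items():
            payload = {
                "trait": trait,
                "sigma2_t": list(fit.components.sigma2_t),
                "sigma2_c": list(fit.components.sigma2_c),
                "sigma2_e": list(fit.components.sigma2_e),
                "G0": [list(r) for r in fit.components.G0],
                "rg": [list(r) for r in fit.rg],
                "neg2_logL": fit.neg2_logL,
                "mu": list(fit.mu),
                "converged": fit.converged,
                "nfev": fit.nfev,
                "unidentifiable_pairs": fit.unidentifiable_pairs,
            }
            with open(outdir / "fits" / f"trivariate_{trait}.json", "w") as fh:
                json.dump(payload, fh, indent=2)


def _sires_with_progeny(ds: StudyDataset, trait: str, lab: int) -> set[str]:
    df = ds.subset(trait, lab)
    ped = ds.pedigree
    sires = {ped.parent1[ped.index[a]] for a in df["animal"]}
    sires.discard(None)
    return sires


def run_study(
    ds: StudyDataset,
    options: StudyOptions | None = None,
    seed: int | None = None,
) -> StudyReport:
    """Execute the full analysis on a validated dataset.

    filter -> validate -> univariate fit per trait x lab -> trivariate fit
    per trait (when three labs are present) -> diagnostics.
    """
    opts = options or StudyOptions()
    records, n_dropped = filter_age_window(ds.records)
    ds = StudyDataset(records=records, pedigree=ds.pedigree)
    violations = validate_structure(ds)
    if violations and opts.strict:
        raise ValidationError("; ".join(violations))

    Ainv = build_A_inverse(ds.pedigree)
    summary = summarize_dataset(ds)
    traits, labs = ds.traits, ds.labs

    univariate_fits: dict[tuple[str, int], UnivariateFit] = {}
    partitions: dict[tuple[str, int], PartitionSummary] = {}
    designs: dict[tuple[str, int], UnivariateDesign] = {}
    for trait in traits:
        for lab in labs:
            design = UnivariateDesign.from_dataset(ds, trait, lab, Ainv=Ainv)
            fit = fit_univariate(design, options=opts.univariate)
            cov = (
                component_covariance(design, fit.components)
                if opts.compute_se
                else None
            )
            univariate_fits[(trait, lab)] = fit
            partitions[(trait, lab)] = PartitionSummary.from_fit(fit.components, cov)
            designs[(trait, lab)] = design

    trivariate_fits: dict[str, TrivariateFit] = {}
    rg_tables: dict[str, pd.DataFrame] = {}
    if len(labs) == 3:
        for trait in traits:
            tdesign = TrivariateDesign(ds, trait, Ainv=Ainv)
            start = start_from_univariate(
                [univariate_fits[(trait, lab)] for lab in labs], rg0=opts.rg0
            )
            tfit = fit_trivariate(tdesign, start, options=opts.trivariate)
            trivariate_fits[trait] = tfit
            rows = []
            for i in range(3):
                for j in range(i + 1, 3):
                    lab_i, lab_j = labs[i], labs[j]
                    common = sorted(
                        _sires_with_progeny(ds, trait, lab_i)
                        & _sires_with_progeny(ds, trait, lab_j)
                    )
                    rg = genetic_correlation(tfit.components.G0, i, j)
                    se = z = np.nan
                    rejected = None
                    rho = np.nan
                    if len(common) >= max(2, opts.min_common_sires):
                        acc = {}
                        ebv = {}
                        for lab in (lab_i, lab_j):
                            fit = univariate_fits[(trait, lab)]
                            _, table = solve_ebv(
                                designs[(trait, lab)], fit.components, pev_animals=common
                            )
                            acc[lab] = float(table["accuracy"].mean())
                            ebv[lab] = table.set_index("animal")["ebv"]
                        if min(acc.values()) > 0:
                            se = se_genetic_correlation(
                                rg, acc[lab_i], acc[lab_j], len(common)
                            )
                            z, rejected = rg_z_test(rg, se)
                        if len(common) >= 3:
                            rho, _ = spearman_ebv_correlation(ebv[lab_i], ebv[lab_j])
                    rows.append(
                        {
                            "lab_i": lab_i,
                            "lab_j": lab_j,
                            "rg": round(rg, 2),
                            "se": round(se, 2) if np.isfinite(se) else np.nan,
                            "z": z,
                            "rejected_vs_1": rejected,
                            "spearman": round(rho, 2) if np.isfinite(rho) else np.nan,
                            "n_common_sires": len(common),
                            "identifiable": (lab_i, lab_j)
                            not in tfit.unidentifiable_pairs,
                        }
                    )
            rg_tables[trait] = pd.DataFrame(rows)
    elif len(labs) > 1:
        warnings.warn(
            f"{len(labs)} labs present; lab-as-trait fits need exactly 3, skipping",
            stacklevel=2,
        )

    bartlett: dict[str, dict] = {}
    dispersion: dict[str, dict[str, float]] = {}
    for trait in traits:
        groups, dropped = residuals_within_technician(ds.subset(trait))
        groups = {t: g for t, g in groups.items() if len(g) >= 2}
        if len(groups) >= 2:
            res = bartlett_homogeneity(groups)
            bartlett[trait] = {
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "n_singleton_cg_dropped": dropped,
                "zero_variance_groups": res.zero_variance_groups,
            }
        if len(labs) >= 2:
            dispersion[trait] = {
                "sigma2_a": dispersion_range_over_mean(
                    [univariate_fits[(trait, lab)].components.sigma2_a for lab in labs]
                ),
                "sigma2_e": dispersion_range_over_mean(
                    [univariate_fits[(trait, lab)].components.sigma2_e for lab in labs]
                ),
            }

    return StudyReport(
        summary=summary,
        partitions=partitions,
        univariate_fits=univariate_fits,
        trivariate_fits=trivariate_fits,
        rg_tables=rg_tables,
        bartlett=bartlett,
        dispersion=dispersion,
        violations=violations,
        n_dropped_age=n_dropped,
        seed=seed,
    )


def run_study_from_files(
    records_path,
    pedigree_path,
    options: StudyOptions | None = None,
    seed: int | None = None,
) -> StudyReport:
    """Convenience wrapper reading the records and pedigree CSVs."""
    records = read_records(records_path)
    pedigree = read_pedigree(pedigree_path)
    return run_study(StudyDataset(records=records, pedigree=pedigree), options, seed)
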