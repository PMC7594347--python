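import numpy as np
import pandas as pd
import pytest

from ultravar.pedigree import Pedigree
from ultravar.phenotypes import StudyDataset
from ultravar.reml import (
    FitOptions,
    InvalidComponentsError,
    UnivariateDesign,
    VarianceComponents,
    assemble_mme,
    component_covariance,
    fit_univariate,
    reml_neg2_loglik,
    solve_ebv,
)
from ultravar.simulate import SimulationConfig, simulate_dataset

from conftest import tiny_config  # noqa: F401  (fixture)
from oracles import dense_blup, dense_neg2_reml

VC1 = VarianceComponents(5.0, 8.0, 4.0, 6.0)
VC2 = VarianceComponents(9.0, 3.0, 7.0, 2.0)


def _records_dataset(rows, pedigree_entries):
    df = pd.DataFrame(
        rows,
        columns=["animal", "breed", "trait", "value", "technician", "cg", "lab", "age_days"],
    )
    return StudyDataset(records=df, pedigree=Pedigree.from_entries(pedigree_entries))


class TestAssembleMME:
    def test_block_sizes(self):
        ds = _records_dataset(
            [
                ("A1", "ANGUS", "LMA", 80.0, "T1", "CG1", 1, 400),
                ("A2", "ANGUS", "LMA", 82.0, "T1", "CG1", 1, 400),
            ],
            [("A1", None, None), ("A2", None, None)],
        )
        design = UnivariateDesign.from_dataset(ds, "LMA", 1)
        C, rhs, layout = assemble_mme(design, VC1)
        assert C.shape == (5, 5)  # mu + 1 technician + 1 CG + 2 animals
        assert rhs.shape == (5,)
        assert layout.animal == slice(3, 5)

    def test_unrecorded_animals_in_a_block(self, tiny_dataset):
        design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        assert len(design.layout.animal_ids) == tiny_dataset.pedigree.n
        assert len(design.layout.animal_ids) > tiny_dataset.records["animal"].nunique()


class TestLikelihood:
    def test_matches_dense_oracle_up_to_constant(self, tiny_dataset):
        design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        off1 = dense_neg2_reml(tiny_dataset, "LMA", 1, VC1) - reml_neg2_loglik(VC1, design)
        off2 = dense_neg2_reml(tiny_dataset, "LMA", 1, VC2) - reml_neg2_loglik(VC2, design)
        assert off1 == pytest.approx(off2, abs=1e-6)

    def test_record_order_invariance(self, tiny_dataset):
        design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        shuffled = StudyDataset(
            records=tiny_dataset.records.sample(frac=1.0, random_state=5),
            pedigree=tiny_dataset.pedigree,
        )
        design2 = UnivariateDesign.from_dataset(shuffled, "LMA", 1)
        assert reml_neg2_loglik(VC1, design) == pytest.approx(
            reml_neg2_loglik(VC1, design2), abs=1e-8
        )

    def test_scaling_shift(self, tiny_dataset):
        k = 1.7
        scaled = StudyDataset(
            records=tiny_dataset.records.assign(value=tiny_dataset.records["value"] * k),
            pedigree=tiny_dataset.pedigree,
        )
        d1 = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        d2 = UnivariateDesign.from_dataset(scaled, "LMA", 1)
        shift = reml_neg2_loglik(VC1.scaled(k**2), d2) - reml_neg2_loglik(VC1, d1)
        assert shift == pytest.approx((d1.n - 1) * np.log(k**2), abs=1e-8)

    def test_nonpositive_components_rejected(self, tiny_dataset):
        design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        with pytest.raises(InvalidComponentsError):
            reml_neg2_loglik(VarianceComponents(1.0, 1.0, 0.0, 1.0), design)


class TestSolveEbv:
    def test_matches_dense_blup(self, tiny_dataset):
        design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        mu, table = solve_ebv(design, VC1)
        mu_d, u_d = dense_blup(tiny_dataset, "LMA", 1, VC1)
        assert mu == pytest.approx(mu_d, abs=1e-8)
        np.testing.assert_allclose(table["ebv"].to_numpy(), u_d, atol=1e-8)

    def test_unconnected_animal_zero(self):
        ds = _records_dataset(
            [
                ("A1", "ANGUS", "LMA", 80.0, "T1", "CG1", 1, 400),
                ("A2", "ANGUS", "LMA", 84.0, "T1", "CG1", 1, 400),
            ],
            [("A1", None, None), ("A2", None, None), ("LONER", None, None)],
        )
        design = UnivariateDesign.from_dataset(ds, "LMA", 1)
        _, table = solve_ebv(design, VC1)
        row = table.set_index("animal").loc["LONER"]
        assert row["ebv"] == pytest.approx(0.0, abs=1e-10)
        assert row["accuracy"] == pytest.approx(0.0, abs=1e-8)

    def test_more_progeny_higher_accuracy(self):
        # CGs must mix families with unrelated herdmates, otherwise the CG
        # effect absorbs the family mean and the sires' PEVs coincide
        rows, entries = [], [("SBIG", None, None), ("SONE", None, None)]
        k = 0
        for cg in range(3):
            for _ in range(3):
                rows.append((f"P{k}", "ANGUS", "LMA", 80.0, "T1", f"CG{cg}", 1, 400))
                entries.append((f"P{k}", "SBIG", None))
                k += 1
            for j in range(2):
                rows.append((f"U{cg}_{j}", "ANGUS", "LMA", 80.0, "T1", f"CG{cg}", 1, 400))
                entries.append((f"U{cg}_{j}", None, None))
        rows.append(("Q0", "ANGUS", "LMA", 83.0, "T1", "CG0", 1, 400))
        entries.append(("Q0", "SONE", None))
        ds = _records_dataset(rows, entries)
        design = UnivariateDesign.from_dataset(ds, "LMA", 1)
        _, table = solve_ebv(design, VC1, pev_animals=["SBIG", "SONE"])
        acc = table.set_index("animal")["accuracy"]
        assert acc["SBIG"] > acc["SONE"]


class TestFitUnivariate:
    def test_balanced_design_matches_anova(self):
        """On a balanced nested design with unrelated single-record animals,
        REML equals the ANOVA components for technician and CG, and the
        additive+residual sum (the two are confounded without a pedigree)."""
        rng = np.random.default_rng(11)
        n_t, n_c, n_r = 6, 5, 8
        st2, sc2, se2 = 4.0, 2.5, 3.0
        rows, entries = [], []
        values = np.zeros((n_t, n_c, n_r))
        for t in range(n_t):
            te = rng.normal(0, np.sqrt(st2))
            for c in range(n_c):
                ce = rng.normal(0, np.sqrt(sc2))
                for r in range(n_r):
                    v = 50.0 + te + ce + rng.normal(0, np.sqrt(se2))
                    values[t, c, r] = v
                    a = f"A{t}_{c}_{r}"
                    rows.append((a, "ANGUS", "LMA", v, f"T{t}", f"CG{t}_{c}", 1, 400))
                    entries.append((a, None, None))
        ds = _records_dataset(rows, entries)
        design = UnivariateDesign.from_dataset(ds, "LMA", 1)
        fit = fit_univariate(
            design, options=FitOptions(n_restarts=0, compute_ebv=False)
        )
        # balanced nested ANOVA expected mean squares
        grand = values.mean()
        ms_t = n_c * n_r * ((values.mean(axis=(1, 2)) - grand) ** 2).sum() / (n_t - 1)
        ms_c = n_r * ((values.mean(axis=2) - values.mean(axis=(1, 2))[:, None]) ** 2).sum() / (
            n_t * (n_c - 1)
        )
        ms_e = ((values - values.mean(axis=2)[:, :, None]) ** 2).sum() / (
            n_t * n_c * (n_r - 1)
        )
        anova_e = ms_e
        anova_c = (ms_c - ms_e) / n_r
        anova_t = (ms_t - ms_c) / (n_c * n_r)
        vc = fit.components
        assert vc.sigma2_a + vc.sigma2_e == pytest.approx(anova_e, rel=1e-2)
        assert vc.sigma2_c == pytest.approx(anova_c, rel=1e-2)
        assert vc.sigma2_t == pytest.approx(anova_t, rel=1e-2)

    def test_restart_agreement(self):
        cfg = SimulationConfig(
            n_labs=1,
            technicians_per_lab=5,
            cgs_per_technician=4,
            animals_per_cg=8,
            n_sires=10,
            n_dams=40,
            true_vc={"LMA": VarianceComponents(5.0, 8.0, 4.0, 6.0)},
            mu={"LMA": 50.0},
            seed=3,
            three_generation=False,
        )
        ds = simulate_dataset(cfg)
        design = UnivariateDesign.from_dataset(ds, "LMA", 1)
        fit = fit_univariate(
            design,
            start=cfg.true_vc["LMA"],
            options=FitOptions(
                n_restarts=2,
                restart_scales=(0.5, 2.0),
                compute_ebv=False,
                fvar_tol=1e-14,  # tightened below the default stopping rule
                max_cycles=40,
            ),
        )
        assert fit.converged
        for f in fit.restart_neg2_logL:
            assert abs(f - fit.neg2_logL) < 1e-6
        assert fit.n_restarts_agreeing == 2

    def test_zero_technician_variance_hits_floor(self):
        cfg = SimulationConfig(
            n_labs=1,
            technicians_per_lab=4,
            cgs_per_technician=4,
            animals_per_cg=6,
            n_sires=8,
            n_dams=30,
            true_vc={"LMA": VarianceComponents(1e-12, 8.0, 4.0, 6.0)},
            mu={"LMA": 50.0},
            seed=2,
            three_generation=False,
        )
        ds = simulate_dataset(cfg)
        design = UnivariateDesign.from_dataset(ds, "LMA", 1)
        fit = fit_univariate(design, options=FitOptions(n_restarts=0, compute_ebv=False))
        assert fit.components.sigma2_t < 0.05 * design.var_y

    def test_relabeling_invariance(self, tiny_dataset):
        design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
        fit = fit_univariate(design, options=FitOptions(n_restarts=0, compute_ebv=False))
        renamed = tiny_dataset.records.copy()
        renamed["technician"] = renamed["technician"].map(lambda t: f"zz_{t}")
        renamed["cg"] = renamed["cg"].map(lambda c: f"qq_{c}")
        ds2 = StudyDataset(records=renamed, pedigree=tiny_dataset.pedigree)
        fit2 = fit_univariate(
            UnivariateDesign.from_dataset(ds2, "LMA", 1),
            options=FitOptions(n_restarts=0, compute_ebv=False),
        )
        np.testing.assert_allclose(
            fit.components.as_array(), fit2.components.as_array(), rtol=1e-4
        )


def test_component_covariance_positive(tiny_dataset):
    design = UnivariateDesign.from_dataset(tiny_dataset, "LMA", 1)
    fit = fit_univariate(design, options=FitOptions(n_restarts=0, compute_ebv=False))
    cov = component_covariance(design, fit.components)
    if not np.any(np.isnan(cov)):
        assert np.all(np.diag(cov) >= 0)
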