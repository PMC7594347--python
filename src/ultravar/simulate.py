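"""Synthetic study generator.

Emulates the structure of a breed-association ultrasound data set: a
multi-generation pedigree with paternal half-sib families, contemporary
groups nested within a single technician, technicians reporting to exactly
one of up to three interpretation laboratories, each animal recorded in
exactly one laboratory, and phenotypes built as
y = mu_lab + technician + CG + breeding value + residual with the
configured true variances.  A single seed drives three split RNG streams
(pedigree/structure, breeding values, environmental effects) so changing
one configuration field perturbs only the matching component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .multitrait import MultiTraitComponents
from .pedigree import Pedigree, PedigreeMode
from .phenotypes import AGE_WINDOWS, Breed, StudyDataset, Trait
from .reference import components as ref_components, pheno_mean
from .reml import VarianceComponents

TraitTruth = VarianceComponents | MultiTraitComponents


@dataclass
class SimulationConfig:
    """Full description of a synthetic study.

    ``true_vc`` maps trait name to either a :class:`VarianceComponents`
    (same truth in every lab, between-lab genetic correlation 1) or a
    :class:`MultiTraitComponents` (per-lab variances and a 3x3 G0).
    ``mu`` maps trait name to a scalar or per-lab means.
    ``sire_sharing`` is the fraction of sires usable in every lab; the rest
    are split lab-exclusively, which controls identifiability of the
    between-lab genetic covariances.
    """

    n_labs: int = 3
    technicians_per_lab: int = 6
    cgs_per_technician: int = 8
    animals_per_cg: int = 10
    n_sires: int = 100
    n_dams: int = 500
    sire_sharing: float = 1.0
    true_vc: dict[str, TraitTruth] = field(default_factory=dict)
    mu: dict[str, float | np.ndarray] = field(default_factory=dict)
    breed: Breed = Breed.ANGUS
    seed: int = 0
    three_generation: bool = True
    cg_size_dispersion: float | None = None  # neg-binomial size heterogeneity
    #: record dams as unknown: pure paternal half-sib families (keeps the
    #: pedigree, and hence the animal block of the MME, minimal)
    dams_unknown: bool = False

    def __post_init__(self) -> None:
        for name, v in [
            ("n_labs", self.n_labs),
            ("technicians_per_lab", self.technicians_per_lab),
            ("cgs_per_technician", self.cgs_per_technician),
            ("animals_per_cg", self.animals_per_cg),
            ("n_sires", self.n_sires),
            ("n_dams", self.n_dams),
        ]:
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        self.breed = Breed(str(getattr(self.breed, "value", self.breed)).upper())

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def truth_dict(t: TraitTruth):
            if isinstance(t, VarianceComponents):
                return {
                    "kind": "univariate",
                    "sigma2_t": t.sigma2_t,
                    "sigma2_c": t.sigma2_c,
                    "sigma2_a": t.sigma2_a,
                    "sigma2_e": t.sigma2_e,
                }
            return {
                "kind": "multitrait",
                "sigma2_t": list(map(float, t.sigma2_t)),
                "sigma2_c": list(map(float, t.sigma2_c)),
                "sigma2_e": list(map(float, t.sigma2_e)),
                "G0": [list(map(float, row)) for row in t.G0],
            }

        return {
            "n_labs": self.n_labs,
            "technicians_per_lab": self.technicians_per_lab,
            "cgs_per_technician": self.cgs_per_technician,
            "animals_per_cg": self.animals_per_cg,
            "n_sires": self.n_sires,
            "n_dams": self.n_dams,
            "sire_sharing": self.sire_sharing,
            "true_vc": {k: truth_dict(v) for k, v in self.true_vc.items()},
            "mu": {
                k: (float(v) if np.isscalar(v) else list(map(float, v)))
                for k, v in self.mu.items()
            },
            "breed": self.breed.value,
            "seed": self.seed,
            "three_generation": self.three_generation,
            "cg_size_dispersion": self.cg_size_dispersion,
            "dams_unknown": self.dams_unknown,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        def truth(t: dict) -> TraitTruth:
            if t["kind"] == "univariate":
                return VarianceComponents(
                    t["sigma2_t"], t["sigma2_c"], t["sigma2_a"], t["sigma2_e"]
                )
            return MultiTraitComponents(
                np.array(t["sigma2_t"]),
                np.array(t["sigma2_c"]),
                np.array(t["sigma2_e"]),
                np.array(t["G0"]),
            )

        d = dict(d)
        d["true_vc"] = {k: truth(v) for k, v in d.get("true_vc", {}).items()}
        d["mu"] = {
            k: (v if np.isscalar(v) else np.asarray(v, dtype=float))
            for k, v in d.get("mu", {}).items()
        }
        d["breed"] = Breed(d.get("breed", "ANGUS"))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _streams(cfg: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return {
        "pedigree": np.random.default_rng(children[0]),
        "bv": np.random.default_rng(children[1]),
        "effects": np.random.default_rng(children[2]),
    }


def _structure(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Recorded-animal skeleton: lab, technician, CG, sire, dam, age."""
    n_shared = int(round(cfg.sire_sharing * cfg.n_sires))
    sires = [f"S{i:05d}" for i in range(1, cfg.n_sires + 1)]
    shared, exclusive = sires[:n_shared], sires[n_shared:]
    rows = []
    k = 0
    lo, hi = AGE_WINDOWS[cfg.breed]
    for lab in range(1, cfg.n_labs + 1):
        pool = shared + exclusive[(lab - 1) :: cfg.n_labs]
        if not pool:
            pool = shared or sires
        for t in range(cfg.technicians_per_lab):
            tech = f"T{lab}{t + 1:03d}"
            for c in range(cfg.cgs_per_technician):
                cg = f"CG{lab}{t + 1:03d}{c + 1:03d}"
                size = cfg.animals_per_cg
                if cfg.cg_size_dispersion:
                    # negative-binomial sizes with the configured mean
                    r = cfg.cg_size_dispersion
                    p = r / (r + cfg.animals_per_cg - 1)
                    size = 1 + rng.negative_binomial(r, p)
                for _ in range(size):
                    k += 1
                    rows.append(
                        {
                            "animal": f"A{k:06d}",
                            "lab": lab,
                            "technician": tech,
                            "cg": cg,
                            "sire": pool[rng.integers(len(pool))],
                            "dam": (
                                None
                                if cfg.dams_unknown
                                else f"D{rng.integers(cfg.n_dams) + 1:05d}"
                            ),
                            "age_days": int(rng.integers(lo, hi + 1)),
                        }
                    )
    return pd.DataFrame(rows)


def _pedigree_from_structure(
    cfg: SimulationConfig, struct: pd.DataFrame, rng: np.random.Generator
) -> Pedigree:
    entries: list[tuple[str, str | None, str | None]] = []
    sires = [f"S{i:05d}" for i in range(1, cfg.n_sires + 1)]
    dams = sorted(d for d in struct["dam"].unique() if d is not None)
    if cfg.three_generation:
        n_gs = max(2, cfg.n_sires // 4)
        n_gd = max(2, cfg.n_dams // 4)
        grandsires = [f"GS{i:04d}" for i in range(1, n_gs + 1)]
        granddams = [f"GD{i:04d}" for i in range(1, n_gd + 1)]
        entries += [(g, None, None) for g in grandsires + granddams]
        for a in sires + dams:
            entries.append(
                (
                    a,
                    grandsires[rng.integers(n_gs)],
                    granddams[rng.integers(n_gd)],
                )
            )
    else:
        entries += [(a, None, None) for a in sires + dams]
    for _, row in struct.iterrows():
        entries.append((row["animal"], row["sire"], row["dam"]))
    return Pedigree.from_entries(entries, mode=PedigreeMode.SIRE_DAM)


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Pedigree of founders plus recorded generation(s) under ``cfg``."""
    rng = _streams(cfg)["pedigree"]
    struct = _structure(cfg, rng)
    return _pedigree_from_structure(cfg, struct, rng)


def simulate_breeding_values(
    ped: Pedigree,
    genetic: float | np.ndarray,
    rng: np.random.Generator | int,
) -> dict[str, np.ndarray]:
    """Breeding values down the pedigree.

    ``genetic`` is a scalar additive variance or a covariance matrix G0
    (one BV per lab-trait).  Founders draw from N(0, G0); a non-founder is
    the mean of its known parents' values plus a Mendelian-sampling
    deviation with variance 0.5 G0 (both parents known), 0.75 G0 (one) or
    G0 (none).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    G = np.atleast_2d(np.asarray(genetic, dtype=float))
    dim = G.shape[0]
    chol = np.linalg.cholesky(G) if np.any(G) else np.zeros_like(G)
    p1, p2 = ped.parent_indices()
    bv = np.zeros((ped.n, dim))
    noise = rng.standard_normal((ped.n, dim))
    for i in range(ped.n):
        s, d = p1[i], p2[i]
        if s >= 0 and d >= 0:
            mean, msv = 0.5 * (bv[s] + bv[d]), 0.5
        elif s >= 0 or d >= 0:
            mean, msv = 0.5 * bv[max(s, d)], 0.75
        else:
            mean, msv = 0.0, 1.0
        bv[i] = mean + np.sqrt(msv) * (chol @ noise[i])
    if dim == 1:
        return {a: bv[i, 0] for i, a in enumerate(ped.animals)}
    return {a: bv[i] for i, a in enumerate(ped.animals)}


def _per_lab(x, n_labs: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return np.full(n_labs, float(arr)) if arr.ndim == 0 else arr


def simulate_dataset(cfg: SimulationConfig) -> StudyDataset:
    """Full synthetic study: records plus pedigree, valid by construction."""
    if not cfg.true_vc:
        raise ValueError("config.true_vc must name at least one trait")
    streams = _streams(cfg)
    struct = _structure(cfg, streams["pedigree"])
    ped = _pedigree_from_structure(cfg, struct, streams["pedigree"])
    rng_e = streams["effects"]
    animal_lab = struct["lab"].to_numpy() - 1
    frames = []
    for trait, truth in cfg.true_vc.items():
        trait = Trait(trait).value
        if isinstance(truth, VarianceComponents):
            st = _per_lab(truth.sigma2_t, cfg.n_labs)
            sc = _per_lab(truth.sigma2_c, cfg.n_labs)
            se = _per_lab(truth.sigma2_e, cfg.n_labs)
            bv_map = simulate_breeding_values(ped, truth.sigma2_a, streams["bv"])
            bv = np.array([bv_map[a] for a in struct["animal"]])
        else:
            st, sc, se = truth.sigma2_t, truth.sigma2_c, truth.sigma2_e
            bv_map = simulate_breeding_values(ped, truth.G0, streams["bv"])
            bv = np.array(
                [bv_map[a][l] for a, l in zip(struct["animal"], animal_lab)]
            )
        mu = _per_lab(cfg.mu.get(trait, 0.0), cfg.n_labs)
        tech_ids = struct["technician"].unique()
        tech_lab = {t: int(t[1]) - 1 for t in tech_ids}
        t_eff = {
            t: rng_e.normal(0.0, np.sqrt(st[tech_lab[t]])) for t in sorted(tech_ids)
        }
        cg_ids = sorted(struct["cg"].unique())
        cg_lab = {c: int(c[2]) - 1 for c in cg_ids}
        c_eff = {c: rng_e.normal(0.0, np.sqrt(sc[cg_lab[c]])) for c in cg_ids}
        resid = rng_e.standard_normal(len(struct)) * np.sqrt(se[animal_lab])
        y = (
            mu[animal_lab]
            + struct["technician"].map(t_eff).to_numpy()
            + struct["cg"].map(c_eff).to_numpy()
            + bv
            + resid
        )
        frames.append(
            pd.DataFrame(
                {
                    "animal": struct["animal"],
                    "breed": cfg.breed.value,
                    "trait": trait,
                    "value": y,
                    "technician": struct["technician"],
                    "cg": struct["cg"],
                    "lab": struct["lab"],
                    "age_days": struct["age_days"],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return StudyDataset(records=records, pedigree=ped)


def write_fixture(ds: StudyDataset, outdir, cfg: SimulationConfig) -> dict[str, Path]:
    """Emit records CSV, pedigree CSV, config YAML and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "pedigree": outdir / "pedigree.csv",
        "config": outdir / "config.yaml",
        "truth": outdir / "truth.json",
    }
    ds.records.to_csv(paths["records"], index=False)
    ds.pedigree.write(paths["pedigree"])
    cfg.to_yaml(paths["config"])
    with open(paths["truth"], "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)
    return paths


# -- canonical scenarios -------------------------------------------------


def angus_lab1_lma_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default univariate scenario: Angus LMA, lab 1 truth, half-sib families."""
    base = dict(
        n_labs=1,
        technicians_per_lab=10,
        cgs_per_technician=8,
        animals_per_cg=10,
        n_sires=80,
        n_dams=400,
        sire_sharing=1.0,
        true_vc={"LMA": ref_components(Breed.ANGUS, Trait.LMA, 1)},
        mu={"LMA": pheno_mean(Breed.ANGUS, Trait.LMA, 1)},
        breed=Breed.ANGUS,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def lab_as_trait_config(
    rg: float = 0.9, seed: int = 0, **overrides
) -> SimulationConfig:
    """Trivariate scenario: Angus LMA per-lab truths, ~300 shared sires.

    The genetic covariance G0 has the published per-lab additive variances
    on its diagonal and correlation ``rg`` between every lab pair.
    """
    sa = np.array(
        [ref_components(Breed.ANGUS, Trait.LMA, lab).sigma2_a for lab in (1, 2, 3)]
    )
    G0 = rg * np.sqrt(np.outer(sa, sa))
    np.fill_diagonal(G0, sa)
    per_lab = [ref_components(Breed.ANGUS, Trait.LMA, lab) for lab in (1, 2, 3)]
    truth = MultiTraitComponents(
        np.array([v.sigma2_t for v in per_lab]),
        np.array([v.sigma2_c for v in per_lab]),
        np.array([v.sigma2_e for v in per_lab]),
        G0,
    )
    mu = np.array([pheno_mean(Breed.ANGUS, Trait.LMA, lab) for lab in (1, 2, 3)])
    base = dict(
        n_labs=3,
        technicians_per_lab=10,
        cgs_per_technician=8,
        animals_per_cg=12,
        n_sires=300,
        n_dams=720,
        sire_sharing=1.0,
        true_vc={"LMA": truth},
        mu={"LMA": mu},
        breed=Breed.ANGUS,
        seed=seed,
        three_generation=False,
        dams_unknown=True,
    )
    base.update(overrides)
    return SimulationConfig(**base)
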