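"""Phenotype records, structural validation, and the breed age-window filter.

A record is one ultrasound measurement of a carcass trait on a live animal:
longissimus muscle area (LMA, cm^2), subcutaneous fat depth (SFD, mm) or
percent intramuscular fat (IMF, %).  Images are collected on contemporary
groups (herd x scan date x sex cohorts) by field technicians, and each
technician reports to exactly one of three image-interpretation
laboratories.  The variance-partitioning models rely on that nesting
(CG within technician within laboratory), which is what
:func:`validate_structure` checks.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import pandas as pd

from .pedigree import Pedigree


class Trait(str, enum.Enum):
    LMA = "LMA"  # longissimus muscle area, cm^2
    SFD = "SFD"  # subcutaneous fat depth, mm
    IMF = "IMF"  # intramuscular fat, %


class Breed(str, enum.Enum):
    ANGUS = "ANGUS"
    HEREFORD = "HEREFORD"
    SIMMENTAL = "SIMMENTAL"


#: Closed age-at-scan windows (days) accepted for genetic evaluation, per breed.
AGE_WINDOWS: dict[Breed, tuple[int, int]] = {
    Breed.ANGUS: (320, 460),
    Breed.SIMMENTAL: (270, 500),
    Breed.HEREFORD: (301, 530),
}

#: Plausibility bounds per trait (observed extremes padded ~20%); violations
#: warn rather than error because records are analyzed exactly as provided.
PLAUSIBILITY: dict[Trait, tuple[float, float]] = {
    Trait.LMA: (20.0, 160.0),
    Trait.SFD: (0.2, 28.0),
    Trait.IMF: (0.25, 13.0),
}

RECORD_COLUMNS = ["animal", "breed", "trait", "value", "technician", "cg", "lab", "age_days"]


@dataclass
class UltrasoundRecord:
    """A single phenotype observation."""

    animal_id: str
    trait: Trait
    value: float
    technician_id: str
    cg_id: str
    lab_id: int
    age_days: int
    breed: Breed


@dataclass
class StudyDataset:
    """Phenotype records plus the pedigree covering every recorded animal."""

    records: pd.DataFrame
    pedigree: Pedigree

    def subset(self, trait: Trait | str | None = None, lab: int | None = None) -> pd.DataFrame:
        df = self.records
        if trait is not None:
            df = df[df["trait"] == str(getattr(trait, "value", trait))]
        if lab is not None:
            df = df[df["lab"] == int(lab)]
        return df

    @property
    def labs(self) -> list[int]:
        return sorted(int(l) for l in self.records["lab"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())


def read_records(path) -> pd.DataFrame:
    """Read a records CSV (header ``animal,breed,trait,value,technician,cg,lab,age_days``)."""
    df = pd.read_csv(
        path,
        dtype={
            "animal": str,
            "breed": str,
            "trait": str,
            "technician": str,
            "cg": str,
        },
    )
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    df["lab"] = df["lab"].astype(int)
    df["age_days"] = df["age_days"].astype(int)
    df["value"] = df["value"].astype(float)
    _warn_implausible(df)
    return df[RECORD_COLUMNS]


def write_records(df: pd.DataFrame, path) -> None:
    df[RECORD_COLUMNS].to_csv(path, index=False)


def _warn_implausible(df: pd.DataFrame) -> None:
    for trait, (lo, hi) in PLAUSIBILITY.items():
        sub = df[df["trait"] == trait.value]
        bad = sub[(sub["value"] < lo) | (sub["value"] > hi)]
        if len(bad):
            warnings.warn(
                f"{len(bad)} {trait.value} values outside plausible range "
                f"[{lo}, {hi}]; kept as provided",
                stacklevel=3,
            )


def validate_structure(ds: StudyDataset) -> list[str]:
    """Check the nesting structure the models assume.

    Returns a list of human-readable violations; an empty list means valid.
    Checked: each contemporary group scanned by one technician; each
    technician reporting to one laboratory; each recorded animal present in
    the pedigree; at most one record per animal x trait (the model carries
    no permanent-environment effect, so repeated measures are rejected).
    """
    df = ds.records
    violations: list[str] = []
    cg_tech = df.groupby("cg")["technician"].nunique()
    for cg in cg_tech[cg_tech > 1].index:
        techs = sorted(df.loc[df["cg"] == cg, "technician"].unique())
        violations.append(f"contemporary group {cg!r} scanned by multiple technicians: {techs}")
    tech_lab = df.groupby("technician")["lab"].nunique()
    for tech in tech_lab[tech_lab > 1].index:
        labs = sorted(df.loc[df["technician"] == tech, "lab"].unique())
        violations.append(f"technician {tech!r} reports to multiple labs: {labs}")
    missing = sorted(set(df["animal"]) - set(ds.pedigree.index))
    for a in missing:
        violations.append(f"recorded animal {a!r} absent from pedigree")
    dup = df.duplicated(subset=["animal", "trait"])
    for _, row in df[dup].iterrows():
        violations.append(
            f"animal {row['animal']!r} has repeated {row['trait']} records"
        )
    return violations


def filter_age_window(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep records whose age at scan lies in the closed breed-specific window.

    Returns the kept records and the dropped count.  Unknown breed -> error.
    """
    if len(records) == 0:
        return records, 0
    windows = {}
    for b in records["breed"].unique():
        try:
            windows[b] = AGE_WINDOWS[Breed(b)]
        except ValueError:
            raise ValueError(f"unknown breed {b!r}") from None
    lo = records["breed"].map(lambda b: windows[b][0])
    hi = records["breed"].map(lambda b: windows[b][1])
    keep = (records["age_days"] >= lo) & (records["age_days"] <= hi)
    return records[keep], int((~keep).sum())


def summarize_dataset(ds: StudyDataset) -> pd.DataFrame:
    """Per breed x trait x lab description: counts, mean, SD, min, max.

    SD is reported as 0.0 for single-record cells (flagged via n).
    """
    rows = []
    for (breed, trait, lab), g in ds.records.groupby(["breed", "trait", "lab"], sort=True):
        rows.append(
            {
                "breed": breed,
                "trait": trait,
                "lab": lab,
                "n_records": len(g),
                "n_technicians": g["technician"].nunique(),
                "n_cgs": g["cg"].nunique(),
                "mean": g["value"].mean(),
                "sd": g["value"].std(ddof=1) if len(g) > 1 else 0.0,
                "min": g["value"].min(),
                "max": g["value"].max(),
            }
        )
    return pd.DataFrame(rows)
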