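"""Published reference estimates used as simulation defaults and inputs.

Variance-component estimates (technician, CG-within-technician, additive
genetic, residual) for LMA, SFD and IMF by breed and interpretation
laboratory, from the national breed-association ultrasound evaluation this
package models, together with the corresponding phenotypic means.  These
are inputs: the synthetic-data generator uses them as true parameters, and
the derived statistics (heritability, percentage partitions, dispersion)
are recomputed from them at run time.
"""

from __future__ import annotations

from .phenotypes import Breed, Trait
from .reml import VarianceComponents

__all__ = ["COMPONENTS", "PHENO_MEANS", "components", "pheno_mean"]

# (breed, trait, lab) -> VarianceComponents(sigma2_t, sigma2_c, sigma2_a, sigma2_e)
_C = VarianceComponents
COMPONENTS: dict[tuple[Breed, Trait, int], VarianceComponents] = {
    # LMA, cm^4
    (Breed.ANGUS, Trait.LMA, 1): _C(53.98, 124.13, 16.87, 35.06),
    (Breed.ANGUS, Trait.LMA, 2): _C(42.58, 162.95, 16.65, 45.10),
    (Breed.ANGUS, Trait.LMA, 3): _C(13.40, 129.10, 17.41, 29.28),
    (Breed.HEREFORD, Trait.LMA, 1): _C(34.24, 120.75, 18.85, 30.50),
    (Breed.HEREFORD, Trait.LMA, 2): _C(15.57, 169.03, 20.45, 35.97),
    (Breed.HEREFORD, Trait.LMA, 3): _C(8.14, 143.16, 14.75, 28.11),
    (Breed.SIMMENTAL, Trait.LMA, 1): _C(57.21, 93.89, 27.31, 38.60),
    (Breed.SIMMENTAL, Trait.LMA, 2): _C(60.64, 126.81, 33.35, 40.31),
    (Breed.SIMMENTAL, Trait.LMA, 3): _C(49.98, 133.84, 30.57, 30.67),
    # SFD, mm^2
    (Breed.ANGUS, Trait.SFD, 1): _C(1.48, 3.58, 0.98, 1.64),
    (Breed.ANGUS, Trait.SFD, 2): _C(0.92, 4.26, 0.87, 1.79),
    (Breed.ANGUS, Trait.SFD, 3): _C(1.44, 3.46, 1.08, 1.42),
    (Breed.HEREFORD, Trait.SFD, 1): _C(0.64, 3.18, 0.86, 2.04),
    (Breed.HEREFORD, Trait.SFD, 2): _C(0.33, 3.27, 0.80, 1.93),
    (Breed.HEREFORD, Trait.SFD, 3): _C(1.68, 3.16, 0.74, 1.75),
    (Breed.SIMMENTAL, Trait.SFD, 1): _C(1.15, 1.58, 1.43, 1.59),
    (Breed.SIMMENTAL, Trait.SFD, 2): _C(0.70, 1.35, 0.92, 1.32),
    (Breed.SIMMENTAL, Trait.SFD, 3): _C(1.24, 2.17, 0.93, 1.15),
    # IMF, %^2
    (Breed.ANGUS, Trait.IMF, 1): _C(0.43, 0.56, 0.34, 0.37),
    (Breed.ANGUS, Trait.IMF, 2): _C(0.21, 0.73, 0.52, 0.26),
    (Breed.ANGUS, Trait.IMF, 3): _C(0.33, 1.03, 0.51, 0.41),
    (Breed.HEREFORD, Trait.IMF, 1): _C(0.21, 0.37, 0.16, 0.27),
    (Breed.HEREFORD, Trait.IMF, 2): _C(0.07, 0.23, 0.15, 0.13),
    (Breed.HEREFORD, Trait.IMF, 3): _C(0.20, 0.69, 0.24, 0.32),
    (Breed.SIMMENTAL, Trait.IMF, 1): _C(0.27, 0.26, 0.28, 0.23),
    (Breed.SIMMENTAL, Trait.IMF, 2): _C(0.10, 0.22, 0.17, 0.16),
    (Breed.SIMMENTAL, Trait.IMF, 3): _C(0.18, 0.55, 0.31, 0.26),
}

# (breed, trait, lab) -> phenotypic mean in trait units
PHENO_MEANS: dict[tuple[Breed, Trait, int], float] = {
    (Breed.ANGUS, Trait.LMA, 1): 78.2,
    (Breed.ANGUS, Trait.LMA, 2): 79.1,
    (Breed.ANGUS, Trait.LMA, 3): 75.8,
    (Breed.ANGUS, Trait.SFD, 1): 6.79,
    (Breed.ANGUS, Trait.SFD, 2): 7.36,
    (Breed.ANGUS, Trait.SFD, 3): 6.73,
    (Breed.ANGUS, Trait.IMF, 1): 4.14,
    (Breed.ANGUS, Trait.IMF, 2): 4.67,
    (Breed.ANGUS, Trait.IMF, 3): 4.72,
    (Breed.HEREFORD, Trait.LMA, 1): 70.6,
    (Breed.HEREFORD, Trait.LMA, 2): 69.3,
    (Breed.HEREFORD, Trait.LMA, 3): 65.8,
    (Breed.HEREFORD, Trait.SFD, 1): 5.74,
    (Breed.HEREFORD, Trait.SFD, 2): 5.96,
    (Breed.HEREFORD, Trait.SFD, 3): 5.62,
    (Breed.HEREFORD, Trait.IMF, 1): 3.00,
    (Breed.HEREFORD, Trait.IMF, 2): 3.45,
    (Breed.HEREFORD, Trait.IMF, 3): 3.46,
    (Breed.SIMMENTAL, Trait.LMA, 1): 86.0,
    (Breed.SIMMENTAL, Trait.LMA, 2): 80.5,
    (Breed.SIMMENTAL, Trait.LMA, 3): 80.3,
    (Breed.SIMMENTAL, Trait.SFD, 1): 5.72,
    (Breed.SIMMENTAL, Trait.SFD, 2): 5.47,
    (Breed.SIMMENTAL, Trait.SFD, 3): 5.07,
    (Breed.SIMMENTAL, Trait.IMF, 1): 3.06,
    (Breed.SIMMENTAL, Trait.IMF, 2): 3.72,
    (Breed.SIMMENTAL, Trait.IMF, 3): 3.57,
}


def components(breed: Breed | str, trait: Trait | str, lab: int) -> VarianceComponents:
    return COMPONENTS[(Breed(str(getattr(breed, "value", breed)).upper()), Trait(str(getattr(trait, "value", trait)).upper()), int(lab))]


def pheno_mean(breed: Breed | str, trait: Trait | str, lab: int) -> float:
    return PHENO_MEANS[(Breed(str(getattr(breed, "value", breed)).upper()), Trait(str(getattr(trait, "value", trait)).upper()), int(lab))]
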