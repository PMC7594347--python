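import numpy as np
import pytest

from ultravar.pedigree import Pedigree
from ultravar.reml import VarianceComponents
from ultravar.simulate import SimulationConfig, simulate_dataset


def random_pedigree(n: int, seed: int, n_founders: int = 5) -> Pedigree:
    """Random acyclic pedigree with ``n`` animals (including founders)."""
    rng = np.random.default_rng(seed)
    entries, ids = [], []
    for i in range(n):
        a = f"X{i}"
        if i < n_founders:
            entries.append((a, "0", "0"))
        else:
            s, d = rng.choice(ids, size=2, replace=False)
            # occasionally drop a parent to exercise unknown-parent rules
            if rng.random() < 0.15:
                d = "0"
            entries.append((a, str(s), str(d)))
        ids.append(a)
    return Pedigree.from_entries(entries)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A dataset small enough for dense-oracle comparisons (n <= 30 records)."""
    return SimulationConfig(
        n_labs=1,
        technicians_per_lab=2,
        cgs_per_technician=2,
        animals_per_cg=5,
        n_sires=4,
        n_dams=8,
        true_vc={"LMA": VarianceComponents(5.0, 8.0, 4.0, 6.0)},
        mu={"LMA": 50.0},
        seed=3,
        three_generation=False,
    )


@pytest.fixture
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)
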