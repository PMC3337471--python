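import numpy as np
import pandas as pd
import pytest

from genoval.pedigree import Pedigree
from genoval.simulate import SimConfig, simulate_population


@pytest.fixture
def trio_ped() -> Pedigree:
    """Two unrelated founders and one offspring."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["S", "D", "X"],
                "sire": ["0", "0", "S"],
                "dam": ["0", "0", "D"],
            }
        )
    )


@pytest.fixture
def fullsib_ped() -> Pedigree:
    """Founders A,B; full sibs C,D; E is an offspring of the full sibs."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["A", "B", "C", "D", "E"],
                "sire": ["0", "0", "A", "A", "C"],
                "dam": ["0", "0", "B", "B", "D"],
            }
        )
    )


SMALL_CFG = SimConfig(
    n_founders=30,
    n_generations=3,
    sires_per_generation=4,
    dams_per_sire=5,
    litter_size=4,
    n_snp=200,
    n_qtl_per_trait=40,
    rng_seed=7,
)

MEDIUM_CFG = SimConfig(
    n_founders=50,
    n_generations=3,
    sires_per_generation=6,
    dams_per_sire=8,
    litter_size=5,
    n_snp=600,
    n_qtl_per_trait=80,
    rng_seed=13,
)


@pytest.fixture(scope="session")
def small_pop():
    """~270-animal nucleus population with pEBV attached."""
    return simulate_population(SMALL_CFG)


@pytest.fixture(scope="session")
def medium_pop():
    """~770-animal population for calibration-level checks."""
    return simulate_population(MEDIUM_CFG)


def random_pedigree_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random valid pedigree: parents sampled among earlier animals."""
    sire, dam, sex = [], [], []
    for i in range(n):
        males = [j for j in range(i) if sex[j] == "M"]
        females = [j for j in range(i) if sex[j] == "F"]
        if males and females and rng.random() < 0.8:
            sire.append(str(rng.choice(males) + 1))
            dam.append(str(rng.choice(females) + 1))
        else:
            sire.append("0")
            dam.append("0")
        sex.append("M" if rng.random() < 0.5 else "F")
    return pd.DataFrame(
        {
            "animal": [str(i + 1) for i in range(n)],
            "sire": sire,
            "dam": dam,
            "sex": sex,
        }
    )
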