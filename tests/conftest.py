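import numpy as np
import pytest

from mitescreen.assign_report import assign_family
from mitescreen.screen import run_screen
from mitescreen.synthetic_data import SyntheticDesign, simulate_dataset


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    # a 12-assembly study, heavy contamination so every stage is exercised
    return SyntheticDesign(
        seed=11,
        n_assemblies=12,
        contigs_per_assembly=6,
        contamination_prob=0.5,
        ixodida_decoy_prob=0.3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_dataset(small_design)


@pytest.fixture(scope="session")
def small_screen(small_dataset):
    ds = small_dataset
    return run_screen(
        ds.assemblies, ds.inclusion, ds.exclusion, ds.nt_records, ds.lineages
    )


@pytest.fixture(scope="session")
def small_assignments(small_dataset, small_screen):
    return [
        assign_family(c, small_dataset.lineages) for c in small_screen.calls
    ]
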