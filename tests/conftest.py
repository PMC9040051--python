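import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytorate.io_formats import CodonAlignment
from cytorate.synthetic_data import (
    DEFAULT_SPECIES_MAP,
    QuintetSimParams,
    simulate_quintet_alignment,
    tip_ids,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_map():
    return DEFAULT_SPECIES_MAP


@pytest.fixture(scope="session")
def role_map():
    return tip_ids("g1")


@pytest.fixture(scope="session")
def small_quintet():
    """One simulated quintet gene (500 codons) shared across tests."""
    params = QuintetSimParams(
        branch_lengths=0.2, kappa=2.0, omega_by_branch=0.2, n_codons=500, seed=11
    )
    return simulate_quintet_alignment(params)


@pytest.fixture
def toy_alignment():
    return CodonAlignment(
        ["s1", "s2"],
        ["ATGGCTAAA", "ATGGCCAAG"],
    )


def random_multispecies_tree(rng: np.random.Generator) -> str:
    """Random newick over tips from the four synthetic species (<=12 tips)."""
    tags = ["Outg", "Dmat", "Dpat", "Poly_M", "Poly_P"]
    labels = []
    counter = 0
    for tag in tags:
        for _ in range(int(rng.integers(0, 3))):
            counter += 1
            sep = "" if tag.startswith("Poly") else "_"
            labels.append(f"{tag}{sep}x{counter}")
    while len(labels) < 2:
        counter += 1
        labels.append(f"Outg_x{counter}")
    rng.shuffle(labels)
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
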