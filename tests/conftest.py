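import random

import pytest

import symcore as sc

BASES = "ACGT"
SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def mutate(seq: str, rate: float, rng: random.Random, protect_ends: int = 0) -> str:
    """Substitute each position independently at ``rate`` (ends optionally kept)."""
    out = list(seq)
    for i in range(protect_ends, len(seq) - protect_ends):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in BASES if c != out[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def pair_clade():
    """Two sister genomes from a 250-gene ancestor with loss and gain."""
    ancestor = sc.simulate_ancestor(250, seed=7)
    scenario = sc.EvolutionScenario(
        tree="(A:0.05,B:0.05);", loss_prob=0.1, gain_rate=5, omega=0.2, seed=7
    )
    genomes, truth = sc.evolve_clade(ancestor, scenario)
    return ancestor, scenario, genomes, truth


@pytest.fixture(scope="session")
def quad_clade():
    """Two genera of two genomes each plus a zero-divergence reduced target."""
    ancestor = sc.simulate_ancestor(150, seed=21)
    scenario = sc.EvolutionScenario(
        tree="(((A1:0.04,A2:0.04)gA:0.04,(B1:0.04,B2:0.04)gB:0.04)anc:0.0,T:0.0)root;",
        loss_prob=0.05,
        gain_rate=3,
        omega=0.2,
        seed=21,
        loss_overrides={"T": 0.15, "anc": 0.0},
        gain_overrides={"anc": 0.0},
    )
    genomes, truth = sc.evolve_clade(ancestor, scenario)
    return ancestor, scenario, genomes, truth
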