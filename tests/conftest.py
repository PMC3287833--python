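import numpy as np
import pandas as pd
import pytest

from famqtl.pedigree import Individual, Pedigree


@pytest.fixture
def trio():
    return Pedigree("T", [
        Individual("fa", None, None, "male", "T"),
        Individual("mo", None, None, "female", "T"),
        Individual("ch", "fa", "mo", "male", "T"),
    ])


@pytest.fixture
def three_gen():
    """12-member, 3-generation pedigree with a first-cousin pair.

    gp1 x gp2 have sons s1, s2; each marries in (w1, w2); cousins c1..c4.
    """
    mem = [
        Individual("gp1", None, None, "male", "F"),
        Individual("gp2", None, None, "female", "F"),
        Individual("s1", "gp1", "gp2", "male", "F"),
        Individual("s2", "gp1", "gp2", "male", "F"),
        Individual("w1", None, None, "female", "F"),
        Individual("w2", None, None, "female", "F"),
        Individual("c1", "s1", "w1", "male", "F"),
        Individual("c2", "s1", "w1", "female", "F"),
        Individual("c3", "s2", "w2", "male", "F"),
        Individual("c4", "s2", "w2", "female", "F"),
        Individual("w3", None, None, "female", "F"),
        Individual("g3", "c1", "w3", "male", "F"),
    ]
    return Pedigree("F", mem)


@pytest.fixture(scope="session")
def default_study():
    """One default eight-family study shared across tests (seed 1)."""
    from famqtl.simulate import default_config, simulate_study

    return simulate_study(default_config(seed=1))


def gene_drop_kinship(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo kinship oracle: repeated gene drops of unique founder
    alleles; phi(i,j) estimated as the probability that one random allele
    from i and one from j are identical by descent.  Independent of the
    recursive kinship implementation.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    lab = np.zeros((n_drops, n, 2), dtype=np.int32)
    next_label = 0
    for i in range(n):
        if ped.father_idx[i] < 0:
            lab[:, i, 0] = next_label
            lab[:, i, 1] = next_label + 1
            next_label += 2
    for i in ped.topological_order:
        f, m = ped.father_idx[i], ped.mother_idx[i]
        if f < 0:
            continue
        pick_f = rng.integers(0, 2, size=n_drops)
        pick_m = rng.integers(0, 2, size=n_drops)
        lab[:, i, 0] = lab[np.arange(n_drops), f, pick_f]
        lab[:, i, 1] = lab[np.arange(n_drops), m, pick_m]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            eq = 0.0
            for s in (0, 1):
                for t in (0, 1):
                    eq += np.mean(lab[:, i, s] == lab[:, j, t])
            phi[i, j] = phi[j, i] = eq / 4.0
    return phi
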