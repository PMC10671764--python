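import itertools

import numpy as np
import pytest

from ncdclust import DistanceMatrix, EvoConfig, ncd_matrix, simulate_phylogeny


def naive_bwt(S: str) -> tuple[str, int]:
    """Rotation-sort oracle: list all cyclic rotations, sort, read last column."""
    n = len(S)
    rotations = sorted((S[i:] + S[:i], i) for i in range(n))
    F = "".join(rot[-1] for rot, _ in rotations)
    s = min(k for k, (rot, _) in enumerate(rotations) if rot == S)
    return F, s


@pytest.fixture(scope="session")
def two_pair_matrix() -> DistanceMatrix:
    """Two tight pairs (within 0.1) with cross-distances 0.9."""
    labels = ["a", "b", "c", "d"]
    V = np.full((4, 4), 0.9)
    np.fill_diagonal(V, 0.0)
    V[0, 1] = V[1, 0] = 0.1
    V[2, 3] = V[3, 2] = 0.1
    return DistanceMatrix(labels, V)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The seeded 3-clade simulation used for end-to-end recovery checks.

    Session-scoped because the NCD matrix over 24 x 20 kb genomes is the
    expensive step shared by several tests.
    """
    seqs, truth = simulate_phylogeny(EvoConfig(seed=42))
    D = ncd_matrix(seqs)
    return seqs, truth, D


def within_between_means(D: DistanceMatrix, truth: dict[str, int]) -> tuple[float, float]:
    within, between = [], []
    for i, j in itertools.combinations(range(D.n), 2):
        same = truth[D.labels[i]] == truth[D.labels[j]]
        (within if same else between).append(D.values[i, j])
    return float(np.mean(within)), float(np.mean(between))
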