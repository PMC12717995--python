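"""Shared fixtures: tiny hand-built alignments, distance matrices and a
seeded synthetic community."""

import numpy as np
import pytest

from fairylit import (
    Alignment,
    CommunitySpec,
    Config,
    DistanceMatrix,
    Partition,
    distance_matrix,
    simulate_community,
)


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        ("s1", "s2", "s3"),
        ("ACGTACGT", "ACGTACGA", "ACGTTCGA"),
    )


@pytest.fixture
def two_cluster_dm() -> tuple[DistanceMatrix, Partition]:
    """Two pairs: intra distance 1%, inter distance ≥ 5%."""
    ids = ("a1", "a2", "b1", "b2")
    d = np.array(
        [
            [0.00, 0.01, 0.05, 0.06],
            [0.01, 0.00, 0.055, 0.05],
            [0.05, 0.055, 0.00, 0.01],
            [0.06, 0.05, 0.01, 0.00],
        ]
    )
    part = Partition(
        method="manual",
        label="toy",
        clusters={"A": frozenset({"a1", "a2"}), "B": frozenset({"b1", "b2"})},
    )
    return DistanceMatrix(ids, d), part


@pytest.fixture(scope="session")
def gap_community():
    """20 species, 200 specimens, clean barcode gap (intra ≤1%, inter ≥5%)."""
    spec = CommunitySpec(
        n_species=20,
        n_specimens=200,
        intra_divergence_max=0.01,
        inter_divergence_range=(0.05, 0.25),
        seed=11,
    )
    aln, specimens, truth = simulate_community(spec)
    return aln, specimens, truth


@pytest.fixture(scope="session")
def gap_community_dm(gap_community):
    aln, _, _ = gap_community
    return distance_matrix(aln, model="p")


@pytest.fixture
def default_config() -> Config:
    return Config()
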