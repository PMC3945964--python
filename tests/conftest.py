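"""Shared fixtures: handcrafted records and simulated study-condition data."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from barcode_eval.datasets import MarkerDataset, SequenceRecord
from barcode_eval.distances import DistanceMatrix, distance_matrix
from barcode_eval.simdata import SimulationConfig, simulate_dataset


def make_record(
    rec_id: str,
    species: str,
    residues: str,
    marker: str = "COI",
    status: str = "published",
    stage: str = "adult",
) -> SequenceRecord:
    return SequenceRecord(
        id=rec_id, species=species, marker=marker, status=status, stage=stage,
        residues=residues,
    )


def make_dataset(records, marker: str = "COI", role: str = "custom") -> MarkerDataset:
    return MarkerDataset(marker, tuple(records), role)


def seq_pair(n_sites: int, transitions: int, transversions: int) -> tuple[str, str]:
    """Two sequences differing by exact transition/transversion counts."""
    assert transitions + transversions <= n_sites
    a = "A" * n_sites
    b = (
        "G" * transitions            # A->G transitions
        + "C" * transversions        # A->C transversions
        + "A" * (n_sites - transitions - transversions)
    )
    return a, b


def matrix_from_pairs(ids, dists: dict) -> DistanceMatrix:
    """Build a DistanceMatrix from {(id_a, id_b): d} (symmetric fill)."""
    n = len(ids)
    values = np.zeros((n, n))
    undefined = np.zeros((n, n), dtype=bool)
    for (a, b), d in dists.items():
        i, j = ids.index(a), ids.index(b)
        if d is None:
            values[i, j] = values[j, i] = np.nan
            undefined[i, j] = undefined[j, i] = True
        else:
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(ids), values, np.full((n, n), 100), undefined)


@pytest.fixture(scope="session")
def sim_default():
    """Default study-condition dataset: 4 genera x 5 species x 4 records."""
    config = SimulationConfig(seed=1)
    dataset, truth = simulate_dataset(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def sim_default_matrix(sim_default):
    _, dataset, _ = sim_default
    return distance_matrix(dataset)


@pytest.fixture(scope="session")
def sim_overlap():
    """Dataset with one near-zero-divergence species pair and a deep split."""
    config = SimulationConfig(seed=2, overlap_pairs=1, deep_split_species=1)
    dataset, truth = simulate_dataset(config)
    return config, dataset, truth
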