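"""Shared fixtures: small hand-built tables and study-shaped metadata."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from baycomm.data_model import CommunityMatrix, build_community_matrix
from baycomm.environment import SeasonLabeling

#: per-month sample counts of the emulated field campaign (Jan..Dec)
STUDY_MONTHLY_SIZES = (23, 22, 22, 21, 20, 20, 18, 21, 20, 2, 15, 22)
STUDY_HYPOXIA_MONTHS = (6, 7, 8, 9)


def study_season_labeling() -> SeasonLabeling:
    labels = {
        m: ("hypoxia" if m in STUDY_HYPOXIA_MONTHS else "normoxia") for m in range(1, 13)
    }
    return SeasonLabeling(labels=labels, threshold=2.0)


def metadata_with_monthly_sizes(sizes=STUDY_MONTHLY_SIZES) -> pd.DataFrame:
    """Metadata frame with the given number of samples per month.

    Sites/layers are assigned round-robin so that (site, month, layer) stays
    unique; depths are arbitrary but valid.
    """
    rows = []
    for month, size in zip(range(1, 13), sizes):
        for i in range(size):
            rows.append(
                {
                    "sample_id": f"m{month:02d}-{i:02d}",
                    "site_id": f"s{i // 2:02d}",
                    "month": month,
                    "layer": "surface" if i % 2 == 0 else "bottom",
                    "site_depth": 10.0 + (i % 7) * 5.0,
                }
            )
    return pd.DataFrame(rows)


def random_community(metadata: pd.DataFrame, n_species: int, seed: int,
                     occupancy: float = 0.15) -> CommunityMatrix:
    rng = np.random.default_rng(seed)
    species = [f"sp{i:03d}" for i in range(n_species)]
    occ = rng.random((len(metadata), n_species)) < occupancy
    records = []
    ids = metadata["sample_id"].to_numpy()
    rows_idx, col_idx = np.nonzero(occ)
    records = pd.DataFrame(
        {"sample_id": ids[rows_idx], "species_name": np.array(species)[col_idx], "detected": True}
    )
    return build_community_matrix(records, metadata)


@pytest.fixture
def tiny_matrix() -> CommunityMatrix:
    """3 samples x 2 retained species, built by hand."""
    metadata = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "site_id": ["s1", "s1", "s2"],
            "month": [1, 1, 1],
            "layer": ["surface", "bottom", "surface"],
            "site_depth": [10.0, 10.0, 20.0],
        }
    )
    records = pd.DataFrame(
        {
            "sample_id": ["a", "a", "b", "c"],
            "species_name": ["x", "y", "x", "y"],
            "detected": [True, True, True, True],
        }
    )
    return build_community_matrix(records, metadata)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset reused by several test modules."""
    from baycomm.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(n_sites=8, species_pool_size=80, seed=42)
    )
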