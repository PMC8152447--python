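"""Shared fixtures: a small simulated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stallsites import calling, profiles
from stallsites.simulate import (
    SimConfig,
    simulate_context_annotations,
    simulate_footprints,
    simulate_homolog_sequences,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_organisms=3, n_genes=12, seed=20240)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_homolog_sequences(small_config)


@pytest.fixture(scope="session")
def small_footprints(small_truth, small_config):
    return simulate_footprints(small_truth, small_config)


@pytest.fixture(scope="session")
def small_annotation(small_truth) -> pd.DataFrame:
    return small_truth.annotation_table()


@pytest.fixture(scope="session")
def small_profiles(small_footprints, small_annotation):
    return profiles.build_codon_profiles(
        small_footprints.table,
        small_footprints.offsets,
        small_annotation,
        selected_lengths=sorted(small_footprints.offsets),
        keep_per_length=True,
    )


@pytest.fixture(scope="session")
def small_peaks(small_profiles):
    return {
        tx: calling.call_peaks(p) for tx, p in small_profiles.items()
    }


@pytest.fixture(scope="session")
def small_annotations_tables(small_truth, small_config):
    return simulate_context_annotations(small_truth, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
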