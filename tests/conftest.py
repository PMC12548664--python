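"""Shared fixtures: small seeded synthetic datasets and their networks."""

import numpy as np
import pytest

from dfcshapley import (SimConfig, WindowSpec, build_temporal_network,
                        make_dataset)


@pytest.fixture(scope="session")
def tiny_sim() -> SimConfig:
    """Small but fully featured design: 12 ROIs in 3 subnetworks, 4 subjects
    x 8 narratives, both effect types planted."""
    return SimConfig(
        n_subjects=4, n_narratives_per_subject=8, n_rois=12,
        n_timepoints=125, subnetwork_sizes=(4, 4, 4),
        modality_effect_subnets=(0,), content_effect_subnets=(1, 2),
        modality_effect_size=0.15, content_effect_size=0.35,
        noise_sd=0.5, ar_coeff=0.4, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim):
    return make_dataset(tiny_sim)


@pytest.fixture(scope="session")
def tiny_networks(tiny_dataset):
    spec = WindowSpec()
    return [build_temporal_network(series, spec)
            for _subj, _narr, series in tiny_dataset.runs]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
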