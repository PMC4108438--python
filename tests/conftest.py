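"""Shared fixtures: one synthetic survey reused across test modules."""

import warnings

import pytest

import camcom
from camcom import prep


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic survey (fixed seed)."""
    return camcom.simulate_dataset(seed=20090724)


@pytest.fixture(scope="session")
def events(dataset):
    return camcom.collapse_events(dataset["records"])


@pytest.fixture(scope="session")
def matrices(dataset, events):
    return prep.build_all_matrices(events, dataset["deployments"])


@pytest.fixture(scope="session")
def summary(dataset, events):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prep.summarize_community(events, dataset["deployments"],
                                        dataset["traits"])
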