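"""Shared fixtures: synthetic studies generated once per session."""

import pytest

from duoreg.synthetic import simulate_preset

SEED = 1  # default study seed used across the suite


@pytest.fixture(scope="session")
def spacing_study(tmp_path_factory):
    return simulate_preset("spacing", tmp_path_factory.mktemp("spacing"), seed=SEED)


@pytest.fixture(scope="session")
def classes_study(tmp_path_factory):
    return simulate_preset("classes", tmp_path_factory.mktemp("classes"), seed=SEED)


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    return simulate_preset("full", tmp_path_factory.mktemp("full"), seed=SEED)


@pytest.fixture(scope="session")
def gradient_study(tmp_path_factory):
    return simulate_preset("gradient", tmp_path_factory.mktemp("gradient"), seed=SEED)
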