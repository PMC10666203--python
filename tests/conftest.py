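import logging

import numpy as np
import pytest

from cellabc.fixtures import make_gaussian_toy, make_invalid_corpus, make_viral_fixture
from cellabc.problem import parse_problem

logging.getLogger("cellabc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gaussian_bundle(tmp_path_factory):
    return make_gaussian_toy(tmp_path_factory.mktemp("gaussian"))


@pytest.fixture(scope="session")
def gaussian_problem(gaussian_bundle):
    return parse_problem(gaussian_bundle.index_path)


@pytest.fixture(scope="session")
def viral_bundle(tmp_path_factory):
    return make_viral_fixture(tmp_path_factory.mktemp("viral"), seed=1)


@pytest.fixture(scope="session")
def viral_problem(viral_bundle):
    return parse_problem(viral_bundle.index_path)


@pytest.fixture(scope="session")
def invalid_corpus(tmp_path_factory):
    return make_invalid_corpus(tmp_path_factory.mktemp("invalid"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
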