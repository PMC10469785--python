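import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blockprime import design
from blockprime.fixtures import (
    FixtureSpec,
    load_oligos,
    make_community,
    make_host,
    make_offtargets,
    write_bundle,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n else ""


@pytest.fixture(scope="session")
def oligos():
    return load_oligos()


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def host(default_spec):
    return make_host(default_spec)


@pytest.fixture(scope="session")
def offtargets(host, default_spec):
    return make_offtargets(host, default_spec)


@pytest.fixture(scope="session")
def design_result(host, offtargets, oligos):
    return design(host, oligos["1389F"], oligos["1015R"], offtargets)


@pytest.fixture(scope="session")
def community(host, offtargets, default_spec):
    return make_community(host, offtargets, default_spec)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, default_spec):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(default_spec, out)
    return out
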