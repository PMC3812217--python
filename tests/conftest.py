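import pytest

from domainflux import (
    Metabolite as M,
    Reaction as R,
    build_network,
    enumerate_efms,
    fixture,
)


def ext(mid, **kw):
    return M(mid, external=True, **kw)


@pytest.fixture(scope="session")
def chain_net():
    """Aext -> B -> Cext: the minimal one-mode network."""
    return build_network(
        [ext("Aext"), M("B"), ext("Cext")],
        [R("R1", {"Aext": -1, "B": 1}), R("R2", {"B": -1, "Cext": 1})],
        name="chain",
    )


@pytest.fixture(scope="session")
def parallel_net():
    """Two independent irreversible routes from source to sink."""
    return build_network(
        [ext("A"), M("B"), M("B2"), ext("C")],
        [
            R("r1", {"A": -1, "B": 1}),
            R("r2", {"B": -1, "C": 1}),
            R("r3", {"A": -1, "B2": 1}),
            R("r4", {"B2": -1, "C": 1}),
        ],
        name="parallel",
    )


@pytest.fixture(scope="session")
def pdh_bundle():
    return fixture("pdh_domain")


@pytest.fixture(scope="session")
def classical_bundle():
    return fixture("tca_classical")


@pytest.fixture(scope="session")
def domain_bundle():
    return fixture("tca_domain")


@pytest.fixture(scope="session")
def classical_efms(classical_bundle):
    return enumerate_efms(classical_bundle.network)


@pytest.fixture(scope="session")
def domain_efms(domain_bundle):
    return enumerate_efms(domain_bundle.network)


@pytest.fixture(scope="session")
def pdh_efms(pdh_bundle):
    return enumerate_efms(pdh_bundle.network)
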