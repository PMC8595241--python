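import pytest

from isct import fixtures as fx


@pytest.fixture(scope="session")
def adult_reference():
    ref, _ = fx.synth_reference_population("adult")
    return ref


@pytest.fixture(scope="session")
def pediatric_reference_and_growth():
    return fx.synth_reference_population("pediatric")


@pytest.fixture(scope="session")
def molecular_fixture():
    """Satisfiable network + disease definition + drug profiles + training."""
    return fx.synth_network_with_definitions(seed=0)


@pytest.fixture(scope="session")
def adult_population_500(adult_reference):
    from isct import vpop

    return vpop.generate_adult_vpop(adult_reference, n=500, seed=11)
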