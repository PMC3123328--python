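import pytest
from hypothesis import HealthCheck, settings

from bahdkit import PipelineConfig, curate_family, generate_genome, load_fixture_spec

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_spec():
    return load_fixture_spec()


@pytest.fixture(scope="session")
def fixture_genome(fixture_spec):
    return generate_genome(fixture_spec, seed=11)


@pytest.fixture(scope="session")
def fixture_family(fixture_genome):
    calls = curate_family(
        fixture_genome.models,
        fixture_genome.proteins,
        PipelineConfig(),
        clade2_exempt=fixture_genome.exempt,
    )
    return calls
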