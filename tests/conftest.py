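import pytest

from pigtx.simulate import FixtureConfig, make_genome_and_annotation, plant_variants


@pytest.fixture(scope="session")
def config():
    return FixtureConfig(seed=7)


@pytest.fixture(scope="session")
def genome_annotation(config):
    return make_genome_and_annotation(config)


@pytest.fixture(scope="session")
def planted_variants(config, genome_annotation):
    genome, ann, truth = genome_annotation
    return plant_variants(genome, ann, truth, config)
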