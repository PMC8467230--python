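import numpy as np
import pytest

import rdnavar as rv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study (3 species x 2 strains, lighter read
    counts) shared by the integration tests; study conditions other than
    problem size match the defaults."""
    cfg = rv.StudyConfig(n_species=3, strains_per_species=2,
                         dominant_reads_range=(40, 80),
                         minor_count_range=(1, 2), seed=7)
    return rv.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    config = rv.PipelineConfig(rng_seed=7)
    result = rv.run_pipeline(config, small_study.reads,
                             small_study.barcode_map,
                             small_study.references)
    return result
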