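import numpy as np
import pytest

from centomics.config import AnalysisConfig
from centomics.synthetic import SynthSpec, generate_cohort

#: canonical seed for every seeded test in the suite
SEED = 0


def small_spec(seed: int = SEED, effect: float = 1.0) -> SynthSpec:
    """A scaled-down cohort for cheap unit tests."""
    return SynthSpec(
        n_per_group=(24, 20, 16, 12),
        n_metabolites=60,
        n_gut_genera=60,
        n_oral_genera=40,
        met_cent_elevated=4,
        met_cent_depleted=3,
        met_family_elevated=5,
        met_aging_increasing=4,
        gut_cent=4,
        gut_family=3,
        gut_aging=2,
        oral_cent=2,
        oral_family=2,
        oral_aging=0,
        hc_n=13,
        fc_n=11,
        hc_marker_n=3,
        depth_mean=8000.0,
        effect_size_log=effect,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle0():
    """Default-size synthetic cohort at the canonical seed."""
    return generate_cohort(SynthSpec(seed=SEED))


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def config0():
    return AnalysisConfig(seed=SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
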