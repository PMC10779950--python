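import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fmoscore import BenchmarkDesign, PairInteraction, gen_benchmark

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def shp099_pair() -> PairInteraction:
    """The reference tunnel-site inhibitor's aggregate PIEDA components (kcal/mol)."""
    return PairInteraction(i=0, j=1, es=-131.0, ex=98.0, ct_mix=-30.0, di=-77.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240104)


@pytest.fixture
def small_benchmark():
    """A modest noisy synthetic benchmark plus its generating truth."""
    design = BenchmarkDesign(seed=42, n_targets=4, ligands_per_target=15)
    records, truth = gen_benchmark(design)
    return design, records, truth
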