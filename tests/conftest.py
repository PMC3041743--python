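import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from agsnp.formats import Platform, Source
from agsnp.pipeline import evaluate_against_truth, run_pipeline
from agsnp.simulate import ShortPlatformSpec, SimConfig, TEFamilySpec, simulate_dataset

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_sim_config(seed: int = 1, **overrides) -> SimConfig:
    """A 400 kb analogue of the default study genome for fast tests."""
    base = dict(
        seed=seed,
        genome_length=400_000,
        n_genes=40,
        te_library=[
            TEFamilySpec("TE01", 3000, 20),
            TEFamilySpec("TE02", 4000, 15),
            TEFamilySpec("TE03", 5000, 12),
            TEFamilySpec("TE04", 6000, 10),
        ],
        unchar_repeat_families=[TEFamilySpec("URF1", 2500, 10)],
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def small_run(small_dataset):
    ds = small_dataset
    result = run_pipeline(
        ds.long_read_records(),
        ds.organellar_hits,
        ds.repeat_hits,
        ds.gene_hits,
        ds.alignments,
        seed=ds.cfg.seed,
    )
    evaluation = evaluate_against_truth(result.passing, ds)
    return ds, result, evaluation


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
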