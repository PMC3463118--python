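import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def tiny_index():
    """The 8-base worked example: ref 'ACGTACGT', k=4, skip=1."""
    from splitmap.index import IndexParams, build_index

    return build_index({"r": "ACGTACGT"}, IndexParams(k=4, skip=1, max_hits=10))


@pytest.fixture(scope="session")
def small_genome_index():
    """A 60 kb random single-sequence genome with a k=11 index, shared by
    pipeline-level tests."""
    from splitmap import sv_sim
    from splitmap.index import IndexParams, build_index

    ref = sv_sim.make_synthetic_reference(1, [60_000], rng_seed=977)
    idx = build_index(ref.sequences, IndexParams(k=11, skip=1, max_hits=650))
    return ref.sequences, idx
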