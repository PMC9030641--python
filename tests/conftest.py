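import numpy as np
import pytest

from fuzzymoth import synth
from fuzzymoth.pfn import arr_project_valid


@pytest.fixture(scope="session")
def small_cohort():
    """Six moths in three groups — the cheapest cohort exercising every
    pipeline stage."""
    return synth.generate_cohort(6, 3, seed=11)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return synth.generate_dataset(small_cohort, 40, seed=12)


@pytest.fixture(scope="session")
def small_probes(small_cohort):
    amb, stim = synth.probe_settings()
    resp = synth.probe_responses(small_cohort, seed=13)
    return amb, stim, resp


def random_pfns(n: int, seed: int) -> np.ndarray:
    """Uniformly sampled valid interval-valued PFNs (via projection)."""
    rng = np.random.default_rng(seed)
    return arr_project_valid(rng.random((n, 4)))
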