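import numpy as np
import pytest

from bandpop.matrix import BandMatrix


def make_matrix(values, primers_per_band=None, system="SSR"):
    """Build a BandMatrix from a raw 0/1 array with generated ids."""
    values = np.asarray(values)
    n, k = values.shape
    sample_ids = [f"s{i + 1}" for i in range(n)]
    band_ids = [f"b{j + 1}" for j in range(k)]
    if primers_per_band is None:
        primers_per_band = ["P1"] * k
    band_to_primer = dict(zip(band_ids, primers_per_band))
    if isinstance(system, str):
        primer_system = {p: system for p in set(primers_per_band)}
    else:
        primer_system = dict(system)
    return BandMatrix(sample_ids, band_ids, values, band_to_primer, primer_system)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_matrix(rng):
    """20 samples x 24 bands over 4 primers in 2 systems, no fixed bands."""
    while True:
        v = (rng.random((20, 24)) < rng.uniform(0.2, 0.8, size=24)).astype(int)
        f = v.mean(axis=0)
        if ((f > 0) & (f < 1)).all():
            break
    primers = ["P1"] * 6 + ["P2"] * 6 + ["P3"] * 6 + ["P4"] * 6
    systems = {"P1": "SSR", "P2": "SSR", "P3": "IT-ISJ", "P4": "IT-ISJ"}
    return make_matrix(v, primers, systems)
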