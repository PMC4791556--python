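import numpy as np
import pytest

from creole_core.io_core import MISSING, GenotypeMatrix, MarkerInfo
from creole_core.synthetic_data import SimulationConfig, simulate_population


def make_genotypes(rows, ids=None, markers=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from a list of per-accession call lists."""
    calls = np.array(rows, dtype=np.int8)
    n, m = calls.shape
    if ids is None:
        ids = [f"A{i}" for i in range(n)]
    if markers is None:
        markers = [
            MarkerInfo(f"M{j}", chrom=None if chrom is None else chrom[j],
                       pos=None if pos is None else pos[j])
            for j in range(m)
        ]
    return GenotypeMatrix(list(ids), calls, markers)


def random_genotypes(rng, n=20, m=50, missing=0.1):
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < missing] = MISSING
    return make_genotypes(calls)


@pytest.fixture(scope="session")
def small_population():
    """A modest structured panel shared across read-only tests."""
    cfg = SimulationConfig(
        n_accessions=300, n_markers=1200, n_groups=5, seed=11, target_fst=0.2
    )
    return simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
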