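import numpy as np
import pandas as pd
import pytest

from ponypop.core import GenotypeMatrix
from ponypop.simulate import (
    AdmixtureGraphSpec,
    default_sweep_fixture,
    simulate_genotypes,
    simulate_graph_frequencies,
)


@pytest.fixture(scope="session")
def bn_two_pop():
    """Balding-Nichols two-population fixture: F=0.1 per branch, 50k sites,
    25+25 diploids — the analytic-recovery substrate."""
    spec = AdmixtureGraphSpec(
        nodes=["root", "A", "B"],
        edges=[("root", "A", 0.1), ("root", "B", 0.1)],
        n_sites=50_000,
        seed=11,
    )
    freqs = simulate_graph_frequencies(spec)
    gm, meta = simulate_genotypes(freqs[["A", "B"]], {"A": 25, "B": 25}, seed=12)
    return freqs, gm, meta


@pytest.fixture(scope="session")
def sweep_fixture():
    """One seed of the standard 2-Mb sweep scenario (phased)."""
    return default_sweep_fixture(seed=0)


def make_gm(dosages, positions=None, chrom="1", samples=None, haplotypes=None):
    """Small-matrix helper for hand fixtures."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    var = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64), "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(d, samples, var, haplotypes)
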