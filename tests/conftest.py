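import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from homeobias.io import HITS_COLUMNS, SignalTrack
from homeobias.simulate import SimConfig, simulate_all

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_hit(query, subject, identity=98.0, aln=1000, e=1e-50, bit=2000.0,
             qlen=1000, slen=1000):
    """One 14-column alignment-hit row with sensible defaults."""
    mism = int(round(aln * (1 - identity / 100)))
    return dict(zip(HITS_COLUMNS, [
        query, subject, identity, aln, mism, 0, 1, aln, 1, aln, e, bit, qlen, slen,
    ]))


def hits_frame(rows):
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


@pytest.fixture(scope="session")
def small_dataset():
    """A small end-to-end synthetic dataset shared across tests."""
    return simulate_all(SimConfig(n_dyads=300, n_unique_per_genome=40, seed=11))


@pytest.fixture()
def flat_track():
    """FE = 2 everywhere on chr 1M over 1 Mb."""
    return SignalTrack(pd.DataFrame(
        {"chrom": ["1M"], "start": [0], "end": [1_000_000], "value": [2.0]}
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
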