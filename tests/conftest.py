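import numpy as np
import pandas as pd
import pytest

from ducksel import simdata
from ducksel.genio import GenotypeMatrix


@pytest.fixture(scope="session")
def small_study():
    """A small polygenic F2 study shared by read-only tests."""
    return simdata.make_study_fixture(
        n_f2=200, markers_per_chromosome=80, n_chromosomes=5, h2=0.5, seed=11
    )


@pytest.fixture(scope="session")
def tiny_geno():
    """60 individuals x 40 markers on 2 chromosomes, a few missing calls."""
    rng = np.random.default_rng(5)
    codes = rng.binomial(2, 0.3, size=(60, 40)).astype(np.int8)
    codes[rng.random(codes.shape) < 0.02] = -1
    pos = np.sort(rng.choice(10_000_000, size=40, replace=False))
    marker_map = pd.DataFrame(
        {
            "chrom": ["chr1"] * 20 + ["chr2"] * 20,
            "pos": np.concatenate([np.sort(pos[:20]), np.sort(pos[20:])]),
            "a1": "A",
            "a2": "G",
        }
    )
    ids = np.array([f"ind{i}" for i in range(60)], dtype=object)
    return GenotypeMatrix(codes, ids, marker_map)
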