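import numpy as np
import pandas as pd
import pytest

import hairmeth as hm
from hairmeth.methcore import ANAGEN, TELOGEN


SAMPLES = ["anagen_1", "anagen_2", "anagen_3",
           "telogen_1", "telogen_2", "telogen_3"]
GROUPS = {s: (ANAGEN if s.startswith("anagen") else TELOGEN)
          for s in SAMPLES}


def matrix_from_counts(pos, meth, total, chrom="chr1", context="CG",
                       strand="+"):
    """Build a 3v3 MethylomeMatrix from explicit count arrays."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    sites = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos),
                          "strand": strand, "context": context})
    return hm.MethylomeMatrix(sites, meth, total, list(SAMPLES),
                              dict(GROUPS))


def matrix_from_levels(pos, level_a, level_t, depth=30, seed=0, **kw):
    """3v3 matrix with binomial counts around per-group level vectors."""
    rng = np.random.default_rng(seed)
    n = len(pos)
    total = np.full((n, 6), depth)
    meth = np.empty((n, 6), dtype=int)
    for j in range(3):
        meth[:, j] = rng.binomial(depth, level_a)
    for j in range(3, 6):
        meth[:, j] = rng.binomial(depth, level_t)
    return matrix_from_counts(pos, meth, total, **kw)


@pytest.fixture(scope="session")
def small_dataset():
    """The default study conditions: 2 x 1 Mb + lambda, all contexts."""
    return hm.simulate_dataset(hm.preset_config("small", 1))


@pytest.fixture(scope="session")
def small_dmr_result(small_dataset):
    return hm.call_dmrs(small_dataset.matrix.drop_chrom("lambda"))
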