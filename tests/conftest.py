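import logging

import numpy as np
import pandas as pd
import pytest

from spdcorr import SummaryStats

logging.getLogger("spdcorr").setLevel(logging.ERROR)


_DEFAULT_Z = object()


def make_sumstats(trait_id="t", snp_ids=("rs1", "rs2", "rs3"),
                  a1="A", a2="G", z=_DEFAULT_Z, n=1000.0,
                  beta=None, se=None):
    m = len(snp_ids)
    if z is _DEFAULT_Z:
        z = None if beta is not None else \
            np.array([0.5, 1.9, 2.1])[:m] if m <= 3 else np.linspace(0.5, 2.1, m)

    def rep(v):
        return np.repeat(v, m) if np.isscalar(v) or isinstance(v, str) \
            else np.asarray(v)
    return SummaryStats.from_arrays(
        trait_id, np.asarray(snp_ids, dtype=object),
        a1=rep(a1).astype(object), a2=rep(a2).astype(object),
        z=np.asarray(z, float) if z is not None else None,
        n=rep(float(n)) if np.isscalar(n) else np.asarray(n, float),
        beta=np.asarray(beta, float) if beta is not None else None,
        se=np.asarray(se, float) if se is not None else None)


@pytest.fixture
def rng():
    return np.random.default_rng(20180824)


@pytest.fixture
def tiny_sumstats():
    return make_sumstats()


def random_conditioned_matrix(rng, m):
    """A valid conditioned correlation matrix from random data."""
    x = rng.standard_normal((4 * m, m)) @ rng.standard_normal((m, m))
    c = pd.DataFrame(x).corr().to_numpy()
    np.fill_diagonal(c, 1.0)
    return np.clip((c + c.T) / 2, -1, 1)
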