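"""Independent brute-force oracles shared by the test suite."""

import itertools

import numpy as np
import pandas as pd

from ksdev.rank_products import rp_statistic


def exact_pfp(fc: pd.DataFrame, direction: str) -> pd.Series:
    """Exact permutation pfp by exhaustive enumeration.

    Under the Rank Products null each comparison column is an independent
    uniform permutation, so a fixed gene's rank in one column is uniform on
    {1..n} and independent across columns. By linearity of expectation the
    expected number of null genes with RP <= r is n × P(single rank tuple
    has geometric mean <= r), which we enumerate exactly over the n^K
    possible tuples. pfp = E / position, with the monotone envelope along
    the RP ordering applied as in the estimator.
    """
    n, K = fc.shape
    obs = rp_statistic(fc, direction).to_numpy()
    tuples = np.array(list(itertools.product(range(1, n + 1), repeat=K)), dtype=float)
    null_rp = np.sort(np.exp(np.log(tuples).mean(axis=1)))
    prob_le = np.searchsorted(null_rp, obs + 1e-12, side="right") / len(tuples)
    expected = n * prob_le
    pos = np.empty(n)
    order = np.argsort(obs, kind="stable")
    pos[order] = np.arange(1, n + 1)
    pfp = expected / pos
    mono = np.minimum.accumulate(pfp[order][::-1])[::-1]
    out = np.empty(n)
    out[order] = mono
    return pd.Series(out, index=fc.index)
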