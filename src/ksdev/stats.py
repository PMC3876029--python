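"""Exact gene-set statistics shared across the pipeline.

Hypergeometric overlap tests (upper tail, enrichment only), Benjamini–
Hochberg adjustment, and plain multi-set intersection reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of a query set (size n) with an annotation set (size K)
    drawn from a universe of N genes; k genes are shared."""

    k: int
    n: int
    K: int
    N: int
    p_upper: float

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else 0.0

    @property
    def percent(self) -> int:
        """Round-half-up integer percentage of the overlap fraction."""
        return int(math.floor(100.0 * self.fraction + 0.5))


def hypergeom_overlap(k: int, n: int, K: int, N: int) -> OverlapResult:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``n`` is the query (e.g. a DEG list), ``K`` the annotation (e.g.
    predicted targets), ``N`` the gene universe.
    """
    if N <= 0:
        raise ValueError("empty universe (N must be positive)")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got k={k} n={n} K={K} N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k} n={n} K={K}")
    # sf(k-1) = P[X >= k]; exact tail sum under the hood
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(k=k, n=n, K=K, N=N, p_upper=min(max(p, 0.0), 1.0) or float(np.finfo(float).tiny))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone envelope)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def overlap_sets(named_sets: Mapping[str, Iterable[str]]) -> dict:
    """Pairwise and full intersections of named gene sets.

    Returns a dict with ``pairwise`` — {(a, b): sorted shared members} for
    every unordered pair — and ``full`` — members common to all sets.
    """
    sets = {name: set(members) for name, members in named_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    names = sorted(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = sorted(sets[a] & sets[b])
    full = set.intersection(*sets.values())
    return {"pairwise": pairwise, "full": sorted(full)}
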