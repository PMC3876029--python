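"""Rank Products differential expression with permutation pfp control.

For a two-group contrast with replicate groups A (test) and B (reference),
all K = |A|·|B| between-group log2 fold changes are formed. Per comparison
genes are ranked (rank 1 = strongest change in the tested direction; ties
get average ranks) and the Rank Product of a gene is the geometric mean of
its K ranks. Significance is a permutation-based proportion of false
positives (pfp): each comparison's rank column is permuted independently,
E(g) is the expected number of null genes with a Rank Product at least as
extreme as gene g's, and pfp(g) = E(g) / rank-position of g. The pfp plays
the role of an FDR-adjusted p-value; DEGs are called at pfp <= alpha with
an additional |log2 fold change| cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ksdev.matrix import ExpressionMatrix


@dataclass(frozen=True)
class Contrast:
    """Two disjoint replicate groups; A is the test group (up = higher in A)."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs at least two replicates")


@dataclass
class RPResult:
    table: pd.DataFrame  # index gene; columns rp_up, rp_down, pfp_up, pfp_down, mean_log2fc
    n_comparisons: int
    n_perm: int
    contrast: Contrast | None = None


@dataclass
class DEGTable:
    up: pd.DataFrame  # columns gene, mean_log2fc, pfp (sorted by pfp then |fc|)
    down: pd.DataFrame
    alpha: float
    fc_cut: float | None

    @property
    def up_genes(self) -> set[str]:
        return set(self.up["gene"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.down["gene"])


def pairwise_log_fold_changes(matrix: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Genes × K table of log2(a) − log2(b) over all between-group pairs."""
    missing = [s for s in (*contrast.group_a, *contrast.group_b) if s not in matrix.sample_ids]
    if missing:
        raise KeyError(f"samples missing from matrix: {missing}")
    cols = {}
    for a in contrast.group_a:
        for b in contrast.group_b:
            cols[f"{a}-{b}"] = matrix.values[a] - matrix.values[b]
    return pd.DataFrame(cols, index=matrix.genes)


def _rank_columns(fc: np.ndarray, direction: str) -> np.ndarray:
    """Per-column ranks; rank 1 = most extreme in the given direction."""
    signed = -fc if direction == "up" else fc
    return np.apply_along_axis(rankdata, 0, signed)


def rp_statistic(fc_table: pd.DataFrame, direction: str) -> pd.Series:
    """Per-gene Rank Product: geometric mean of per-comparison ranks."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    ranks = _rank_columns(fc_table.to_numpy(dtype=float), direction)
    rp = np.exp(np.log(ranks).mean(axis=1))
    return pd.Series(rp, index=fc_table.index, name=f"rp_{direction}")


def _null_rp_sorted(n_genes: int, K: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted pool of n_perm × n_genes null Rank Products from random ranks."""
    out = np.empty(n_perm * n_genes)
    base = np.arange(1, n_genes + 1, dtype=float)
    for p in range(n_perm):
        ranks = np.column_stack([rng.permutation(base) for _ in range(K)])
        out[p * n_genes : (p + 1) * n_genes] = np.exp(np.log(ranks).mean(axis=1))
    out.sort()
    return out


def _pfp_from_null(rp_obs: np.ndarray, null_sorted: np.ndarray, n_perm: int) -> np.ndarray:
    order = np.argsort(rp_obs, kind="stable")
    exp_counts = np.searchsorted(null_sorted, rp_obs, side="right") / n_perm
    pfp = np.empty_like(rp_obs)
    positions = np.empty(len(rp_obs), dtype=float)
    positions[order] = np.arange(1, len(rp_obs) + 1)
    pfp = exp_counts / positions
    # enforce monotone non-decreasing pfp along the RP ordering
    sorted_pfp = np.minimum.accumulate((pfp[order])[::-1])[::-1]
    pfp[order] = sorted_pfp
    return pfp


def rp_pfp(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    n_perm: int = 1000,
    seed: int = 0,
) -> RPResult:
    """Rank Products with Monte-Carlo pfp for both directions.

    The null is the original Rank Products permutation scheme: each
    comparison's ranks are an independent uniform permutation of 1..n.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fc = pairwise_log_fold_changes(matrix, contrast)
    n_genes, K = fc.shape
    rp_up = rp_statistic(fc, "up").to_numpy()
    rp_down = rp_statistic(fc, "down").to_numpy()
    rng = np.random.default_rng(seed)
    null_sorted = _null_rp_sorted(n_genes, K, n_perm, rng)
    pfp_up = _pfp_from_null(rp_up, null_sorted, n_perm)
    pfp_down = _pfp_from_null(rp_down, null_sorted, n_perm)
    table = pd.DataFrame(
        {
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
            "mean_log2fc": fc.mean(axis=1).to_numpy(),
        },
        index=fc.index,
    )
    return RPResult(table=table, n_comparisons=K, n_perm=n_perm, contrast=contrast)


def call_degs(rp: RPResult, alpha: float = 0.05, fc_cut: float | None = 0.9) -> DEGTable:
    """DEG lists at pfp <= alpha and |mean log2 FC| >= fc_cut.

    ``fc_cut=None`` disables the fold-change filter.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    t = rp.table

    def _side(pfp_col: str, sign: int) -> pd.DataFrame:
        keep = t[pfp_col] <= alpha
        if fc_cut is not None:
            keep &= sign * t["mean_log2fc"] >= fc_cut
        sub = t.loc[keep, ["mean_log2fc", pfp_col]].rename(columns={pfp_col: "pfp"})
        sub = sub.assign(gene=sub.index, abs_fc=sub["mean_log2fc"].abs())
        sub = sub.sort_values(["pfp", "abs_fc"], ascending=[True, False], kind="stable")
        return sub[["gene", "mean_log2fc", "pfp"]].reset_index(drop=True)

    return DEGTable(up=_side("pfp_up", +1), down=_side("pfp_down", -1), alpha=alpha, fc_cut=fc_cut)
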