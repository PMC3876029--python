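"""Mesenchymal-contamination estimation and subtraction correction.

Epithelial dissections of the embryonic olfactory epithelium inevitably
carry attached nasal mesenchyme. With a mixing fraction ``F`` the observed
epithelial profile is, on the linear intensity scale,

    E_obs(g) = (1 - F) * E_pure(g) + F * M(g)

so a gene's mesenchymal contribution can be removed replicate-wise as

    E_c_i(g) = E_i(g) - F * mean_replicates(M(g))

with negative results floored (the gene "reached no expression" and is
flagged dropped). ``F`` itself is estimated from tissue-exclusive marker
genes: for a mesenchymal-only marker the epithelial-sample abundance is
roughly ``F`` times its pure-mesenchyme abundance.

The comparative-Cq (2^-ddCq) helper quantifies marker abundance ratios
from qPCR plates normalized to reference genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ksdev.matrix import ExpressionMatrix
from ksdev.stats import OverlapResult, hypergeom_overlap


@dataclass(frozen=True)
class MarkerPanel:
    """Tissue-exclusive marker genes used to estimate the mixing fraction.

    The classic panel: epithelial-only FoxJ1, Fmo2, Ehf; mesenchymal-only
    Sp7 and Lect1.
    """

    epithelial_only: tuple[str, ...]
    mesenchymal_only: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.epithelial_only or not self.mesenchymal_only:
            raise ValueError("both marker lists must be non-empty")
        if set(self.epithelial_only) & set(self.mesenchymal_only):
            raise ValueError("marker lists must be disjoint")


@dataclass
class ContaminationEstimate:
    F: float
    per_marker_ratios: dict[str, float]
    scope: str = "all"


@dataclass
class CorrectedMatrix:
    matrix: ExpressionMatrix  # log2 scale, post-subtraction
    dropped: set[str] = field(default_factory=set)
    F: float = 0.0
    floor_linear: float = 0.0


@dataclass
class CqTable:
    """Long-format qPCR table: one Cq measurement per row."""

    data: pd.DataFrame  # columns: gene, sample, condition, cq
    reference_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"gene", "sample", "condition", "cq"}
        if not required <= set(self.data.columns):
            raise ValueError(f"CqTable needs columns {sorted(required)}")
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        if (self.data["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")


def ddcq_fold_change(
    cq: CqTable, target_gene: str, test_condition: str, ref_condition: str
) -> float:
    """Comparative-Cq fold change of ``target_gene``, test vs reference.

    Per sample, dCq = Cq(target) - mean Cq(reference genes); per condition
    dCq values are averaged; ddCq = dCq(test) - dCq(ref); the fold change
    is 2^(-ddCq).
    """
    dcq = {}
    for condition in (test_condition, ref_condition):
        sub = cq.data[cq.data["condition"] == condition]
        targets = sub[sub["gene"] == target_gene]
        if targets.empty:
            raise ValueError(f"no Cq for {target_gene!r} in condition {condition!r}")
        per_sample = []
        for sample, grp in targets.groupby("sample"):
            refs = sub[(sub["sample"] == sample) & (sub["gene"].isin(cq.reference_genes))]
            if refs.empty:
                raise ValueError(
                    f"no reference-gene Cq in sample {sample!r} (condition {condition!r})"
                )
            per_sample.append(float(grp["cq"].mean() - refs["cq"].mean()))
        dcq[condition] = float(np.mean(per_sample))
    ddcq = dcq[test_condition] - dcq[ref_condition]
    return float(2.0 ** (-ddcq))


def estimate_mes_fraction(
    epi: ExpressionMatrix,
    mes: ExpressionMatrix,
    markers: MarkerPanel,
    central: str = "median",
    min_mes_linear: float | None = None,
    scope: str = "all",
) -> ContaminationEstimate:
    """Estimate the mesenchymal fraction F from mesenchymal-only markers.

    For each marker, the ratio of its mean linear-scale abundance in the
    epithelial samples to that in the pure-mesenchyme samples; F is the
    median (or mean) of the ratios, clipped to [0, 1]. Markers whose
    mesenchymal abundance does not clear ``min_mes_linear`` (default: the
    5th percentile of the mesenchyme matrix) carry no signal and are
    excluded with a warning.
    """
    missing = [g for g in markers.mesenchymal_only if g not in epi.genes or g not in mes.genes]
    if missing:
        raise KeyError(f"mesenchymal markers absent from the matrices: {missing}")
    mes_linear = 2.0 ** mes.values
    if min_mes_linear is None:
        min_mes_linear = float(np.percentile(mes_linear.to_numpy(), 5))
    ratios: dict[str, float] = {}
    for g in markers.mesenchymal_only:
        m = float(mes_linear.loc[g].mean())
        if m <= min_mes_linear:
            warnings.warn(f"marker {g!r} not expressed in mesenchyme; excluded from F estimate")
            continue
        e = float((2.0 ** epi.values.loc[g]).mean())
        ratios[g] = min(max(e / m, 0.0), 1.0)
    if not ratios:
        raise ValueError("no usable mesenchymal marker left to estimate F")
    vals = np.array(list(ratios.values()))
    F = float(np.median(vals) if central == "median" else np.mean(vals))
    return ContaminationEstimate(F=F, per_marker_ratios=ratios, scope=scope)


def subtract_mes(
    epi: ExpressionMatrix,
    mes: ExpressionMatrix,
    F: float,
    floor_linear: float | None = None,
) -> CorrectedMatrix:
    """Subtract ``F`` times the replicate-averaged mesenchymal profile.

    The subtraction runs on linear intensities and the result is re-logged.
    Corrected values below ``floor_linear`` (default: the 5th percentile of
    the linear epithelial matrix, standing in for "no expression") are set
    to the floor; a gene is dropped ("reached no expression") when at least
    half of its replicates hit the floor — a majority vote rather than
    unanimity, so that multiplicative noise on a strongly contaminated gene
    cannot rescue it through a single above-floor replicate.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F must lie in [0, 1); got {F}")
    extra = set(epi.genes) ^ set(mes.genes)
    if extra:
        raise ValueError(f"gene sets differ between EPI and MES: {sorted(extra)[:10]}")
    if F == 0.0:  # nothing to subtract; exact identity, no flooring
        return CorrectedMatrix(
            matrix=ExpressionMatrix(epi.values.copy(), epi.samples.copy()),
            dropped=set(), F=0.0, floor_linear=0.0,
        )
    epi_lin = 2.0 ** epi.values
    mes_mean = (2.0 ** mes.values.loc[epi.genes]).mean(axis=1)
    corrected = epi_lin.sub(F * mes_mean, axis=0)
    if floor_linear is None:
        floor_linear = float(np.percentile(epi_lin.to_numpy(), 5))
    floored = corrected < floor_linear
    corrected = corrected.clip(lower=floor_linear)
    majority = floored.sum(axis=1) >= 0.5 * floored.shape[1]
    dropped = set(epi.genes[majority]) if F > 0 else set()
    out = ExpressionMatrix(np.log2(corrected), epi.samples.copy())
    return CorrectedMatrix(matrix=out, dropped=dropped, F=F, floor_linear=floor_linear)


def dropped_gene_check(
    dropped: set[str], mes_up_degs: set[str], universe: set[str]
) -> OverlapResult:
    """Are the genes lost to the subtraction enriched for mesenchymal
    up-regulated DEGs? Hypergeometric upper-tail test."""
    if not universe:
        raise ValueError("empty gene universe")
    if not (dropped <= universe and mes_up_degs <= universe):
        raise ValueError("dropped and mes_up_degs must be subsets of the universe")
    k = len(dropped & mes_up_degs)
    return hypergeom_overlap(k=k, n=len(dropped), K=len(mes_up_degs), N=len(universe))
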