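"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of a developing-olfactory-system
profiling study: triplicate epithelial (EPI) and mesenchymal (MES) samples
across embryonic stages, regions, and genotypes, with a known mesenchymal
mixing fraction F contaminating the epithelial observations; toy
multi-species genomes with PWM site instances planted at known coordinates
and a per-site conservation plan; two-species expression compendia with
planted conserved co-expression modules containing designated reference
disease genes; and qPCR plates whose comparative-Cq analysis recovers
known fold changes.

Expression is generated and stored on the log2 scale; tissue mixing is
performed on linear intensities and re-logged before log-scale Gaussian
noise is added. All randomness derives from one top-level seed through
the labelled-stream scheme in :mod:`ksdev._rng`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ksdev._rng import stream
from ksdev.contamination import CqTable, MarkerPanel
from ksdev.coexpression import OrthologMap
from ksdev.matrix import ExpressionMatrix
from ksdev.motif import BASES, BackgroundModel, MafBlock, PWMatrix, max_score, score_window
from ksdev.rank_products import Contrast

# ---------------------------------------------------------------------------
# profiling study


@dataclass(frozen=True)
class DegSpec:
    """One planted differential-expression set."""

    size: int
    log2_effect: float
    direction: str  # "up" | "down": sign of the change in the test condition
    contrast: str  # label into StudyDesign.contrasts


@dataclass
class StudyDesign:
    """Shape and effect sizes of the synthetic profiling study.

    Defaults reproduce the study structure: three stages, two regions,
    two genotypes, three biological replicates, and a mesenchymal mixing
    fraction of 0.15 in the epithelial samples.
    """

    stages: tuple[str, ...] = ("E11.5", "E12.5", "E14.5")
    regions: tuple[str, ...] = ("OE", "VNO")
    genotypes: tuple[str, ...] = ("WT", "KO")
    n_replicates: int = 3
    n_genes: int = 2000
    mes_fraction: float = 0.15
    deg_spec: tuple[DegSpec, ...] = (
        DegSpec(30, 2.0, "up", "stage"),
        DegSpec(60, 2.0, "down", "stage"),
        DegSpec(20, 2.0, "up", "genotype"),
        DegSpec(40, 2.0, "down", "genotype"),
    )
    contrasts: dict = field(
        default_factory=lambda: {
            "stage": ({"stage": "E12.5", "region": "OE", "genotype": "WT"},
                      {"stage": "E11.5", "region": "OE", "genotype": "WT"}),
            "genotype": ({"stage": "E12.5", "region": "OE", "genotype": "KO"},
                         {"stage": "E12.5", "region": "OE", "genotype": "WT"}),
        }
    )
    noise_sd: float = 0.25
    n_epi_markers: int = 3
    n_mes_markers: int = 2
    n_mes_specific: int = 50
    background_log2: float = 2.0
    marker_delta: float = 8.0
    baseline_range: tuple[float, float] = (4.0, 9.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.mes_fraction < 1.0:
            raise ValueError("mes_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for spec in self.deg_spec:
            if spec.contrast not in self.contrasts:
                raise ValueError(f"deg_spec references unknown contrast {spec.contrast!r}")
            if spec.direction not in ("up", "down"):
                raise ValueError("deg_spec direction must be 'up' or 'down'")
        n_special = (
            self.n_epi_markers + self.n_mes_markers + self.n_mes_specific
            + sum(s.size for s in self.deg_spec)
        )
        if n_special > self.n_genes:
            raise ValueError("marker + mes-specific + DEG genes exceed n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset; consumed by recovery tests."""

    true_F: float | None = None
    planted_deg_sets: dict = field(default_factory=dict)  # contrast -> (up set, down set)
    marker_panel: MarkerPanel | None = None
    mes_specific: set = field(default_factory=set)
    contrasts: dict = field(default_factory=dict)
    planted_sites: list = field(default_factory=list)  # dicts: chrom/start/end/strand/...
    planted_site_species: list = field(default_factory=list)  # set per site
    site_genes: list = field(default_factory=list)
    tss_distances: list = field(default_factory=list)
    planted_modules: list = field(default_factory=list)  # species-A gene sets
    decoy_modules: list = field(default_factory=list)
    reference_genes: set = field(default_factory=set)
    disease_genes: set = field(default_factory=set)
    true_folds: dict = field(default_factory=dict)


def _condition_table(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for stage, region, genotype in itertools.product(
        design.stages, design.regions, design.genotypes
    ):
        for rep in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{region}_{stage}_{genotype}_r{rep}",
                    "stage": stage,
                    "region": region,
                    "genotype": genotype,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def contrast_from_design(
    design: StudyDesign, label: str, samples: pd.DataFrame
) -> Contrast:
    """Materialize a design contrast into explicit sample-id groups."""
    test_sel, ref_sel = design.contrasts[label]

    def pick(sel: dict) -> tuple[str, ...]:
        mask = pd.Series(True, index=samples.index)
        for k, v in sel.items():
            mask &= samples[k] == v
        return tuple(samples.index[mask])

    return Contrast(group_a=pick(test_sel), group_b=pick(ref_sel), label=label)


def gen_profiling_study(
    design: StudyDesign,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate matched EPI and MES expression matrices with known truth.

    The epithelial observation of gene g is the linear-scale mixture
    (1−F)·epithelial signal + F·mesenchymal signal, re-logged, plus
    log2-scale Gaussian noise; the mesenchymal observation is the
    mesenchymal signal plus noise.
    """
    design.validate()
    samples = _condition_table(design)
    n_cond_samples = len(samples)

    # gene universe: regular genes, then markers, then mes-specific genes
    n_plain = design.n_genes - design.n_epi_markers - design.n_mes_markers - design.n_mes_specific
    genes = [f"g{i:05d}" for i in range(n_plain)]
    epi_markers = [f"epiMarker{i+1}" for i in range(design.n_epi_markers)]
    mes_markers = [f"mesMarker{i+1}" for i in range(design.n_mes_markers)]
    mes_specific = [f"mesOnly{i:03d}" for i in range(design.n_mes_specific)]
    all_genes = genes + epi_markers + mes_markers + mes_specific

    rng = stream(design.seed, "profiling/baseline")
    lo, hi = design.baseline_range
    base_epi = rng.uniform(lo, hi, size=len(all_genes))
    base_mes = rng.uniform(lo, hi, size=len(all_genes))

    sig_epi = np.tile(base_epi[:, None], (1, n_cond_samples))
    sig_mes = np.tile(base_mes[:, None], (1, n_cond_samples))
    gene_pos = {g: i for i, g in enumerate(all_genes)}

    bg = design.background_log2
    hi_sig = bg + design.marker_delta
    for g in epi_markers:
        sig_epi[gene_pos[g], :] = hi_sig
        sig_mes[gene_pos[g], :] = bg
    for g in mes_markers + mes_specific:
        sig_epi[gene_pos[g], :] = bg
        sig_mes[gene_pos[g], :] = hi_sig

    # plant DEGs in the epithelial signal, disjoint sets drawn from plain genes
    planted: dict[str, tuple[set, set]] = {lab: (set(), set()) for lab in design.contrasts}
    pool = iter(genes)
    for spec in design.deg_spec:
        members = {next(pool) for _ in range(spec.size)}
        test_sel, _ = design.contrasts[spec.contrast]
        mask = pd.Series(True, index=samples.index)
        for k, v in test_sel.items():
            mask &= samples[k] == v
        cols = np.flatnonzero(mask.to_numpy())
        sign = 1.0 if spec.direction == "up" else -1.0
        for g in members:
            sig_epi[gene_pos[g], cols] += sign * spec.log2_effect
        up, down = planted[spec.contrast]
        (up if spec.direction == "up" else down).update(members)

    F = design.mes_fraction
    mix_lin = (1.0 - F) * 2.0 ** sig_epi + F * 2.0 ** sig_mes
    noise = stream(design.seed, "profiling/noise")
    epi_obs = np.log2(mix_lin) + noise.normal(0, design.noise_sd, size=mix_lin.shape)
    mes_obs = sig_mes + noise.normal(0, design.noise_sd, size=sig_mes.shape)

    epi = ExpressionMatrix(
        pd.DataFrame(epi_obs, index=all_genes, columns=samples.index), samples.copy()
    )
    mes = ExpressionMatrix(
        pd.DataFrame(mes_obs, index=all_genes, columns=samples.index), samples.copy()
    )
    truth = SyntheticTruth(
        true_F=F,
        planted_deg_sets=planted,
        marker_panel=MarkerPanel(tuple(epi_markers), tuple(mes_markers)),
        mes_specific=set(mes_specific),
        contrasts=dict(design.contrasts),
    )
    return epi, mes, truth


# ---------------------------------------------------------------------------
# genomes, planted sites, alignments


def default_pwm() -> PWMatrix:
    """A sharp synthetic homeodomain-style PWM (TAAT-core consensus).

    This is a synthetic stand-in constructed for testing, not a database
    matrix: 97 counts on the consensus base and 1 elsewhere at every one
    of its 12 positions, consensus TAATTAGCGTCA.
    """
    consensus = "TAATTAGCGTCA"
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts[BASES.index(b), j] = 97
    return PWMatrix(counts=counts, identifier="synthetic_homeobox")


def _random_seq(rng: np.random.Generator, length: int, bg: BackgroundModel) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=np.asarray(bg.freqs)))


def _degrade(
    window: str, pwm: PWMatrix, bg: BackgroundModel, rel_threshold: float
) -> str:
    """Mutate a site copy until it scores below the relative threshold."""
    threshold = rel_threshold * max_score(pwm, bg)
    probs = pwm.probabilities()
    out = list(window)
    for j in range(pwm.width):
        if score_window("".join(out), pwm, bg) < threshold:
            break
        out[j] = BASES[int(np.argmin(probs[:, j]))]
    degraded = "".join(out)
    if score_window(degraded, pwm, bg) >= threshold:
        raise RuntimeError("could not degrade site copy below threshold")
    return degraded


def gen_genome_and_alignments(
    pwm: PWMatrix,
    n_species: int = 8,
    seq_len: int = 10_000,
    n_planted: int = 6,
    conservation_plan: list[set[str]] | None = None,
    tss_distances: list[int] | None = None,
    seed: int = 0,
    bg: BackgroundModel | None = None,
    rel_threshold: float = 0.5,
    focal_species: str = "focal",
    flank: int = 10,
) -> tuple[dict[str, dict[str, str]], list[MafBlock], pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Toy focal genome plus aligned species with planted PWM sites.

    Consensus-sequence site instances are planted at known, non-overlapping
    coordinates in the focal genome. Each planted footprint gets one
    gapless alignment block: species named in its conservation plan carry
    an exact copy, the others a copy degraded below the scanning threshold.
    A TSS is placed at a known distance downstream of each site.

    Returns (genomes, alignment blocks, tss BED frame, intergenic BED
    frame, truth). ``genomes`` maps species -> {chrom: sequence}.
    """
    if n_species < 2:
        raise ValueError("need at least two aligned species")
    W = pwm.width
    if W >= seq_len:
        raise ValueError("PWM wider than the genome")
    bg = bg or BackgroundModel.uniform()
    species = [f"sp{i+1}" for i in range(n_species)]
    if conservation_plan is None:
        # default plan cycles through informative support levels
        sizes = [n_species, 3, 2, 1, 0, 4]
        conservation_plan = [set(species[: sizes[i % len(sizes)]]) for i in range(n_planted)]
    if len(conservation_plan) != n_planted:
        raise ValueError("conservation_plan length must equal n_planted")
    for plan in conservation_plan:
        if not plan <= set(species):
            raise ValueError(f"plan names unknown species: {plan - set(species)}")
    if tss_distances is None:
        # modest distances so each site's nearest TSS is its own gene's
        pattern = [100, 400, 200, 450, 300, 150]
        tss_distances = [pattern[i % len(pattern)] for i in range(n_planted)]

    rng = stream(seed, "genome")
    slot = (seq_len - 2 * flank) // max(n_planted, 1)
    if slot < W + 2 * flank:
        raise ValueError("planted sites do not fit in seq_len")
    jitter = max(min(slot // 4, slot - W - flank), 1)
    starts = [flank + i * slot + int(rng.integers(0, jitter)) for i in range(n_planted)]
    for a, b in itertools.pairwise(starts):
        if a + W > b:
            raise ValueError("overlapping planted sites")

    focal_seq = list(_random_seq(rng, seq_len, bg))
    consensus = pwm.consensus()
    for s in starts:
        focal_seq[s : s + W] = consensus
    focal_seq = "".join(focal_seq)

    # species genomes: background with block copies written at shifted coords
    genomes: dict[str, dict[str, str]] = {focal_species: {"chr1": focal_seq}}
    species_seqs = {sp: list(_random_seq(stream(seed, f"genome/{sp}"), seq_len, bg)) for sp in species}

    blocks: list[MafBlock] = []
    truth_sites = []
    shift = 17  # fixed focal->species coordinate offset, keeps blocks in range
    for i, s in enumerate(starts):
        b_start = max(s - flank, 0)
        b_end = min(s + W + flank, seq_len)
        focal_text = focal_seq[b_start:b_end]
        off = s - b_start
        rows = {focal_species: ("chr1", b_start, focal_text)}
        for sp in species:
            sp_start = min(b_start + shift, seq_len - len(focal_text))
            if sp in conservation_plan[i]:
                text = focal_text
            else:
                degraded = _degrade(consensus, pwm, bg, rel_threshold)
                text = focal_text[:off] + degraded + focal_text[off + W :]
            species_seqs[sp][sp_start : sp_start + len(text)] = text
            rows[sp] = ("chr1", sp_start, text)
        blocks.append(MafBlock(rows=rows))
        truth_sites.append({"chrom": "chr1", "start": s, "end": s + W, "strand": "+"})
    for sp in species:
        genomes[sp] = {"chr1": "".join(species_seqs[sp])}

    # a few background blocks in unplanted focal regions
    bg_rng = stream(seed, "genome/background-blocks")
    for _ in range(3):
        b_start = int(bg_rng.integers(0, seq_len - 30))
        if any(t["start"] - 30 <= b_start <= t["end"] for t in truth_sites):
            continue
        text = focal_seq[b_start : b_start + 30]
        rows = {focal_species: ("chr1", b_start, text)}
        for sp in species[:2]:
            rows[sp] = ("chr1", min(b_start + shift, seq_len - 30), text)
        blocks.append(MafBlock(rows=rows))

    tss_rows = []
    site_genes = []
    actual_distances = []
    for i, s in enumerate(starts):
        pos = min(s + W - 1 + tss_distances[i], seq_len - 1)
        gene = f"gene{i+1}"
        site_genes.append(gene)
        actual_distances.append(pos - (s + W - 1))
        tss_rows.append(
            {"chrom": "chr1", "start": pos, "end": pos + 1,
             "name": f"{gene}|tx{i+1}", "score": 0, "strand": "+"}
        )
    tss = pd.DataFrame(tss_rows)
    intergenic = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": seq_len}])

    truth = SyntheticTruth(
        planted_sites=truth_sites,
        planted_site_species=list(conservation_plan),
        site_genes=site_genes,
        tss_distances=actual_distances,
    )
    return genomes, blocks, tss, intergenic, truth


# ---------------------------------------------------------------------------
# two-species compendia with planted co-expression modules


def gen_compendium_pair(
    n_genes: int = 200,
    n_samples_a: int = 100,
    n_samples_b: int = 100,
    module_spec: tuple[tuple[int, float], ...] = ((10, 0.9), (10, 0.9)),
    decoy_spec: tuple[tuple[int, float], ...] = ((10, 0.9),),
    n_reference_in_modules: int = 6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologMap, SyntheticTruth]:
    """Two-species compendia with planted conserved co-expression modules.

    Genes of a conserved module share a latent factor in BOTH species
    (pairwise correlation = the specified within-correlation); decoy
    modules share a factor in species A only. ``n_reference_in_modules``
    module members are designated known disease ("reference") genes; the
    remaining module members are the planted novel disease genes that
    prioritization should recover.
    """
    sizes = [s for s, _ in module_spec] + [s for s, _ in decoy_spec]
    if sum(sizes) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    for _, r in (*module_spec, *decoy_spec):
        if not 0.0 < r < 1.0:
            raise ValueError("within-correlation must lie in (0, 1)")
    total_module = sum(s for s, _ in module_spec)
    if n_reference_in_modules > total_module:
        raise ValueError("more reference genes requested than planted module members")

    genes_a = [f"gA{i:04d}" for i in range(n_genes)]
    genes_b = [f"gB{i:04d}" for i in range(n_genes)]
    rng = stream(seed, "compendium")
    data = {
        "A": rng.normal(size=(n_genes, n_samples_a)),
        "B": rng.normal(size=(n_genes, n_samples_b)),
    }

    def plant(rows: list[int], r: float, which: tuple[str, ...]) -> None:
        for sp in which:
            z = rng.normal(size=data[sp].shape[1])
            data[sp][rows, :] = np.sqrt(r) * z + np.sqrt(1.0 - r) * rng.normal(
                size=(len(rows), data[sp].shape[1])
            )

    cursor = 0
    planted_modules: list[set[str]] = []
    for size, r in module_spec:
        rows = list(range(cursor, cursor + size))
        plant(rows, r, ("A", "B"))
        planted_modules.append({genes_a[i] for i in rows})
        cursor += size
    decoy_modules: list[set[str]] = []
    for size, r in decoy_spec:
        rows = list(range(cursor, cursor + size))
        plant(rows, r, ("A",))
        decoy_modules.append({genes_a[i] for i in rows})
        cursor += size

    # spread reference genes across the planted (conserved) modules
    ordered_members = [g for mod in planted_modules for g in sorted(mod)]
    step = max(len(ordered_members) // n_reference_in_modules, 1)
    reference = set(ordered_members[::step][:n_reference_in_modules])
    disease = {g for mod in planted_modules for g in mod} - reference

    comp_a = ExpressionMatrix(
        pd.DataFrame(data["A"], index=genes_a, columns=[f"a{j:03d}" for j in range(n_samples_a)])
    )
    comp_b = ExpressionMatrix(
        pd.DataFrame(data["B"], index=genes_b, columns=[f"b{j:03d}" for j in range(n_samples_b)])
    )
    orthomap = OrthologMap(tuple(zip(genes_a, genes_b)))
    truth = SyntheticTruth(
        planted_modules=planted_modules,
        decoy_modules=decoy_modules,
        reference_genes=reference,
        disease_genes=disease,
    )
    return comp_a, comp_b, orthomap, truth


# ---------------------------------------------------------------------------
# qPCR plates


def gen_qpcr_plate(
    true_fold_changes: dict[str, float],
    reference_genes: tuple[str, ...] = ("Tbp", "Gapdh"),
    cq_noise_sd: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
    conditions: tuple[str, str] = ("test", "control"),
    base_cq: float = 24.0,
    ref_cq: float = 20.0,
) -> tuple[CqTable, SyntheticTruth]:
    """Emit a Cq table whose ddCq analysis recovers the given fold changes.

    Target genes sit at ``base_cq`` cycles in the control condition and at
    base_cq − log2(fold) in the test condition; reference genes sit at
    ``ref_cq`` in both. Gaussian cycle noise is added everywhere.
    """
    for g, f in true_fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {g!r} must be positive")
    rng = stream(seed, "qpcr")
    rows = []
    test_cond, _ = conditions
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            for g in reference_genes:
                rows.append(
                    {"gene": g, "sample": sample, "condition": cond,
                     "cq": ref_cq + rng.normal(0, cq_noise_sd) if cq_noise_sd else ref_cq}
                )
            for g, fold in true_fold_changes.items():
                cq = base_cq - (np.log2(fold) if cond == test_cond else 0.0)
                if cq_noise_sd:
                    cq += rng.normal(0, cq_noise_sd)
                rows.append({"gene": g, "sample": sample, "condition": cond, "cq": float(cq)})
    table = CqTable(pd.DataFrame(rows), reference_genes=tuple(reference_genes))
    return table, SyntheticTruth(true_folds=dict(true_fold_changes))


# ---------------------------------------------------------------------------
# writers


def write_profiling(
    outdir: str | Path, epi: ExpressionMatrix, mes: ExpressionMatrix, truth: SyntheticTruth
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    epi.write_tsv(out / "epi_expression.tsv", out / "samples.tsv")
    mes.write_tsv(out / "mes_expression.tsv")
    manifest = {
        "true_F": truth.true_F,
        "planted_deg_sets": {
            lab: {"up": sorted(up), "down": sorted(down)}
            for lab, (up, down) in truth.planted_deg_sets.items()
        },
        "epithelial_markers": list(truth.marker_panel.epithelial_only),
        "mesenchymal_markers": list(truth.marker_panel.mesenchymal_only),
        "mes_specific": sorted(truth.mes_specific),
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(manifest))


def write_genome_bundle(
    outdir: str | Path,
    genomes: dict[str, dict[str, str]],
    blocks: list[MafBlock],
    tss: pd.DataFrame,
    intergenic: pd.DataFrame,
    truth: SyntheticTruth,
    focal_species: str = "focal",
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO

    for sp, chroms in genomes.items():
        recs = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in chroms.items()]
        SeqIO.write(recs, str(out / f"{sp}.fa"), "fasta")
    alns = []
    for block in blocks:
        recs = []
        ordered = [focal_species] + sorted(k for k in block.rows if k != focal_species)
        for sp in ordered:
            chrom, start, text = block.rows[sp]
            rec = SeqRecord(Seq(text), id=f"{sp}.{chrom}")
            rec.annotations = {
                "start": start, "size": len(text), "strand": 1,
                "srcSize": len(genomes[sp][chrom]),
            }
            recs.append(rec)
        alns.append(MultipleSeqAlignment(recs))
    with open(out / "alignments.maf", "w") as fh:
        AlignIO.write(alns, fh, "maf")
    tss.to_csv(out / "tss.bed", sep="\t", header=False, index=False)
    intergenic.to_csv(out / "intergenic.bed", sep="\t", header=False, index=False)
    manifest = {
        "planted_sites": truth.planted_sites,
        "conservation_plan": [sorted(s) for s in truth.planted_site_species],
        "site_genes": truth.site_genes,
        "tss_distances": truth.tss_distances,
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(manifest))


def write_compendium(
    outdir: str | Path,
    comp_a: ExpressionMatrix,
    comp_b: ExpressionMatrix,
    orthomap: OrthologMap,
    truth: SyntheticTruth,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    comp_a.write_tsv(out / "compendium_a.tsv")
    comp_b.write_tsv(out / "compendium_b.tsv")
    pd.DataFrame(orthomap.pairs).to_csv(out / "orthologs.tsv", sep="\t", header=False, index=False)
    manifest = {
        "planted_modules": [sorted(m) for m in truth.planted_modules],
        "decoy_modules": [sorted(m) for m in truth.decoy_modules],
        "reference_genes": sorted(truth.reference_genes),
        "disease_genes": sorted(truth.disease_genes),
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(manifest))
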