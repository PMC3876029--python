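"""PWM site prediction with cross-species conservation filtering.

Sites are scored as standard log-likelihood ratios (log2, i.e. bits) of a
pseudocounted position weight matrix against an intergenic background
nucleotide model, on both strands; windows scoring at least a fixed
fraction (default 50%) of the maximum possible score are kept. A hit is
counted as conserved with species S when its footprint lies in a gapless
aligned block and the aligned sequence in S is itself a site by the same
definition. Hits conserved in at least ``min_species`` species are
associated to the nearest transcription start site, and genes are ranked
by an aggregate of site score, conservation support, and TSS proximity.

Coordinates follow the BED convention: 0-based, half-open, plus-strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO, motifs

BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(BASES)}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PWMatrix:
    """Position count matrix over {A, C, G, T} with an identifier."""

    counts: np.ndarray  # shape (4, W), rows in A,C,G,T order
    identifier: str = "pwm"
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x W matrix (A, C, G, T rows)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every position needs a positive column sum")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class BackgroundModel:
    """Background base frequencies (A, C, G, T), strictly positive."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("frequencies must be positive and sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls((0.25, 0.25, 0.25, 0.25))


@dataclass
class SiteHit:
    chrom: str
    start: int  # 0-based
    end: int  # half-open; end - start == PWM width
    strand: str
    score: float  # bits
    species_support: int = 0
    species: tuple[str, ...] = ()

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TargetAssoc:
    gene: str
    transcript: str
    sites: list[SiteHit] = field(default_factory=list)
    min_tss_distance: int = 0
    max_species_support: int = 0
    rank_score: float = 0.0
    is_best: bool = False


@dataclass
class MafBlock:
    """One gapless alignment block: per-species (chrom, start, text)."""

    rows: dict[str, tuple[str, int, str]]  # species -> (chrom, 0-based start, sequence)


# ---------------------------------------------------------------------------
# parsing


def load_pwm(text: str, pseudocount: float = 0.01) -> PWMatrix:
    """Parse a JASPAR-format count block into a PWMatrix."""
    try:
        parsed = motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise ValueError(f"malformed JASPAR PWM: {exc}") from exc
    if not parsed:
        raise ValueError("no motif found in PWM text")
    m = parsed[0]
    counts = np.array([m.counts[b] for b in BASES], dtype=float)
    ident = m.matrix_id or m.name or "pwm"
    return PWMatrix(counts=counts, identifier=ident, pseudocount=pseudocount)


def write_pwm(pwm: PWMatrix) -> str:
    lines = [f">{pwm.identifier}"]
    for i, b in enumerate(BASES):
        joined = " ".join(f"{int(c) if c == int(c) else c:>6}" for c in pwm.counts[i])
        lines.append(f"{b} [ {joined} ]")
    return "\n".join(lines) + "\n"


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    cols = names or ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def read_maf(path: str | Path) -> list[MafBlock]:
    """Read simplified (gapless) MAF blocks; record ids are species.chrom."""
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = {}
        for rec in aln:
            text = str(rec.seq).upper()
            if "-" in text:
                raise ValueError("only gapless alignment blocks are supported")
            species, _, chrom = rec.id.partition(".")
            rows[species] = (chrom, int(rec.annotations["start"]), text)
        blocks.append(MafBlock(rows=rows))
    return blocks


# ---------------------------------------------------------------------------
# scoring


def background_freqs(
    intergenic: pd.DataFrame, genome: dict[str, str], pseudocount: float = 1.0
) -> BackgroundModel:
    """Pooled base frequencies over intergenic intervals, pseudocounted."""
    if intergenic.empty:
        raise ValueError("empty intergenic interval set")
    counts = np.full(4, pseudocount)
    for row in intergenic.itertuples(index=False):
        seq = genome[row.chrom][int(row.start) : int(row.end)]
        for b, i in _ENC.items():
            counts[i] += seq.count(b)
    freqs = counts / counts.sum()
    return BackgroundModel(tuple(freqs))


def score_matrix(pwm: PWMatrix, bg: BackgroundModel) -> np.ndarray:
    """Per-position log2 likelihood ratios, shape (4, W)."""
    q = np.asarray(bg.freqs)[:, None]
    return np.log2(pwm.probabilities() / q)


def max_score(pwm: PWMatrix, bg: BackgroundModel) -> float:
    return float(score_matrix(pwm, bg).max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    enc = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _ENC.items():
        enc[arr == ord(b)] = i
    return enc


def score_window(window: str, pwm: PWMatrix, bg: BackgroundModel) -> float:
    """Best-of-both-strands LLR score of a single W-length window."""
    if len(window) != pwm.width:
        raise ValueError("window length must equal PWM width")
    enc = _encode(window)
    if (enc == 4).any():
        return -np.inf
    sm = score_matrix(pwm, bg)
    fwd = float(sm[enc, np.arange(pwm.width)].sum())
    rc = np.array([_COMP[int(i)] for i in enc[::-1]])
    rev = float(sm[rc, np.arange(pwm.width)].sum())
    return max(fwd, rev)


def scan_genome(
    genome: dict[str, str],
    pwm: PWMatrix,
    bg: BackgroundModel,
    rel_threshold: float = 0.5,
) -> list[SiteHit]:
    """All windows on either strand scoring >= rel_threshold × max score.

    Minus-strand hits are reported in plus-strand coordinates with the
    strand flag set; windows containing non-ACGT bases are skipped.
    """
    smax = max_score(pwm, bg)
    if smax <= 0:
        raise ValueError("maximum possible PWM score is not positive; relative threshold undefined")
    threshold = rel_threshold * smax
    sm = score_matrix(pwm, bg)
    W = pwm.width
    hits: list[SiteHit] = []
    for chrom, seq in genome.items():
        L = len(seq)
        if W > L:
            warnings.warn(f"PWM wider than sequence {chrom!r}; no hits possible")
            continue
        enc = _encode(seq)
        n_win = L - W + 1
        fwd = np.zeros(n_win)
        rev = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        for off in range(W):
            col = enc[off : off + n_win]
            ok = col != 4
            valid &= ok
            safe = np.where(ok, col, 0)
            fwd += sm[safe, off]
            # minus strand: genome position start+off pairs with PWM column
            # W-1-off through the complement base
            rev += sm[np.array([_COMP[int(c)] for c in safe]), W - 1 - off]
        for strand, scores in (("+", fwd), ("-", rev)):
            for pos in np.nonzero(valid & (scores >= threshold))[0]:
                hits.append(
                    SiteHit(
                        chrom=chrom,
                        start=int(pos),
                        end=int(pos) + W,
                        strand=strand,
                        score=float(scores[pos]),
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# conservation


def conservation_filter(
    hits: list[SiteHit],
    alignments: list[MafBlock],
    pwm: PWMatrix,
    bg: BackgroundModel,
    focal_species: str,
    min_species: int = 2,
    rel_threshold: float = 0.5,
) -> list[SiteHit]:
    """Keep hits whose aligned window is itself a site in >= min_species
    other species.

    A species counts only when the hit's footprint lies fully inside a
    gapless aligned block and the species' aligned W bases score at or
    above the same relative threshold (either strand).
    """
    threshold = rel_threshold * max_score(pwm, bg)
    W = pwm.width
    kept: list[SiteHit] = []
    for hit in hits:
        supporting: set[str] = set()
        for block in alignments:
            focal = block.rows.get(focal_species)
            if focal is None:
                continue
            chrom, bstart, text = focal
            if chrom != hit.chrom or hit.start < bstart or hit.end > bstart + len(text):
                continue
            off = hit.start - bstart
            for species, (_, _, stext) in block.rows.items():
                if species == focal_species:
                    continue
                window = stext[off : off + W]
                if len(window) == W and score_window(window, pwm, bg) >= threshold:
                    supporting.add(species)
        hit.species_support = len(supporting)
        hit.species = tuple(sorted(supporting))
        if hit.species_support >= min_species:
            kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# target association and ranking


def _site_tss_distance(hit: SiteHit, tss_pos: int) -> int:
    if hit.start <= tss_pos < hit.end:
        return 0
    return min(abs(tss_pos - hit.start), abs(tss_pos - (hit.end - 1)))


def associate_targets(
    hits: list[SiteHit],
    tss: pd.DataFrame,
    max_dist: int = 100_000,
    best_min_species: int = 3,
    best_max_dist: int = 10_000,
) -> list[TargetAssoc]:
    """Assign each hit to the transcript with the nearest TSS within
    ``max_dist`` and aggregate per gene.

    ``tss`` is a BED-like frame with chrom, start, name ("gene|transcript"),
    strand. A gene is flagged best target when some assigned site is
    conserved in at least ``best_min_species`` species and lies strictly
    closer than ``best_max_dist`` bp to the TSS.
    """
    if tss.empty:
        raise ValueError("empty TSS set")
    per_gene: dict[str, TargetAssoc] = {}
    for hit in hits:
        cands = tss[tss["chrom"] == hit.chrom]
        best: tuple[int, int, str] | None = None  # (distance, tss_pos, name)
        for row in cands.itertuples(index=False):
            d = _site_tss_distance(hit, int(row.start))
            if d > max_dist:
                continue
            key = (d, int(row.start), str(row.name))
            if best is None or key < best:
                best = key
        if best is None:
            continue
        dist, _, name = best
        gene, _, transcript = name.partition("|")
        assoc = per_gene.get(gene)
        if assoc is None:
            assoc = TargetAssoc(gene=gene, transcript=transcript, min_tss_distance=dist)
            per_gene[gene] = assoc
        assoc.sites.append(hit)
        assoc.min_tss_distance = min(assoc.min_tss_distance, dist)
        assoc.max_species_support = max(assoc.max_species_support, hit.species_support)
        if hit.species_support >= best_min_species and dist < best_max_dist:
            assoc.is_best = True
    return sorted(per_gene.values(), key=lambda a: a.gene)


def rank_targets(
    assocs: list[TargetAssoc],
    pwm: PWMatrix,
    bg: BackgroundModel,
    distance_scale: float = 5_000.0,
    tss: pd.DataFrame | None = None,
) -> list[TargetAssoc]:
    """Total order over candidate target genes.

    Each gene's rank score sums, over its assigned sites,
    species_support × (score / max score) × exp(−distance / distance_scale);
    ties break lexicographically by gene id. The distance used per site is
    its distance to the gene's nearest assigned TSS when ``tss`` is given,
    else the gene-level minimum distance.
    """
    if not assocs:
        raise ValueError("no target associations to rank")
    smax = max_score(pwm, bg)
    for assoc in assocs:
        total = 0.0
        for hit in assoc.sites:
            if tss is not None:
                cands = tss[tss["chrom"] == hit.chrom]
                dist = min(
                    (_site_tss_distance(hit, int(r.start)) for r in cands.itertuples(index=False)),
                    default=assoc.min_tss_distance,
                )
            else:
                dist = assoc.min_tss_distance
            total += hit.species_support * (hit.score / smax) * np.exp(-dist / distance_scale)
        assoc.rank_score = float(total)
    return sorted(assocs, key=lambda a: (-a.rank_score, a.gene))


def hits_to_bed(hits: list[SiteHit], name: str = "pwm") -> pd.DataFrame:
    """BED6+2 frame: name=PWM id, score=bits, extras species_support, species."""
    return pd.DataFrame(
        {
            "chrom": [h.chrom for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": name,
            "score": [round(h.score, 4) for h in hits],
            "strand": [h.strand for h in hits],
            "species_support": [h.species_support for h in hits],
            "species": [",".join(h.species) for h in hits],
        }
    )
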