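"""PWM parsing, LLR scanning, conservation filtering, target association."""

import numpy as np
import pandas as pd
import pytest

from ksdev import motif
from ksdev.motif import (
    BackgroundModel,
    PWMatrix,
    SiteHit,
    associate_targets,
    background_freqs,
    conservation_filter,
    load_pwm,
    max_score,
    rank_targets,
    scan_genome,
    score_window,
    write_pwm,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# parsing and background


def test_load_pwm_roundtrip_and_width(pwm):
    text = write_pwm(pwm)
    back = load_pwm(text)
    assert back.width == pwm.width
    assert np.allclose(back.counts, pwm.counts)
    assert back.identifier == pwm.identifier


def test_load_pwm_uniform_matrix_scores_zero_bits(uniform_bg):
    text = ">flat\nA [ 5 5 ]\nC [ 5 5 ]\nG [ 5 5 ]\nT [ 5 5 ]\n"
    flat = load_pwm(text, pseudocount=0.0)
    assert max_score(flat, uniform_bg) == pytest.approx(0.0)


def test_load_pwm_rejects_garbage():
    with pytest.raises(ValueError):
        load_pwm(">bad\nA [ 1 ]\nC [ 1 1 ]\nG [ 1 1 ]\nT [ 1 1 ]\n")


def test_background_freqs_hand_tally():
    genome = {"chr1": "ACGTACGTAAAA"}
    bed = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 8}])
    bg = background_freqs(bed, genome, pseudocount=0.0)
    assert np.allclose(bg.freqs, (0.25, 0.25, 0.25, 0.25))
    bed2 = pd.DataFrame([{"chrom": "chr1", "start": 8, "end": 12}])
    bg2 = background_freqs(bed2, genome, pseudocount=1.0)
    # 4 A's + 1 pseudocount per base
    assert np.allclose(bg2.freqs, (5 / 8, 1 / 8, 1 / 8, 1 / 8))
    with pytest.raises(ValueError):
        background_freqs(bed.iloc[:0], genome)


def test_background_model_validation():
    with pytest.raises(ValueError):
        BackgroundModel((0.5, 0.5, 0.0, 0.0))
    with pytest.raises(ValueError):
        BackgroundModel((0.5, 0.4, 0.2, 0.1))


# ---------------------------------------------------------------------------
# scanning


def test_consensus_window_scores_max(pwm, uniform_bg):
    cons = pwm.consensus()
    assert score_window(cons, pwm, uniform_bg) == pytest.approx(max_score(pwm, uniform_bg))


def test_scan_finds_planted_consensus_and_matches_bruteforce(pwm, uniform_bg):
    rng = np.random.default_rng(42)
    bgseq = "".join(rng.choice(list("ACGT"), size=200))
    cons = pwm.consensus()
    seq = bgseq[:50] + cons + bgseq[50:130] + revcomp(cons) + bgseq[130:]
    genome = {"chr1": seq}
    hits = scan_genome(genome, pwm, uniform_bg, rel_threshold=0.5)
    found = {(h.start, h.strand) for h in hits}
    assert (50, "+") in found
    assert (142, "-") in found  # 50 + W + 80 = start of the reverse plant
    # brute force: rescore every window on both strands independently
    threshold = 0.5 * max_score(pwm, uniform_bg)
    sm = motif.score_matrix(pwm, uniform_bg)
    expected = set()
    for pos in range(len(seq) - pwm.width + 1):
        window = seq[pos : pos + pwm.width]
        for strand, w in (("+", window), ("-", revcomp(window))):
            s = sum(sm["ACGT".index(b), j] for j, b in enumerate(w))
            if s >= threshold:
                expected.add((pos, strand, round(s, 8)))
    got = {(h.start, h.strand, round(h.score, 8)) for h in hits}
    assert got == expected


def test_scan_skips_ambiguous_windows(pwm, uniform_bg):
    cons = pwm.consensus()
    seq = cons[:5] + "N" + cons[6:]
    assert scan_genome({"chr1": seq}, pwm, uniform_bg) == []


def test_scan_strand_symmetry(genome_bundle, pwm, uniform_bg):
    genomes, *_ = genome_bundle
    fwd = scan_genome(genomes["focal"], pwm, uniform_bg)
    L = len(genomes["focal"]["chr1"])
    rc = {"chr1": revcomp(genomes["focal"]["chr1"])}
    back = scan_genome(rc, pwm, uniform_bg)
    flipped = {(L - h.end, L - h.start, "+-"["+-".index(h.strand) ^ 1], round(h.score, 6))
               for h in back}
    orig = {(h.start, h.end, h.strand, round(h.score, 6)) for h in fwd}
    assert flipped == orig


def test_scan_monotone_in_threshold(genome_bundle, pwm, uniform_bg):
    genomes, *_ = genome_bundle
    counts = [
        len(scan_genome(genomes["focal"], pwm, uniform_bg, rel_threshold=t))
        for t in (0.3, 0.5, 0.7, 0.9)
    ]
    assert counts == sorted(counts, reverse=True)


def test_scan_rejects_nonpositive_max_score():
    flat = PWMatrix(np.full((4, 3), 5.0), pseudocount=0.0)
    with pytest.raises(ValueError):
        scan_genome({"c": "ACGTACGT"}, flat, BackgroundModel.uniform())


# ---------------------------------------------------------------------------
# conservation


def test_conservation_counts_match_plan(genome_bundle, pwm, uniform_bg):
    genomes, blocks, _, _, truth = genome_bundle
    hits = scan_genome(genomes["focal"], pwm, uniform_bg)
    kept = conservation_filter(
        hits, blocks, pwm, uniform_bg, focal_species="focal", min_species=0
    )
    support = {h.start: h for h in kept}
    for site, plan in zip(truth.planted_sites, truth.planted_site_species):
        h = support[site["start"]]
        assert h.species_support == len(plan)
        assert set(h.species) == plan


def test_conservation_filter_removes_unsupported_sites(genome_bundle, pwm, uniform_bg):
    genomes, blocks, _, _, truth = genome_bundle
    hits = scan_genome(genomes["focal"], pwm, uniform_bg)
    kept2 = conservation_filter(
        hits, blocks, pwm, uniform_bg, focal_species="focal", min_species=2
    )
    starts = {h.start for h in kept2}
    for site, plan in zip(truth.planted_sites, truth.planted_site_species):
        assert (site["start"] in starts) == (len(plan) >= 2)
    # monotone in min_species
    sizes = [
        len(conservation_filter(hits, blocks, pwm, uniform_bg, "focal", min_species=k))
        for k in (0, 1, 2, 3, 4)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_aligned_copy_below_threshold_not_counted(pwm, uniform_bg):
    """A species whose aligned window scores just below the threshold is not
    conserved support; at or above, it is."""
    from ksdev.motif import MafBlock
    from ksdev.synthetic import _degrade

    cons = pwm.consensus()
    hit = SiteHit("chr1", 0, pwm.width, "+", max_score(pwm, uniform_bg))
    degraded = _degrade(cons, pwm, uniform_bg, 0.5)
    blocks = [MafBlock(rows={
        "focal": ("chr1", 0, cons), "spA": ("chr1", 0, degraded), "spB": ("chr1", 0, cons),
    })]
    kept = conservation_filter([hit], blocks, pwm, uniform_bg, "focal", min_species=0)
    assert kept[0].species == ("spB",)
    # a hit with no aligned block at all has zero support
    orphan = SiteHit("chr1", 500, 500 + pwm.width, "+", 10.0)
    kept2 = conservation_filter([orphan], blocks, pwm, uniform_bg, "focal", min_species=0)
    assert kept2[0].species_support == 0


# ---------------------------------------------------------------------------
# target association and ranking


def _tss_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def test_associate_targets_best_rule_boundary(pwm):
    W = pwm.width
    near = SiteHit("chr1", 1000, 1000 + W, "+", 10.0, species_support=3)
    tss = _tss_frame([("chr1", 1000 + W - 1 + 9999, 1000 + W + 9999, "gA|t1", 0, "+")])
    assoc = associate_targets([near], tss)
    assert assoc[0].min_tss_distance == 9999 and assoc[0].is_best
    tss10k = _tss_frame([("chr1", 1000 + W - 1 + 10_000, 1000 + W + 10_000, "gA|t1", 0, "+")])
    assoc2 = associate_targets([near], tss10k)
    assert assoc2[0].min_tss_distance == 10_000 and not assoc2[0].is_best
    # support below 3 never qualifies as best regardless of distance
    weak = SiteHit("chr1", 1000, 1000 + W, "+", 10.0, species_support=2)
    assert not associate_targets([weak], tss)[0].is_best


def test_associate_targets_tie_breaks_to_lower_coordinate(pwm):
    W = pwm.width
    hit = SiteHit("chr1", 5000, 5000 + W, "+", 8.0, species_support=2)
    tss = _tss_frame([
        ("chr1", 5000 - 100, 5000 - 99, "gLeft|t1", 0, "+"),
        ("chr1", 5000 + W - 1 + 100, 5000 + W + 100, "gRight|t2", 0, "+"),
    ])
    assoc = associate_targets([hit], tss)
    assert [a.gene for a in assoc] == ["gLeft"]
    with pytest.raises(ValueError):
        associate_targets([hit], tss.iloc[:0])


def test_associate_targets_hand_map(genome_bundle, pwm, uniform_bg):
    genomes, blocks, tss, _, truth = genome_bundle
    hits = scan_genome(genomes["focal"], pwm, uniform_bg)
    kept = conservation_filter(hits, blocks, pwm, uniform_bg, "focal", min_species=0)
    assocs = associate_targets(kept, tss, max_dist=200_000)
    by_gene = {a.gene: a for a in assocs}
    for gene, dist in zip(truth.site_genes, truth.tss_distances):
        assert by_gene[gene].min_tss_distance == dist


def test_rank_targets_dominance_and_aggregation(pwm, uniform_bg):
    smax = max_score(pwm, uniform_bg)
    strong = motif.TargetAssoc(
        gene="gStrong", transcript="t1", min_tss_distance=0,
        sites=[SiteHit("c", 0, pwm.width, "+", smax, species_support=8)],
        max_species_support=8,
    )
    weak = motif.TargetAssoc(
        gene="gWeak", transcript="t2", min_tss_distance=9000,
        sites=[SiteHit("c", 0, pwm.width, "+", 0.5 * smax, species_support=2)],
        max_species_support=2,
    )
    ranked = rank_targets([weak, strong], pwm, uniform_bg)
    assert [a.gene for a in ranked] == ["gStrong", "gWeak"]
    assert ranked[0].rank_score > ranked[1].rank_score
    with pytest.raises(ValueError):
        rank_targets([], pwm, uniform_bg)


def test_more_planted_sites_rank_higher(pwm, uniform_bg):
    """A gene with three conserved sites near its TSS outranks a gene with
    one."""
    W = pwm.width
    sites_g1 = [
        SiteHit("c", 100 * i, 100 * i + W, "+", max_score(pwm, uniform_bg), species_support=3)
        for i in range(3)
    ]
    tss = _tss_frame(
        [("c", 50, 51, "g1|t1", 0, "+"), ("c", 5000, 5001, "g2|t2", 0, "+")]
    )
    site_g2 = [SiteHit("c", 4900, 4900 + W, "+", max_score(pwm, uniform_bg), species_support=3)]
    assocs = associate_targets(sites_g1 + site_g2, tss, max_dist=1000)
    ranked = rank_targets(assocs, pwm, uniform_bg, tss=tss)
    assert [a.gene for a in ranked] == ["g1", "g2"]
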