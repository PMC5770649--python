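"""Discovery engine: scan semantics, filters, exclusion rules, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrscout import (
    CoverageTrack,
    GeneModel,
    SyntheticTruth,
    UtrCandidate,
    apply_exclusion_rules,
    call_upstream_transcription,
    discover,
    filter_comparable_expression,
    filter_min_length,
    generate_coverage,
    generate_genome,
    plant_utrs,
    prioritize_candidates,
)


# ---------------------------------------------------------------------------
# an independent per-base oracle: walk upstream one base at a time


def oracle_tss(track, gene, genes, genome_length, min_depth, max_gap, max_scan):
    blocked = set()
    for other in genes:
        if other is not gene and other.strand == gene.strand:
            blocked.update(range(other.cds_start, other.cds_end))
    if gene.strand == "+":
        positions = range(gene.cds_start - 1, -1, -1)
        dist = lambda p: gene.cds_start - p
    else:
        positions = range(gene.cds_end, genome_length)
        dist = lambda p: p - gene.cds_end + 1
    best, gap = None, 0
    for p in positions:
        if dist(p) > max_scan or p in blocked:
            break
        if track[p] >= min_depth:
            best, gap = p, 0
        else:
            gap += 1
            if gap > max_gap:
                break
    return best


def _make_candidate(gene_id="g", strand="+", tss=50, cds_start=100, length=None,
                    ratio=1.0, product="", flags=None):
    if strand == "+":
        start, end = tss, cds_start
    else:
        start, end = cds_start, tss + 1
    return UtrCandidate(
        gene_id=gene_id, strand=strand, tss=tss, utr_start=start, utr_end=end,
        mean_utr_depth=ratio * 100, mean_cds_depth=100, expression_ratio=ratio,
        product=product, flags=set(flags or ()),
    )


# ---------------------------------------------------------------------------
# calling


def test_no_upstream_coverage_yields_no_candidates():
    genes = [GeneModel("g1", "+", 1000, 2000), GeneModel("g2", "-", 3000, 4000)]
    cov = CoverageTrack(np.zeros(5000), np.zeros(5000))
    cov.plus[1000:2000] = 100  # CDS only
    cov.minus[3000:4000] = 100
    assert call_upstream_transcription(cov, genes) == []


def test_planted_utr_recovered_exactly(small_study):
    _, truth, cov = small_study
    candidates = call_upstream_transcription(cov, truth.genes, min_depth=5)
    tss_truth = {u.gene_id: u.tss for u in truth.utrs}
    assert len(candidates) == len(truth.utrs)
    for cand in candidates:
        assert cand.length == 50
        assert cand.tss == tss_truth[cand.gene_id]
        assert cand.expression_ratio == pytest.approx(1.0)


def test_scan_truncates_at_long_gap():
    genes = [GeneModel("g", "+", 100, 400)]
    plus = np.zeros(500)
    plus[100:400] = 100
    plus[40:100] = 100  # 60 nt upstream plateau ...
    plus[60:75] = 0  # ... interrupted by a 15 nt hole
    cov = CoverageTrack(plus, np.zeros(500))
    (cand,) = call_upstream_transcription(cov, genes, min_depth=5, max_gap=10)
    assert cand.tss == 75  # truncated at the proximal side of the gap
    assert cand.utr_interval == (75, 100)


def test_gap_within_tolerance_is_bridged():
    genes = [GeneModel("g", "+", 100, 400)]
    plus = np.zeros(500)
    plus[100:400] = 100
    plus[40:100] = 100
    plus[60:68] = 0  # 8 nt <= max_gap
    cov = CoverageTrack(plus, np.zeros(500))
    (cand,) = call_upstream_transcription(cov, genes, min_depth=5, max_gap=10)
    assert cand.tss == 40


def test_scan_stops_at_same_strand_gene_but_not_opposite():
    # upstream neighbour on the same strand blocks; opposite strand does not
    plus = np.zeros(2000)
    plus[200:1500] = 100  # continuous coverage across everything
    for neighbour_strand, expected_tss in (("+", 1000), ("-", 1500 - 600)):
        genes = [
            GeneModel("up", neighbour_strand, 900, 1000),
            GeneModel("g", "+", 1500, 1900),
        ]
        cov = CoverageTrack(plus.copy(), plus.copy())
        (cand,) = [
            c for c in call_upstream_transcription(cov, genes, max_scan=600)
            if c.gene_id == "g"
        ]
        assert cand.tss == expected_tss


def test_abutting_upstream_gene_yields_no_candidate_not_error():
    genes = [GeneModel("up", "+", 500, 1000), GeneModel("g", "+", 1000, 1500)]
    plus = np.zeros(2000)
    plus[500:1500] = 50
    cov = CoverageTrack(plus, np.zeros(2000))
    out = call_upstream_transcription(cov, genes)
    assert all(c.gene_id != "g" for c in out)


def test_gene_outside_coverage_is_an_error():
    genes = [GeneModel("g", "+", 100, 900)]
    cov = CoverageTrack(np.zeros(500), np.zeros(500))
    with pytest.raises(ValueError, match="outside genome"):
        call_upstream_transcription(cov, genes)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_oracle_equivalence_on_small_genomes(seed):
    """Candidate TSS match an independent per-base upstream walk exactly."""
    sequence, genes = generate_genome(
        4, 5000, seed=seed, min_gap=120, cds_length_range=(150, 400)
    )
    utrs = plant_utrs(genes, 5000, seed=seed, length_range=(10, 100))
    truth = SyntheticTruth(genes=genes, utrs=utrs, seed=seed)
    cov = generate_coverage(truth, 5000, mean_depth=60, background_depth=2)
    candidates = {
        c.gene_id: c for c in call_upstream_transcription(cov, genes, min_depth=5)
    }
    for gene in genes:
        expected = oracle_tss(
            cov.strand(gene.strand), gene, genes, 5000,
            min_depth=5, max_gap=10, max_scan=600,
        )
        got = candidates.get(gene.gene_id)
        assert (got.tss if got else None) == expected


# ---------------------------------------------------------------------------
# filters


def test_comparable_expression_threshold_is_inclusive():
    cands = [
        _make_candidate("a", ratio=0.5),
        _make_candidate("b", ratio=0.25),
        _make_candidate("c", ratio=0.249),
    ]
    kept = filter_comparable_expression(cands, min_ratio=0.25)
    assert [c.gene_id for c in kept] == ["a", "b"]
    assert all("passed_comparable" in c.flags for c in kept)


def test_comparable_expression_on_planted_ratios(small_study):
    _, truth, _ = small_study
    genes = truth.genes[:3]
    ratios = {genes[0].gene_id: 0.1, genes[1].gene_id: 0.3, genes[2].gene_id: 1.0}
    utrs = plant_utrs(genes, 50_000, lengths=50, ratios=ratios, seed=5)
    sub_truth = SyntheticTruth(genes=genes, utrs=utrs, seed=5)
    cov = generate_coverage(sub_truth, 50_000, mean_depth=100, noise_model="none")
    called = call_upstream_transcription(cov, genes)
    kept = filter_comparable_expression(called, min_ratio=0.25)
    assert {c.gene_id for c in kept} == {genes[1].gene_id, genes[2].gene_id}


def test_min_length_boundary():
    cands = [
        _make_candidate("short", tss=66, cds_start=100),  # 34 nt
        _make_candidate("exact", tss=65, cds_start=100),  # 35 nt
    ]
    kept = filter_min_length(cands, min_length=35)
    assert [c.gene_id for c in kept] == ["exact"]
    assert filter_min_length([]) == []


def test_prioritize_metabolic_enzymes_stably():
    products = [
        "hypothetical protein",
        "Thioredoxin reductase",
        "membrane protein",
        "sugar Transporter",
        "acetolactate synthase",
    ]
    cands = [_make_candidate(f"g{i}", product=p) for i, p in enumerate(products)]
    out = prioritize_candidates(cands)
    assert [c.gene_id for c in out] == ["g1", "g3", "g4", "g0", "g2"]
    assert all("prioritized" in c.flags for c in out[:3])
    # empty keyword list: order untouched, nothing flagged
    out2 = prioritize_candidates(
        [_make_candidate(f"g{i}", product=p) for i, p in enumerate(products)], keywords=[]
    )
    assert [c.gene_id for c in out2] == [f"g{i}" for i in range(5)]


# ---------------------------------------------------------------------------
# exclusion rules


def test_exclusion_overlap_by_one_base():
    genes = [GeneModel("up", "+", 100, 200), GeneModel("g", "+", 300, 600)]
    cand = _make_candidate("g", tss=199, cds_start=300, flags={"confirmed_rtpcr"})
    kept, excluded = apply_exclusion_rules([cand], genes)
    assert kept == [] and "excluded_overlap" in excluded[0].flags


def test_exclusion_race_length_boundary():
    genes = [GeneModel("g", "+", 300, 600)]
    for race_tss, expect_kept in ((271, False), (270, True)):  # 29 vs 30 nt
        cand = _make_candidate("g", tss=200, cds_start=300, flags={"confirmed_rtpcr"})
        kept, excluded = apply_exclusion_rules(
            [cand], genes, race_tss={"g": race_tss}, min_final_length=30
        )
        assert bool(kept) == expect_kept


def test_exclusion_rule_table_exhaustive():
    """All 8 combinations of (overlaps, short-after-race, confirmed) match a
    brute-force rule table: kept iff confirmed and not overlapping and not
    short."""
    for overlap, short, confirmed in itertools.product([False, True], repeat=3):
        up_end = 250 if overlap else 200  # candidate interval starts at 240
        genes = [GeneModel("up", "+", 100, up_end), GeneModel("g", "+", 300, 600)]
        race_tss = {"g": 280} if short else {"g": 240}  # 20 vs 60 nt refined
        flags = {"confirmed_rtpcr"} if confirmed else set()
        cand = _make_candidate("g", tss=240, cds_start=300, flags=flags)
        kept, excluded = apply_exclusion_rules([cand], genes, race_tss=race_tss)
        expected_kept = confirmed and not overlap and not short
        assert bool(kept) == expected_kept, (overlap, short, confirmed)
        if overlap:
            assert "excluded_overlap" in excluded[0].flags
        if short:
            assert "excluded_short_after_race" in (kept + excluded)[0].flags


# ---------------------------------------------------------------------------
# invariants


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    min_depth=st.integers(1, 30),
    min_ratio=st.floats(0.0, 1.5),
    min_length=st.integers(1, 120),
)
def test_filters_are_monotone(seed, min_depth, min_ratio, min_length):
    """Tightening any threshold never increases the surviving set."""
    rng = np.random.default_rng(seed)
    genes = [GeneModel("a", "+", 600, 1200), GeneModel("b", "-", 1500, 2100)]
    cov = CoverageTrack(rng.poisson(12, 3000).astype(float),
                        rng.poisson(12, 3000).astype(float))

    def survivors(md, mr, ml):
        return len(discover(cov, genes, min_depth=md, min_ratio=mr, min_length=ml))

    base = survivors(min_depth, min_ratio, min_length)
    assert survivors(min_depth + 5, min_ratio, min_length) <= base
    assert survivors(min_depth, min_ratio + 0.3, min_length) <= base
    assert survivors(min_depth, min_ratio, min_length + 20) <= base


def test_strand_symmetry(small_study):
    """Mirroring the genome (and swapping strands/tracks) mirrors the calls
    with identical lengths and expression ratios."""
    _, truth, cov = small_study
    L = cov.genome_length
    flipped_genes = [
        GeneModel(g.gene_id, "-" if g.strand == "+" else "+",
                  L - g.cds_end, L - g.cds_start, g.product)
        for g in truth.genes
    ]
    flipped_cov = CoverageTrack(plus=cov.minus[::-1].copy(), minus=cov.plus[::-1].copy())
    fwd = {c.gene_id: c for c in call_upstream_transcription(cov, truth.genes)}
    rev = {c.gene_id: c for c in call_upstream_transcription(flipped_cov, flipped_genes)}
    assert set(fwd) == set(rev)
    for gene_id, a in fwd.items():
        b = rev[gene_id]
        assert b.length == a.length
        assert b.expression_ratio == pytest.approx(a.expression_ratio)
        assert b.tss == L - 1 - a.tss
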