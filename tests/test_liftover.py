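"""Seed index, banded aligner, best-hit selection, feature derivation."""

import random

import pytest

from strainlift import liftover
from strainlift.liftover import (
    KmerIndex,
    banded_local_alignment,
    build_kmer_index,
    derive_gene_spans,
    find_best_hit,
    identity_summary,
    lift_exons,
    reverse_complement,
    select_best,
)
from strainlift.models import AlignmentHit, ExonRecord, GenomeInterval, LiftedFeature


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


# ---------------------------------------------------------------------------
# K-mer index


def test_kmer_index_positions_and_absent_kmer():
    index = build_kmer_index({"chr1": "ACGTACGTACGT"}, k=8)
    assert list(index.lookup("ACGTACGT")) == [("chr1", 0), ("chr1", 4)]
    assert list(index.lookup("TTTTTTTT")) == []


def test_kmer_index_skips_n_and_validates_k():
    index = build_kmer_index({"chr1": "ACGTNCGTACGTACGT"}, k=8)
    assert all("N" not in k for k in index._positions)
    with pytest.raises(ValueError):
        build_kmer_index({"chr1": "ACGTACGTACGT"}, k=4)
    with pytest.raises(ValueError):
        build_kmer_index({"chr1": "ACGT"}, k=8)


def test_kmer_index_reverse_complement_symmetry():
    """The index of a genome and of its reverse complement expose the
    same seeds with flipped strand/coordinates."""
    rng = random.Random(11)
    genome = _random_dna(rng, 300)
    k = 10
    fwd = build_kmer_index({"c": genome}, k=k)
    rev = build_kmer_index({"c": reverse_complement(genome)}, k=k)
    for i in range(0, len(genome) - k + 1, 7):
        kmer = genome[i : i + k]
        fwd_pos = {p for _, p in fwd.lookup(kmer)}
        rc_pos = {len(genome) - k - p for _, p in rev.lookup(reverse_complement(kmer))}
        assert fwd_pos == rc_pos


# ---------------------------------------------------------------------------
# Banded aligner vs an unbanded Smith-Waterman oracle


def _full_smith_waterman(q, t, match=1, mismatch=-2, gap_open=-4, gap_extend=-1):
    """Independent unbanded affine local alignment; returns best score."""
    n, m = len(q), len(t)
    NEG = -(1 << 30)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            M[i][j] = max(0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_extend)
            Y[i][j] = max(M[i - 1][j] + gap_open, Y[i - 1][j] + gap_extend)
            best = max(best, M[i][j])
    return best


def test_banded_alignment_matches_full_dp_oracle():
    rng = random.Random(5)
    for trial in range(40):
        t = _random_dna(rng, rng.randint(20, 40))
        # query: a mutated slice of the target, so the optimum sits near
        # the main diagonal covered by a wide band
        a = rng.randint(0, len(t) // 2)
        b = rng.randint(a + 8, len(t))
        q = list(t[a:b])
        for _ in range(rng.randint(0, 3)):
            op = rng.random()
            pos = rng.randrange(len(q))
            if op < 0.5:
                q[pos] = rng.choice("ACGT")
            elif op < 0.75 and len(q) > 9:
                del q[pos]
            else:
                q.insert(pos, rng.choice("ACGT"))
        q = "".join(q)
        aln = banded_local_alignment(q, t, diag=a, band=len(t))
        expected = _full_smith_waterman(q, t)
        got = aln.score if aln else 0
        assert got == expected, (q, t, a)
        if aln:
            assert aln.matches + aln.mismatches + (
                aln.columns - aln.matches - aln.mismatches
            ) == aln.columns


def test_banded_alignment_exact_match_coordinates():
    t = "GGGGACGTACGTTTTT"
    aln = banded_local_alignment("ACGTACGT", t, diag=4, band=4)
    assert (aln.t_start, aln.t_end) == (4, 12)
    assert (aln.q_start, aln.q_end) == (0, 8)
    assert aln.matches == 8 and aln.mismatches == 0 and aln.gap_opens == 0


# ---------------------------------------------------------------------------
# find_best_hit


@pytest.fixture(scope="module")
def toy_genome():
    rng = random.Random(42)
    return {"chrA": _random_dna(rng, 2000), "chrB": _random_dna(rng, 1500)}


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return build_kmer_index(toy_genome, k=16)


def _exon(seq, exon_id="EX1", strand="+"):
    return ExonRecord(exon_id, "G1", "Abc", "chr1", strand, seq)


def test_find_best_hit_exact_substring(toy_genome, toy_index):
    seq = toy_genome["chrA"][300:420]
    hit = find_best_hit(_exon(seq), toy_index, toy_genome)
    assert hit.percent_identity == 100.0
    assert hit.target_chromosome == "chrA"
    assert (hit.target_interval.start, hit.target_interval.end) == (300, 420)
    assert hit.strand == "+"


def test_find_best_hit_single_substitution_identity(toy_genome, toy_index):
    base = toy_genome["chrB"][500:600]
    mutated = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
    hit = find_best_hit(_exon(mutated), toy_index, toy_genome)
    assert hit.percent_identity == 99.0
    assert hit.mismatches == 1
    assert (hit.target_interval.start, hit.target_interval.end) == (500, 600)


def test_find_best_hit_reverse_complement_same_interval(toy_genome, toy_index):
    seq = toy_genome["chrA"][700:820]
    fwd = find_best_hit(_exon(seq), toy_index, toy_genome)
    rev = find_best_hit(_exon(reverse_complement(seq)), toy_index, toy_genome)
    assert fwd.strand == "+" and rev.strand == "-"
    assert fwd.target_interval == rev.target_interval
    assert fwd.percent_identity == rev.percent_identity == 100.0


def test_find_best_hit_no_seed_returns_none(toy_genome, toy_index):
    hit = find_best_hit(_exon("A" * 40), toy_index, toy_genome)
    assert hit is None or hit.percent_identity < 100  # poly-A unlikely present
    hit2 = find_best_hit(
        _exon("ACGT" * 10), toy_index, toy_genome, min_coverage=1.01
    )
    assert hit2 is None  # impossible coverage bound


# ---------------------------------------------------------------------------
# select_best


def _hit(score=50.0, pid=100.0, alen=100, chrom="chr1", start=100, qid="E1"):
    return AlignmentHit(
        query_id=qid,
        target_chromosome=chrom,
        target_interval=GenomeInterval(chrom, start, start + alen),
        strand="+",
        percent_identity=pid,
        alignment_length=alen,
        mismatches=0,
        gap_opens=0,
        score=score,
    )


def test_select_best_ordering_and_tie_breaks():
    assert select_best([_hit(score=50), _hit(score=40)]).score == 50
    assert select_best([_hit(pid=100.0), _hit(pid=99.0)]).percent_identity == 100.0
    tied = [_hit(chrom="chr2", start=500), _hit(chrom="chr1", start=900)]
    best = select_best(tied)
    assert (best.target_chromosome, best.target_interval.start) == ("chr1", 900)


def test_select_best_permutation_invariant():
    rng = random.Random(3)
    hits = [
        _hit(score=s, pid=p, start=st)
        for s, p, st in [(50, 99, 10), (50, 99, 5), (40, 100, 1), (50, 98, 2)]
    ]
    picks = set()
    for _ in range(10):
        rng.shuffle(hits)
        b = select_best(hits)
        picks.add((b.score, b.percent_identity, b.target_interval.start))
    assert picks == {(50.0, 99.0, 5)}


def test_select_best_rejects_empty_and_mixed_queries():
    with pytest.raises(ValueError):
        select_best([])
    with pytest.raises(ValueError):
        select_best([_hit(qid="E1"), _hit(qid="E2")])


# ---------------------------------------------------------------------------
# lift_exons / derive_gene_spans / identity_summary


@pytest.mark.parametrize(
    "gene_strand,hit_strand,expected",
    [("+", "+", "+"), ("+", "-", "-"), ("-", "+", "-"), ("-", "-", "+")],
)
def test_lift_exons_strand_composition(gene_strand, hit_strand, expected):
    exon = ExonRecord("E1", "G1", "Abc", "chr1", gene_strand, "ACGTACGTAC")
    hit = AlignmentHit("E1", "t1", GenomeInterval("t1", 10, 20), hit_strand,
                       100.0, 10, 0, 0, 10.0)
    (feature,) = lift_exons([exon], {"E1": hit})
    assert feature.strand == expected
    assert feature.kind == "exon" and feature.percent_identity == 100.0


def test_lift_exons_unmapped_dropped_and_unknown_rejected():
    exons = [
        ExonRecord(f"E{i}", "G1", "Abc", "chr1", "+", "ACGTACGT")
        for i in range(3)
    ]
    hit = AlignmentHit("E0", "t1", GenomeInterval("t1", 0, 8), "+",
                       100.0, 8, 0, 0, 8.0)
    hit2 = AlignmentHit("E2", "t1", GenomeInterval("t1", 50, 58), "+",
                        100.0, 8, 0, 0, 8.0)
    features = lift_exons(exons, {"E0": hit, "E2": hit2})
    assert [f.exon_id for f in features] == ["E0", "E2"]
    stray = AlignmentHit("EX9", "t1", GenomeInterval("t1", 0, 8), "+",
                         100.0, 8, 0, 0, 8.0)
    with pytest.raises(ValueError, match="EX9"):
        lift_exons(exons, {"EX9": stray})


def _exon_feature(exon_id, gene_id, chrom, start, end, strand="+"):
    return LiftedFeature("exon", GenomeInterval(chrom, start, end), exon_id,
                         gene_id, "Abc", strand, 99.0)


def test_derive_gene_spans_outermost_and_single_exon():
    feats = [
        _exon_feature("E1", "G1", "chr1", 100, 200),
        _exon_feature("E2", "G1", "chr1", 500, 600),
        _exon_feature("E3", "G2", "chr1", 900, 950),
    ]
    spans = {f.gene_id: f for f in derive_gene_spans(feats)}
    assert spans["G1"].interval == GenomeInterval("chr1", 100, 600)
    assert spans["G2"].interval == GenomeInterval("chr1", 900, 950)
    assert spans["G1"].kind == "gene" and spans["G1"].percent_identity is None


def test_derive_gene_spans_majority_chromosome():
    feats = [
        _exon_feature("E1", "G1", "chr1", 100, 200),
        _exon_feature("E2", "G1", "chr1", 300, 400),
        _exon_feature("E3", "G1", "chr1", 500, 600),
        _exon_feature("E4", "G1", "chr2", 900, 950),
    ]
    (span,) = derive_gene_spans(feats)
    assert span.interval == GenomeInterval("chr1", 100, 600)


def test_derive_gene_spans_majority_strand():
    feats = [
        _exon_feature("E1", "G1", "chr1", 100, 200, "-"),
        _exon_feature("E2", "G1", "chr1", 300, 400, "-"),
        _exon_feature("E3", "G1", "chr1", 500, 600, "+"),
    ]
    (span,) = derive_gene_spans(feats)
    assert span.strand == "-"


def test_identity_summary_statistics():
    hits = [
        _hit(pid=100.0, qid="E1"),
        _hit(pid=99.0, qid="E2"),
        _hit(pid=98.0, qid="E3"),
    ]
    chroms = {"E1": "chr1", "E2": "chr1", "E3": "chr2"}
    table, overall = identity_summary(hits, chroms)
    assert overall == pytest.approx(99.0)
    row1 = table[table["chromosome"] == "chr1"].iloc[0]
    assert row1["n"] == 2 and row1["min"] == 99.0 and row1["mean"] == 99.5
    assert int(table["n"].sum()) == 3
    empty_table, none_overall = identity_summary([], {})
    assert none_overall is None and len(empty_table) == 0
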