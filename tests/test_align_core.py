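import itertools
import math
import random

import pytest

from tadscan.align_core import (HSP, ScoringScheme, global_alignment,
                                global_identity, read_tabular, revcomp,
                                seeded_search, smith_waterman, write_tabular)

from oracles import make_local_oracle


def test_identity_alignment_scores_full_length(nt_unit_scheme):
    a = "ACGTACGTAC"
    res = smith_waterman(a, a, nt_unit_scheme)
    assert res.score == len(a)
    assert res.hsp.pct_identity == 100.0
    assert (res.hsp.q_start, res.hsp.q_end) == (0, len(a))


def test_disjoint_alphabets_give_empty_alignment(nt_unit_scheme):
    res = smith_waterman("AAAA", "CCCC", nt_unit_scheme)
    assert res.score == 0
    assert res.hsp is None
    assert res.aligned_a == ""


def test_alphabet_mismatch_raises(nt_unit_scheme):
    with pytest.raises(ValueError, match="alphabet"):
        smith_waterman("ACGT", "ACXT", nt_unit_scheme)


def test_local_score_matches_path_enumeration(nt_unit_scheme):
    """Sampled sequence pairs over {A,C}: DP equals exhaustive enumeration
    of all affine-gap local alignment paths."""
    oracle = make_local_oracle(match=1, mismatch=-1, gap_open=2,
                               gap_extend=1)
    rng = random.Random(11)
    for _ in range(150):
        a = "".join(rng.choice("AC") for _ in range(rng.randint(1, 5)))
        b = "".join(rng.choice("AC") for _ in range(rng.randint(1, 5)))
        assert smith_waterman(a, b, nt_unit_scheme).score == oracle(a, b), \
            (a, b)


def test_exact_substring_yields_full_identity_hsp():
    rng = random.Random(5)
    subject = "".join(rng.choice("ACGT") for _ in range(1500))
    query = subject[400:700]
    scheme = ScoringScheme.nucleotide()
    hits = seeded_search({"q": query}, {"s": subject}, scheme)
    assert len(hits) == 1
    h = hits[0]
    assert (h.s_start, h.s_end, h.subject_strand) == (400, 700, "+")
    assert h.pct_identity == 100.0


def test_reverse_complement_query_maps_to_minus_strand():
    rng = random.Random(6)
    subject = "".join(rng.choice("ACGT") for _ in range(1500))
    query = revcomp(subject[400:700])
    hits = seeded_search({"q": query}, {"s": subject},
                         ScoringScheme.nucleotide())
    assert len(hits) == 1
    h = hits[0]
    assert (h.s_start, h.s_end, h.subject_strand) == (400, 700, "-")
    assert (h.q_start, h.q_end) == (0, 300)


def test_searching_reverse_complemented_subject_swaps_strands():
    rng = random.Random(7)
    subject = "".join(rng.choice("ACGT") for _ in range(1200))
    query = subject[200:500]
    scheme = ScoringScheme.nucleotide()
    fwd = seeded_search({"q": query}, {"s": subject}, scheme)
    rev = seeded_search({"q": query}, {"s": revcomp(subject)}, scheme)
    assert len(fwd) == len(rev) == 1
    L = len(subject)
    assert fwd[0].subject_strand == "+" and rev[0].subject_strand == "-"
    assert (rev[0].s_start, rev[0].s_end) == \
        (L - fwd[0].s_end, L - fwd[0].s_start)
    assert rev[0].bitscore == fwd[0].bitscore


def test_seeded_search_never_beats_smith_waterman_and_k1_attains_it(
        nt_unit_scheme):
    rng = random.Random(8)
    for _ in range(40):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 14)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 14)))
        sw = max(smith_waterman(a, b, nt_unit_scheme).score,
                 smith_waterman(revcomp(a), b, nt_unit_scheme).score)
        hits = seeded_search({"q": a}, {"s": b}, nt_unit_scheme, k=1)
        best_bits = max((h.bitscore for h in hits), default=None)
        if sw <= 0:
            assert best_bits is None
        else:
            assert best_bits == pytest.approx(
                nt_unit_scheme.bitscore(sw), abs=1e-9)


def test_empty_query_set_returns_empty():
    assert seeded_search({}, {"s": "ACGT"},
                         ScoringScheme.nucleotide()) == []


def test_evalue_monotone_in_bitscore_and_linear_in_k():
    s = ScoringScheme.nucleotide()
    e1 = s.evalue(100, 500, 10000)
    e2 = s.evalue(120, 500, 10000)
    assert e2 < e1
    s2 = ScoringScheme(mode="nucleotide", karlin_lambda=s.karlin_lambda,
                       karlin_k=2 * s.karlin_k)
    assert s2.evalue(100, 500, 10000) == pytest.approx(2 * e1)
    assert s.bitscore(120) > s.bitscore(100)


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(mode="nucleotide", gap_open=1, gap_extend=2)
    with pytest.raises(ValueError):
        ScoringScheme(mode="nucleotide", karlin_lambda=0.0)
    with pytest.raises(ValueError):
        ScoringScheme(mode="rna")


def _random_hsp(rng):
    q0 = rng.randrange(0, 500)
    s0 = rng.randrange(0, 5000)
    qlen = rng.randrange(1, 300)
    slen = rng.randrange(2, 300)  # 1-bp minus intervals are inexpressible
    aln = max(qlen, slen) + rng.randrange(0, 20)
    matches = rng.randrange(0, aln + 1)
    return HSP(query_id=f"q{rng.randrange(5)}",
               subject_id=f"s{rng.randrange(3)}",
               q_start=q0, q_end=q0 + qlen, s_start=s0, s_end=s0 + slen,
               subject_strand=rng.choice("+-"),
               pct_identity=round(100.0 * matches / aln, 3),
               aln_length=aln, mismatches=aln - matches,
               gap_opens=rng.randrange(0, 5),
               bitscore=round(rng.uniform(20, 500), 1),
               evalue=float(f"{rng.uniform(1e-50, 1e-2):.3g}"))


def test_tabular_round_trip_is_identity(tmp_path):
    rng = random.Random(9)
    hsps = [_random_hsp(rng) for _ in range(300)]
    path = tmp_path / "hits.tsv"
    write_tabular(hsps, path)
    assert read_tabular(path) == hsps


def test_tabular_minus_strand_encoding(tmp_path):
    h = HSP(query_id="q", subject_id="s", q_start=0, q_end=50,
            s_start=100, s_end=150, subject_strand="-",
            pct_identity=100.0, aln_length=50, bitscore=95.0,
            evalue=1e-20)
    path = tmp_path / "m.tsv"
    write_tabular([h], path)
    fields = path.read_text().split("\t")
    assert (fields[8], fields[9]) == ("150", "101")  # sstart > send
    assert read_tabular(path) == [h]


def test_tabular_plus_strand_convention(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("q\ts\t100.000\t50\t0\t0\t1\t50\t101\t150\t1e-20\t95.0\n")
    (h,) = read_tabular(path)
    assert (h.q_start, h.q_end) == (0, 50)
    assert (h.s_start, h.s_end, h.subject_strand) == (100, 150, "+")


def test_tabular_wrong_column_count_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("q\ts\t100.0\n")
    with pytest.raises(ValueError, match="line 1"):
        read_tabular(path)


def test_global_identity_extremes():
    scheme = ScoringScheme.protein()
    assert global_identity("MKVLA", "MKVLA", scheme) == 1.0
    # unrelated: the core may match a little, the overhangs dilute it
    assert global_identity("M" + "A" * 50, "M" + "W" * 50, scheme) < 0.3


def test_global_alignment_with_end_gaps_penalised():
    scheme = ScoringScheme.nucleotide(match=1, mismatch=-1, gap_open=2,
                                      gap_extend=1)
    score, pa, pb = global_alignment("ACGT", "ACGT", scheme)
    assert score == 4 and pa == pb == "ACGT"
    score, pa, pb = global_alignment("ACGT", "AGT", scheme)
    assert score == 0  # three matches minus one length-1 gap (2+1)
    assert pa == "ACGT" and pb == "A-GT"
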