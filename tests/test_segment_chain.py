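import random

import pytest

from tadscan.align_core import HSP
from tadscan.segment_chain import (ChainParams, merge_hsps,
                                   segment_query_coverage, write_bed)

from oracles import coverage_bitmap, interval_components


def make_hsp(s_start, s_end, subject="r1", query="q", q_start=0,
             q_end=None, bitscore=50.0, strand="+"):
    return HSP(query_id=query, subject_id=subject, q_start=q_start,
               q_end=q_end if q_end is not None else q_start + (s_end - s_start),
               s_start=s_start, s_end=s_end, subject_strand=strand,
               pct_identity=90.0, aln_length=s_end - s_start,
               bitscore=bitscore, evalue=1e-10)


def test_single_hsp_gives_identical_segment():
    (seg,) = merge_hsps([make_hsp(100, 400)], ChainParams(max_gap=50,
                                                          min_segment_score=0))
    assert (seg.start, seg.end) == (100, 400)
    assert seg.total_bitscore == 50.0


@pytest.mark.parametrize("max_gap,n_expected", [(100, 1), (50, 1), (30, 2)])
def test_gap_threshold_splits_segments(max_gap, n_expected):
    """Intervals [100,200) and [250,400): gap 50, joined iff max_gap >= 50."""
    hsps = [make_hsp(100, 200), make_hsp(250, 400)]
    segs = merge_hsps(hsps, ChainParams(max_gap=max_gap, min_segment_score=0))
    assert len(segs) == n_expected
    if n_expected == 1:
        assert (segs[0].start, segs[0].end) == (100, 400)


def test_empty_input_gives_empty_output():
    assert merge_hsps([], ChainParams()) == []


def test_score_floor_drops_weak_segments():
    hsps = [make_hsp(0, 100, bitscore=30.0), make_hsp(5000, 5100,
                                                      bitscore=300.0)]
    segs = merge_hsps(hsps, ChainParams(max_gap=100, min_segment_score=100))
    assert len(segs) == 1 and segs[0].start == 5000


def test_merge_matches_connected_components_oracle():
    """Random interval sets on up to 3 replicons: segments equal the
    connected components of the interval-proximity graph."""
    rng = random.Random(17)
    for _ in range(300):
        max_gap = rng.choice([0, 10, 100, 1000])
        hsps = []
        for idx in range(rng.randint(1, 60)):
            rep = f"r{rng.randint(1, 3)}"
            s = rng.randrange(0, 10000)
            e = s + rng.randint(1, 800)
            hsps.append(make_hsp(s, e, subject=rep, query=f"q{idx}"))
        segs = merge_hsps(hsps, ChainParams(max_gap=max_gap,
                                            min_segment_score=0))
        got = set()
        for seg in segs:
            got.add(frozenset((h.query_id for h in seg.members)))
        expected = set()
        for rep in {h.subject_id for h in hsps}:
            sub = [h for h in hsps if h.subject_id == rep]
            for comp in interval_components(
                    [(h.s_start, h.s_end) for h in sub], max_gap):
                expected.add(frozenset(sub[i].query_id for i in comp))
        assert got == expected


def test_consecutive_segments_are_separated_beyond_max_gap():
    rng = random.Random(23)
    for _ in range(50):
        hsps = [make_hsp(s, s + rng.randint(1, 300))
                for s in rng.sample(range(0, 20000), 40)]
        params = ChainParams(max_gap=500, min_segment_score=0)
        segs = merge_hsps(hsps, params)
        for a, b in zip(segs, segs[1:]):
            assert b.start - a.end > params.max_gap


def test_merge_is_idempotent_and_monotone_and_conserving():
    rng = random.Random(19)
    for _ in range(50):
        hsps = [make_hsp(s, s + rng.randint(10, 500), query=f"q{i}")
                for i, s in enumerate(rng.sample(range(0, 30000), 30))]
        p_small = ChainParams(max_gap=200, min_segment_score=0)
        p_big = ChainParams(max_gap=2000, min_segment_score=0)
        segs = merge_hsps(hsps, p_small)
        # conservation: every HSP lands in exactly one segment
        all_members = [h for s in segs for h in s.members]
        assert sorted(h.query_id for h in all_members) == \
            sorted(h.query_id for h in hsps)
        # idempotence: merging each segment's hull again changes nothing
        hulls = [make_hsp(s.start, s.end, query=f"hull{i}")
                 for i, s in enumerate(segs)]
        re_merged = merge_hsps(hulls, p_small)
        assert [(s.start, s.end) for s in re_merged] == \
            [(s.start, s.end) for s in segs]
        # monotonicity: larger max_gap never yields more segments
        assert len(merge_hsps(hsps, p_big)) <= len(segs)


def test_query_coverage_simple_cases():
    full = make_hsp(0, 100, q_start=0, q_end=100)
    (seg,) = merge_hsps([full], ChainParams(min_segment_score=0))
    assert segment_query_coverage(seg, {"q": 100}) == {"q": 1.0}

    halves = [make_hsp(0, 50, q_start=0, q_end=50),
              make_hsp(50, 100, q_start=50, q_end=100)]
    (seg,) = merge_hsps(halves, ChainParams(min_segment_score=0))
    assert segment_query_coverage(seg, {"q": 100})["q"] == 1.0

    overlapping = [make_hsp(0, 60, q_start=0, q_end=60),
                   make_hsp(40, 100, q_start=40, q_end=100)]
    (seg,) = merge_hsps(overlapping, ChainParams(min_segment_score=0))
    assert segment_query_coverage(seg, {"q": 120})["q"] == pytest.approx(
        100 / 120)


def test_query_coverage_matches_bitmap_oracle():
    rng = random.Random(29)
    for _ in range(100):
        qlen = rng.randint(50, 400)
        ivals = []
        for _ in range(rng.randint(1, 8)):
            s = rng.randrange(0, qlen - 1)
            e = rng.randrange(s + 1, qlen + 1)
            ivals.append((s, e))
        hsps = [make_hsp(1000 + 500 * i, 1000 + 500 * i + (e - s),
                         q_start=s, q_end=e) for i, (s, e) in enumerate(ivals)]
        (seg,) = merge_hsps(hsps, ChainParams(max_gap=100000,
                                              min_segment_score=0))
        got = segment_query_coverage(seg, {"q": qlen})["q"]
        assert got == pytest.approx(coverage_bitmap(ivals, qlen), abs=1e-9)


def test_missing_query_length_raises():
    (seg,) = merge_hsps([make_hsp(0, 10)], ChainParams(min_segment_score=0))
    with pytest.raises(KeyError):
        segment_query_coverage(seg, {})


def test_bed_export_is_zero_based(tmp_path):
    (seg,) = merge_hsps([make_hsp(100, 400)], ChainParams(min_segment_score=0))
    p = tmp_path / "segs.bed"
    write_bed([seg], p)
    chrom, start, end, name, score = p.read_text().split()
    assert (chrom, start, end) == ("r1", "100", "400")
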