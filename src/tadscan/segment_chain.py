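"""Chaining of nearby HSPs into contiguous genomic segments.

A candidate gene-cluster locus is the union hull of all HSPs on one
replicon whose subject intervals lie within ``max_gap`` nucleotides of one
another — the connected components of the interval-proximity graph. This
is proximity chaining, not collinear chaining: gene order and orientation
inside the locus are deliberately ignored at this stage, because Tad
clusters carry genes on either strand and cluster calling deals with
order separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import HSP


@dataclass(frozen=True)
class ChainParams:
    """max_gap: largest subject-coordinate gap bridged (overlap counts as
    gap 0); min_segment_score: summed-bitscore floor below which a segment
    is dropped; per_strand: chain each strand separately."""

    max_gap: int = 5000
    min_segment_score: float = 100.0
    per_strand: bool = False

    def __post_init__(self):
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class Segment:
    subject_id: str
    start: int
    end: int
    members: list[HSP] = field(default_factory=list)

    @property
    def total_bitscore(self) -> float:
        return sum(h.bitscore for h in self.members)

    @property
    def query_ids_covered(self) -> set[str]:
        return {h.query_id for h in self.members}

    def __post_init__(self):
        if self.members:
            assert self.start == min(h.s_start for h in self.members)
            assert self.end == max(h.s_end for h in self.members)
            assert all(h.subject_id == self.subject_id for h in self.members)


def merge_hsps(hsps: list[HSP], params: ChainParams | None = None) -> list[Segment]:
    """Merge HSPs whose subject intervals are within ``max_gap`` of each
    other into segments; drop segments under the score floor.

    Consecutive output segments on one replicon are separated by more than
    ``max_gap``; output is sorted by (subject_id, start).
    """
    params = params or ChainParams()
    groups: dict[tuple, list[HSP]] = {}
    for h in hsps:
        key = (h.subject_id, h.subject_strand) if params.per_strand \
            else (h.subject_id,)
        groups.setdefault(key, []).append(h)

    segments: list[Segment] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda h: (h.s_start, h.s_end))
        run: list[HSP] = []
        run_end = None
        for h in members:
            if run and h.s_start - run_end > params.max_gap:
                segments.append(_make_segment(run))
                run = []
                run_end = None
            run.append(h)
            run_end = h.s_end if run_end is None else max(run_end, h.s_end)
        if run:
            segments.append(_make_segment(run))

    segments = [s for s in segments
                if s.total_bitscore >= params.min_segment_score]
    segments.sort(key=lambda s: (s.subject_id, s.start))
    return segments


def _make_segment(members: list[HSP]) -> Segment:
    return Segment(
        subject_id=members[0].subject_id,
        start=min(h.s_start for h in members),
        end=max(h.s_end for h in members),
        members=list(members),
    )


def segment_query_coverage(seg: Segment, query_lengths: dict) -> dict:
    """Fraction of each member query covered by the union of its HSP
    query-intervals within this segment."""
    by_query: dict[str, list[tuple[int, int]]] = {}
    for h in seg.members:
        by_query.setdefault(h.query_id, []).append((h.q_start, h.q_end))
    out = {}
    for qid, ivals in by_query.items():
        if qid not in query_lengths:
            raise KeyError(f"no length for query {qid!r}")
        covered = 0
        last_end = -1
        for s, e in sorted(ivals):
            s = max(s, last_end)
            if e > s:
                covered += e - s
                last_end = e
            last_end = max(last_end, e)
        out[qid] = covered / query_lengths[qid]
    return out


def write_bed(segments: list[Segment], path) -> None:
    """Segments as BED (0-based half-open; score = total bitscore)."""
    with open(path, "w") as fh:
        for i, s in enumerate(segments, 1):
            fh.write(f"{s.subject_id}\t{s.start}\t{s.end}\t"
                     f"segment_{i}\t{s.total_bitscore:.1f}\n")


def write_evidence_tsv(segments: list[Segment], path) -> None:
    with open(path, "w") as fh:
        fh.write("segment\tsubject_id\tstart\tend\ttotal_bitscore\t"
                 "query_id\tq_start\tq_end\ts_start\ts_end\tstrand\t"
                 "pct_identity\tbitscore\tevalue\n")
        for i, s in enumerate(segments, 1):
            for h in sorted(s.members, key=lambda h: (h.s_start, h.query_id)):
                fh.write(f"segment_{i}\t{s.subject_id}\t{s.start}\t{s.end}\t"
                         f"{s.total_bitscore:.1f}\t{h.query_id}\t"
                         f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                         f"{h.subject_strand}\t{h.pct_identity:.1f}\t"
                         f"{h.bitscore:.1f}\t{h.evalue:.3g}\n")
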