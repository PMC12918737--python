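"""Local alignment primitives, seeded homology search and BLAST-tabular I/O.

The module provides an internal search backend (exact k-mer seeding plus
windowed Smith–Waterman extension) whose output is interchangeable with any
external tool that emits the 12-column BLAST outfmt-6 dialect: the rest of
the pipeline consumes only :class:`HSP` records.

Coordinates are 0-based half-open on the forward strand everywhere inside
the package; the tabular reader/writer converts to/from the 1-based
inclusive convention (minus-strand subject intervals encoded as
``sstart > send``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _dp

_NT_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ENCODE_TABLES: dict = {}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _blosum62():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat, dtype=np.int16)
    return alphabet, arr


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin–Altschul calibration.

    ``gap_open`` is the cost of opening a gap and ``gap_extend`` the cost
    per gap residue, so a gap of length L costs ``gap_open + L*gap_extend``
    (BLAST convention). Karlin parameters are fixed per mode rather than
    computed; downstream filters use bitscores, so calibration precision is
    non-critical.
    """

    mode: str  # "nucleotide" | "protein"
    match: int = 2
    mismatch: int = -3
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41
    word_size: int = 11

    def __post_init__(self):
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")

    @classmethod
    def nucleotide(cls, match=2, mismatch=-3, gap_open=5, gap_extend=2,
                   word_size=11) -> "ScoringScheme":
        return cls(mode="nucleotide", match=match, mismatch=mismatch,
                   gap_open=gap_open, gap_extend=gap_extend,
                   karlin_lambda=0.625, karlin_k=0.41, word_size=word_size)

    @classmethod
    def protein(cls, gap_open=11, gap_extend=1, word_size=4) -> "ScoringScheme":
        return cls(mode="protein", gap_open=gap_open, gap_extend=gap_extend,
                   matrix_name="BLOSUM62", karlin_lambda=0.267,
                   karlin_k=0.041, word_size=word_size)

    @property
    def alphabet(self) -> str:
        if self.mode == "nucleotide":
            return _NT_ALPHABET
        return _blosum62()[0]

    def substitution_matrix(self) -> np.ndarray:
        if self.mode == "nucleotide":
            n = len(_NT_ALPHABET)
            arr = np.full((n, n), self.mismatch, dtype=np.int16)
            for i in range(4):  # N (index 4) mismatches everything, itself too
                arr[i, i] = self.match
            return arr
        if self.matrix_name != "BLOSUM62":
            raise ValueError(f"unsupported matrix {self.matrix_name!r}")
        return _blosum62()[1]

    def _encode_table(self) -> np.ndarray:
        table = _ENCODE_TABLES.get(self.mode)
        if table is None:
            table = np.full(256, -1, dtype=np.int8)
            for i, c in enumerate(self.alphabet):
                table[ord(c)] = i
                table[ord(c.lower())] = i
            _ENCODE_TABLES[self.mode] = table
        return table

    def encode(self, seq: str) -> np.ndarray:
        raw = np.frombuffer(seq.encode("ascii", errors="replace"), np.uint8)
        out = self._encode_table()[raw]
        if (out < 0).any():
            bad = seq[int(np.flatnonzero(out < 0)[0])]
            raise ValueError(f"character {bad!r} not in {self.mode} alphabet")
        return out

    def bitscore(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: float, query_len: int, db_len: int) -> float:
        return self.karlin_k * query_len * db_len * math.exp(
            -self.karlin_lambda * raw_score)


@dataclass
class HSP:
    """One local alignment hit (high-scoring segment pair).

    All coordinates are 0-based half-open on the forward strand of both
    sequences; ``subject_strand == '-'`` means the query matches the
    reverse complement of the subject interval.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_strand: str = "+"
    pct_identity: float = 100.0
    aln_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    bitscore: float = 0.0
    evalue: float = 0.0

    def __post_init__(self):
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("HSP intervals must be non-empty half-open")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity out of [0, 100]")
        if self.subject_strand not in "+-":
            raise ValueError("subject_strand must be '+' or '-'")


@dataclass
class LocalAlignment:
    score: int
    aligned_a: str
    aligned_b: str
    hsp: HSP | None


def _path_stats(a: str, b: str, i0: int, j0: int, ops: np.ndarray):
    """Matches / mismatches / gap-opens and aligned strings along a path."""
    matches = mismatches = gap_opens = 0
    pa, pb = [], []
    i, j = i0, j0
    prev = -1
    for op in ops:
        if op == _dp.OP_DIAG:
            ca, cb = a[i], b[j]
            pa.append(ca)
            pb.append(cb)
            if ca == cb:
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
        elif op == _dp.OP_UP:
            pa.append(a[i])
            pb.append("-")
            if prev != _dp.OP_UP:
                gap_opens += 1
            i += 1
        else:
            pa.append("-")
            pb.append(b[j])
            if prev != _dp.OP_LEFT:
                gap_opens += 1
            j += 1
        prev = op
    return matches, mismatches, gap_opens, "".join(pa), "".join(pb)


def _align(a: str, b: str, scheme: ScoringScheme, mode: int):
    ea, eb = scheme.encode(a), scheme.encode(b)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("cannot align empty sequences")
    sub = scheme.substitution_matrix()
    score, i0, i1, j0, j1, ops, n_ops = _dp.align_kernel(
        ea, eb, sub, scheme.gap_open, scheme.gap_extend, mode)
    return int(score), i0, i1, j0, j1, ops[:n_ops]


def smith_waterman(a: str, b: str, scheme: ScoringScheme,
                   query_id: str = "query",
                   subject_id: str = "subject") -> LocalAlignment:
    """Optimal affine-gap local alignment with deterministic traceback.

    Tie-break order at equal score: diagonal > up > left. A pair with no
    positively-scoring common substring yields score 0 and no HSP.
    """
    score, i0, i1, j0, j1, ops = _align(a, b, scheme, _dp.LOCAL)
    if score <= 0 or len(ops) == 0:
        return LocalAlignment(0, "", "", None)
    matches, mism, gaps, pa, pb = _path_stats(a, b, i0, j0, ops)
    cols = len(ops)
    hsp = HSP(
        query_id=query_id, subject_id=subject_id,
        q_start=i0, q_end=i1, s_start=j0, s_end=j1,
        subject_strand="+",
        pct_identity=100.0 * matches / cols,
        aln_length=cols, mismatches=mism, gap_opens=gaps,
        bitscore=scheme.bitscore(score),
        evalue=scheme.evalue(score, len(a), len(b)),
    )
    return LocalAlignment(score, pa, pb, hsp)


def global_alignment(a: str, b: str, scheme: ScoringScheme,
                     end_gap_free: bool = False):
    """Global (or end-gap-free semiglobal) alignment.

    Returns ``(score, aligned_a, aligned_b)``. In end-gap-free mode the
    reported alignment covers only the aligned core: unaligned terminal
    overhangs are excluded from the returned strings.
    """
    mode = _dp.SEMIGLOBAL if end_gap_free else _dp.GLOBAL
    score, i0, i1, j0, j1, ops = _align(a, b, scheme, mode)
    _, _, _, pa, pb = _path_stats(a, b, i0, j0, ops)
    return score, pa, pb


def global_identity(a: str, b: str, scheme: ScoringScheme,
                    end_gap_free: bool = True) -> float:
    """Fraction identity of a global alignment over its full extent.

    With ``end_gap_free`` the alignment path is scored semiglobally
    (terminal gaps free), but unaligned terminal overhangs still count as
    alignment columns, so short high-identity cores of unrelated
    sequences do not inflate the identity.
    """
    mode = _dp.SEMIGLOBAL if end_gap_free else _dp.GLOBAL
    score, i0, i1, j0, j1, ops = _align(a, b, scheme, mode)
    if len(ops) == 0:
        return 0.0
    matches, _, _, _, _ = _path_stats(a, b, i0, j0, ops)
    overhang = max(i0, j0) + max(len(a) - i1, len(b) - j1)
    return matches / (len(ops) + overhang)


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Matches / alignment columns, as a fraction in [0, 1]."""
    if not aligned_a:
        return 0.0
    matches = sum(1 for x, y in zip(aligned_a, aligned_b)
                  if x == y and x != "-")
    return matches / len(aligned_a)


# ---------------------------------------------------------------------------
# seeded search
# ---------------------------------------------------------------------------

def _as_subject_pairs(subject) -> list[tuple[str, str]]:
    if hasattr(subject, "replicons"):  # a Genome
        return [(r.id, r.sequence) for r in subject.replicons]
    if isinstance(subject, Mapping):
        return list(subject.items())
    return list(subject)


def _as_query_pairs(queries) -> list[tuple[str, str]]:
    if isinstance(queries, Mapping):
        return list(queries.items())
    return list(queries)


def _kmer_index(seq: str, k: int) -> dict:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def _seed_groups(seeds: list[tuple[int, int]], qlen: int):
    """Group (qpos, spos) seed hits into candidate alignment loci: seeds
    whose subject positions lie within one query length of each other."""
    seeds = sorted(set(seeds), key=lambda t: (t[1], t[0]))
    groups: list[list[tuple[int, int]]] = []
    for qp, sp in seeds:
        if groups and sp - groups[-1][-1][1] <= qlen:
            groups[-1].append((qp, sp))
        else:
            groups.append([(qp, sp)])
    return groups


_XDROP = 30  # raw-score drop terminating ungapped extension


def seeded_search(queries, subject, scheme: ScoringScheme,
                  k: int | None = None,
                  min_bitscore: float = 0.0,
                  max_evalue: float = math.inf,
                  gap_trigger_bits: float | None = None) -> list[HSP]:
    """Exact k-mer seeding, ungapped x-drop extension, then Smith–Waterman
    extension in a window around the ungapped extent.

    Nucleotide searches scan both strands of each query against the
    forward subject; protein searches are single-strand. Seed groups whose
    best ungapped extension stays below ``gap_trigger_bits`` (default:
    60% of ``min_bitscore``, i.e. no pruning when no score floor is
    requested) are discarded before the gapped stage. The reported score
    never exceeds the full Smith–Waterman optimum for the pair, and with
    ``k=1`` and no thresholds it attains it on small instances.
    """
    if k is None:
        k = scheme.word_size
    min_k = 4 if scheme.mode == "nucleotide" else 3
    if k < 1 or (k < min_k and k != 1):
        raise ValueError(f"seed length {k} too short for {scheme.mode} mode")
    if gap_trigger_bits is None:
        gap_trigger_bits = 0.6 * min_bitscore

    query_pairs = _as_query_pairs(queries)
    subject_pairs = _as_subject_pairs(subject)
    if not query_pairs:
        return []
    db_len = sum(len(s) for _, s in subject_pairs)
    sub = scheme.substitution_matrix()

    hsps: list[HSP] = []
    for sid, sseq in subject_pairs:
        sseq = sseq.upper()
        slen = len(sseq)
        if slen < k:
            continue
        index = _kmer_index(sseq, k)
        es = scheme.encode(sseq)
        for qid, qseq in query_pairs:
            qseq = qseq.upper()
            qlen = len(qseq)
            if qlen < k:
                continue
            strands = ("+", "-") if scheme.mode == "nucleotide" else ("+",)
            candidates: list[HSP] = []
            for strand in strands:
                oriented = qseq if strand == "+" else revcomp(qseq)
                seeds = []
                for i in range(qlen - k + 1):
                    for sp in index.get(oriented[i:i + k], ()):
                        seeds.append((i, sp))
                if not seeds:
                    continue
                eq = scheme.encode(oriented)
                for group in _seed_groups(seeds, qlen):
                    # ungapped x-drop pass over the group's seeds
                    best_raw = -(1 << 30)
                    ext_lo, ext_hi = slen, 0
                    covered: dict[int, int] = {}
                    for qp, sp in group:
                        diag = sp - qp
                        if covered.get(diag, -1) >= sp + k:
                            continue
                        raw, q0, q1, s0, s1 = _dp.ungapped_extend(
                            eq, es, qp, sp, k, sub, _XDROP)
                        covered[diag] = s1
                        best_raw = max(best_raw, int(raw))
                        ext_lo = min(ext_lo, int(s0))
                        ext_hi = max(ext_hi, int(s1))
                    if scheme.bitscore(best_raw) < gap_trigger_bits:
                        continue
                    pad = max(128, k)
                    lo = max(0, ext_lo - pad)
                    hi = min(slen, ext_hi + pad)
                    score, i0, i1, j0, j1, ops, n_ops = _dp.align_kernel(
                        eq, es[lo:hi], sub, scheme.gap_open,
                        scheme.gap_extend, _dp.LOCAL)
                    score = int(score)
                    if score <= 0 or n_ops == 0:
                        continue
                    ops = ops[:n_ops]
                    matches, mism, gaps, _, _ = _path_stats(
                        oriented, sseq[lo:hi], i0, j0, ops)
                    cols = int(n_ops)
                    if strand == "+":
                        qs, qe = i0, i1
                    else:
                        qs, qe = qlen - i1, qlen - i0
                    candidates.append(HSP(
                        query_id=qid, subject_id=sid,
                        q_start=qs, q_end=qe,
                        s_start=lo + j0, s_end=lo + j1,
                        subject_strand=strand,
                        pct_identity=100.0 * matches / cols,
                        aln_length=cols, mismatches=mism, gap_opens=gaps,
                        bitscore=scheme.bitscore(score),
                        evalue=scheme.evalue(score, qlen, db_len),
                    ))
            hsps.extend(_dedupe(candidates))

    hsps = [h for h in hsps
            if h.bitscore >= min_bitscore and h.evalue <= max_evalue]
    hsps.sort(key=lambda h: (h.subject_id, h.s_start, h.query_id, h.q_start))
    return hsps


def _dedupe(candidates: list[HSP]) -> list[HSP]:
    """Drop HSPs mostly contained (>50% subject overlap) in a better one."""
    kept: list[HSP] = []
    for h in sorted(candidates, key=lambda x: (-x.bitscore, x.s_start)):
        redundant = False
        for g in kept:
            if g.subject_strand != h.subject_strand:
                continue
            ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start)
            if ov > 0.5 * (h.s_end - h.s_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# BLAST outfmt-6 dialect
# ---------------------------------------------------------------------------

_TAB_COLUMNS = ("qseqid sseqid pident length mismatch gapopen "
                "qstart qend sstart send evalue bitscore").split()


def write_tabular(hsps: Iterable[HSP], path) -> None:
    """Write HSPs as 12-column BLAST outfmt-6 (1-based inclusive coords).

    Round trip is lossless except for the convention's one blind spot: a
    single-base minus-strand subject interval cannot be expressed as
    ``sstart > send`` and reads back as plus strand (no real HSP is
    shorter than the seed length, so this never arises in practice).
    """
    with open(path, "w") as fh:
        for h in hsps:
            if h.subject_strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fh.write("\t".join([
                h.query_id, h.subject_id,
                f"{h.pct_identity:.3f}", str(h.aln_length),
                str(h.mismatches), str(h.gap_opens),
                str(h.q_start + 1), str(h.q_end),
                str(sstart), str(send),
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            ]) + "\n")


def read_tabular(path) -> list[HSP]:
    """Read 12-column BLAST outfmt-6; ``sstart > send`` marks minus strand."""
    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, "
                    f"got {len(parts)}")
            (qid, sid, pident, length, mism, gapo,
             qstart, qend, sstart, send, evalue, bits) = parts
            sstart_i, send_i = int(sstart), int(send)
            if sstart_i <= send_i:
                strand, s0, s1 = "+", sstart_i - 1, send_i
            else:
                strand, s0, s1 = "-", send_i - 1, sstart_i
            hsps.append(HSP(
                query_id=qid, subject_id=sid,
                q_start=int(qstart) - 1, q_end=int(qend),
                s_start=s0, s_end=s1, subject_strand=strand,
                pct_identity=float(pident), aln_length=int(length),
                mismatches=int(mism), gap_opens=int(gapo),
                bitscore=float(bits), evalue=float(evalue),
            ))
    return hsps
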