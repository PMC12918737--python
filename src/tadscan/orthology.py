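"""Reciprocal-best-hit (RBH) functional assignment of proteins.

Genome proteins are assigned to reference Tad gene roles by bidirectional
all-vs-all local protein alignment: a pair is reciprocal iff each member
is the other's unique top hit by bitscore, both directions passing the
identity/E-value/coverage thresholds. Gene roles encoded in more than one
reference cluster (paralogs) are displayed with the cluster number as a
suffix, e.g. ``tadA2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .align_core import ScoringScheme, smith_waterman

_REF_ID = re.compile(r"^c(\d+)\|(.+)$")


def parse_ref_id(ref_id: str) -> tuple[str, int | None]:
    """Split a reference protein id 'c<cluster>|<role>' into (role, cluster)."""
    m = _REF_ID.match(ref_id)
    if m:
        return m.group(2), int(m.group(1))
    return ref_id, None


@dataclass
class Assignment:
    locus_tag: str
    reference_gene: str
    reference_cluster: int | None
    pct_identity: float
    bitscore: float
    evalue: float
    reciprocal: bool
    ambiguous: bool = False
    display_name: str = ""


def mutual_best_indices(bitscore: np.ndarray,
                        identity: np.ndarray | None = None,
                        valid: np.ndarray | None = None):
    """Mutual-argmax pairs of a score matrix.

    Rows are proteome A, columns proteome B. Ties on bitscore are broken
    by higher identity, then by the smaller column/row index (callers sort
    ids lexicographically so index order is lexicographic order). A top
    hit tied even after the identity tie-break is ambiguous and can never
    be reciprocal.

    Returns a list of (i, j, reciprocal, ambiguous) — one entry per row
    with at least one valid hit, j being the row's (tie-broken) top hit.
    """
    bitscore = np.asarray(bitscore, dtype=float)
    n_a, n_b = bitscore.shape
    if identity is None:
        identity = np.zeros_like(bitscore)
    if valid is None:
        valid = np.ones_like(bitscore, dtype=bool)

    def top_of(vec_bits, vec_ident, vec_valid):
        idx = np.flatnonzero(vec_valid)
        if idx.size == 0:
            return None, False
        keys = sorted(idx, key=lambda k: (-vec_bits[k], -vec_ident[k], k))
        best = keys[0]
        ambiguous = (len(keys) > 1 and
                     vec_bits[keys[1]] == vec_bits[best] and
                     vec_ident[keys[1]] == vec_ident[best])
        return int(best), ambiguous

    top_a = [top_of(bitscore[i], identity[i], valid[i]) for i in range(n_a)]
    top_b = [top_of(bitscore[:, j], identity[:, j], valid[:, j])
             for j in range(n_b)]

    out = []
    for i, (j, amb_a) in enumerate(top_a):
        if j is None:
            continue
        j_top_i, amb_b = top_b[j]
        reciprocal = (not amb_a and not amb_b and j_top_i == i)
        out.append((i, j, reciprocal, amb_a))
    return out


def reciprocal_best_hits(proteome_a: Sequence[tuple[str, str]],
                         proteome_b: Sequence[tuple[str, str]],
                         scheme: ScoringScheme | None = None,
                         min_pct_id: float = 30.0,
                         max_evalue: float = 1e-5,
                         min_coverage: float = 0.5,
                         ref_parser: Callable | None = parse_ref_id,
                         seed_prefilter: int | None = 5,
                         ) -> list[Assignment]:
    """Bidirectional best-hit assignment of proteome A against proteome B.

    ``min_coverage`` is measured on the shorter protein of each pair.
    Non-reciprocal top hits are retained with ``reciprocal=False``.
    ``seed_prefilter`` skips the alignment of pairs sharing no exact
    k-mer of that length — a cheap negative filter that cannot discard
    pairs of biologically meaningful similarity at the default
    thresholds; pass None to align every pair.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scheme = scheme or ScoringScheme.protein()

    a_items = sorted(proteome_a, key=lambda kv: kv[0])
    b_items = sorted(proteome_b, key=lambda kv: kv[0])
    n_a, n_b = len(a_items), len(b_items)
    bits = np.zeros((n_a, n_b))
    ident = np.zeros((n_a, n_b))
    ev = np.full((n_a, n_b), np.inf)
    valid = np.zeros((n_a, n_b), dtype=bool)

    def kmers(seq, k):
        return {seq[i:i + k] for i in range(len(seq) - k + 1)}

    if seed_prefilter:
        a_kmers = [kmers(s, seed_prefilter) for _, s in a_items]
        b_kmers = [kmers(s, seed_prefilter) for _, s in b_items]

    for i, (tag_a, seq_a) in enumerate(a_items):
        for j, (tag_b, seq_b) in enumerate(b_items):
            if seed_prefilter and a_kmers[i].isdisjoint(b_kmers[j]):
                continue
            aln = smith_waterman(seq_a, seq_b, scheme,
                                 query_id=tag_a, subject_id=tag_b)
            if aln.hsp is None:
                continue
            h = aln.hsp
            shorter = min(len(seq_a), len(seq_b))
            span = min(h.q_end - h.q_start, h.s_end - h.s_start)
            coverage = span / shorter
            bits[i, j] = h.bitscore
            ident[i, j] = h.pct_identity
            ev[i, j] = h.evalue
            valid[i, j] = (h.pct_identity >= min_pct_id
                           and h.evalue <= max_evalue
                           and coverage >= min_coverage)

    assignments = []
    for i, j, reciprocal, ambiguous in mutual_best_indices(bits, ident, valid):
        tag_a = a_items[i][0]
        tag_b = b_items[j][0]
        role, cluster = ref_parser(tag_b) if ref_parser else (tag_b, None)
        assignments.append(Assignment(
            locus_tag=tag_a, reference_gene=role, reference_cluster=cluster,
            pct_identity=float(ident[i, j]), bitscore=float(bits[i, j]),
            evalue=float(ev[i, j]), reciprocal=reciprocal,
            ambiguous=ambiguous,
        ))
    return assignments


def name_with_suffix(assignments: list[Assignment],
                     role_clusters: Mapping[str, set] | None = None,
                     ) -> list[Assignment]:
    """Set display_name, appending the cluster number for paralogous roles.

    ``role_clusters`` maps each reference role to the set of clusters that
    encode it; when omitted it is derived from the assignments themselves.
    Renaming is order-independent.
    """
    if role_clusters is None:
        role_clusters = {}
        for a in assignments:
            if a.reference_cluster is not None:
                role_clusters.setdefault(a.reference_gene, set()).add(
                    a.reference_cluster)
    for a in assignments:
        multi = len(role_clusters.get(a.reference_gene, set())) > 1
        if multi and a.reference_cluster is not None:
            a.display_name = f"{a.reference_gene}{a.reference_cluster}"
        else:
            a.display_name = a.reference_gene
    return assignments


def write_assignments_tsv(assignments: list[Assignment], genome_id: str,
                          path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tlocus_tag\tdisplay_name\treference_cluster\t"
                 "pct_identity\tbitscore\tevalue\treciprocal\n")
        for a in sorted(assignments, key=lambda a: a.locus_tag):
            cluster = "" if a.reference_cluster is None \
                else str(a.reference_cluster)
            fh.write(f"{genome_id}\t{a.locus_tag}\t"
                     f"{a.display_name or a.reference_gene}\t{cluster}\t"
                     f"{a.pct_identity:.1f}\t{a.bitscore:.1f}\t"
                     f"{a.evalue:.3g}\t{str(a.reciprocal).lower()}\n")
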