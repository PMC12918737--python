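"""Per-genome classification of reference Tad clusters as complete,
partial or absent, plus the genus-wide presence–absence matrix.

The caller distinguishes *canonical* presence — all of a cluster's
required gene roles found at one chained locus in conserved order — from
*fallback* presence, where a role (the pseudopilins TadE/TadF/TadG) is
detected anywhere in the proteome by reciprocal best hit regardless of
genomic arrangement. Scattered genes therefore never make a cluster
canonical, while a cluster split across two contigs of a fragmented
assembly is still recognised by joining edge-touching segments from
different contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align_core import ScoringScheme, seeded_search
from .genome_io import Genome, extract_proteome
from .orthology import name_with_suffix, reciprocal_best_hits
from .references import PSEUDOPILIN_ROLES, ReferenceSet
from .segment_chain import ChainParams, Segment, merge_hsps


@dataclass
class CallParams:
    """Thresholds for the cluster-locus scan.

    Role-level thresholds apply to nucleotide hits inside an assigned
    segment; fallback thresholds apply to protein reciprocal best hits.
    """

    chain: ChainParams = field(default_factory=ChainParams)
    word_size: int = 11
    min_hsp_bitscore: float = 50.0
    max_hsp_evalue: float = 1e-6
    min_role_identity: float = 60.0   # percent, nucleotide level
    min_role_coverage: float = 0.5    # fraction of the reference gene
    min_partial_roles: int = 2
    order_tolerance: int = 1          # rank displacement allowed for canonical
    edge_tolerance: int = 200         # nt from a contig edge = truncated
    fallback_min_pct_id: float = 30.0
    fallback_max_evalue: float = 1e-5
    fallback_min_coverage: float = 0.5
    complete_requires: dict | None = None  # cluster_id -> role set override

    def required_roles(self, refs: ReferenceSet, cluster_id: int) -> set:
        if self.complete_requires and cluster_id in self.complete_requires:
            return set(self.complete_requires[cluster_id])
        return refs.clusters[cluster_id].required_roles()


@dataclass
class ClusterCall:
    genome_id: str
    cluster_id: int
    status: str                      # complete | partial | absent
    segment: Segment | None = None
    roles_found: set = field(default_factory=set)
    fragmented_assembly: bool = False
    n_segments: int = 0
    assignment_tied: bool = False

    def __post_init__(self):
        if self.status not in ("complete", "partial", "absent"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "absent":
            self.segment = None


def _segment_cluster_scores(segment: Segment) -> dict[int, float]:
    from .orthology import parse_ref_id

    scores: dict[int, float] = {}
    for h in segment.members:
        _, cid = parse_ref_id(h.query_id)
        if cid is not None:
            scores[cid] = scores.get(cid, 0.0) + h.bitscore
    return scores


def _roles_in_segments(segments, cluster_id, refs, params,
                       query_lengths) -> tuple[set, dict]:
    """Roles passing identity+coverage within the given segments; also
    the mean subject position of each found role (for order checks)."""
    from .orthology import parse_ref_id

    found: set[str] = set()
    positions: dict[str, float] = {}
    roles = set(refs.clusters[cluster_id].roles)
    for role in roles:
        qid = f"c{cluster_id}|{role}"
        ivals, best_ident, pos_acc, span_acc = [], 0.0, 0.0, 0
        for seg in segments:
            for h in seg.members:
                if h.query_id != qid:
                    continue
                ivals.append((h.q_start, h.q_end))
                best_ident = max(best_ident, h.pct_identity)
                mid = (h.s_start + h.s_end) / 2
                span = h.s_end - h.s_start
                pos_acc += mid * span
                span_acc += span
        if not ivals:
            continue
        covered, last = 0, -1
        for s, e in sorted(ivals):
            s = max(s, last)
            if e > s:
                covered += e - s
                last = e
            last = max(last, e)
        coverage = covered / query_lengths[qid]
        if coverage >= params.min_role_coverage \
                and best_ident >= params.min_role_identity:
            found.add(role)
            positions[role] = pos_acc / span_acc
    return found, positions


def _order_conserved(roles_found, positions, reference_order,
                     tolerance) -> bool:
    """Observed role order matches the reference order (or its reverse)
    within the allowed rank displacement."""
    present = [r for r in reference_order if r in roles_found]
    if len(present) <= 2:
        return True
    observed = sorted(present, key=lambda r: positions[r])
    ref_rank = {r: i for i, r in enumerate(present)}

    def max_displacement(seq):
        return max(abs(i - ref_rank[r]) for i, r in enumerate(seq))

    return (max_displacement(observed) <= tolerance
            or max_displacement(observed[::-1]) <= tolerance)


def _near_edge(seg: Segment, genome: Genome, tol: int) -> bool:
    rep = genome.replicon(seg.subject_id)
    return seg.start <= tol or len(rep) - seg.end <= tol


def scan_genome(genome: Genome, refs: ReferenceSet,
                params: CallParams | None = None,
                hsps=None) -> list[ClusterCall]:
    """Nucleotide search, chaining and completeness calls for one genome.

    Segments are assigned exclusively to the reference cluster with the
    greatest summed bitscore (ties to the lower cluster id, flagged);
    clusters 1 and 2 are close homologs, so exclusive assignment keeps a
    single locus from being counted twice. Precomputed HSPs (e.g. read
    from BLAST tabular output of an external search tool) may be passed
    via ``hsps`` to replace the internal seeded search.
    """
    params = params or CallParams()
    if not refs.clusters:
        raise ValueError("no reference clusters loaded")
    scheme = ScoringScheme.nucleotide(word_size=params.word_size)
    queries = refs.nucleotide_queries()
    query_lengths = {qid: len(seq) for qid, seq in queries}

    if hsps is None:
        hsps = seeded_search(queries, genome, scheme,
                             min_bitscore=params.min_hsp_bitscore,
                             max_evalue=params.max_hsp_evalue)
    segments = merge_hsps(hsps, params.chain)

    assigned: dict[int, list[Segment]] = {cid: [] for cid in refs.clusters}
    tied: set[int] = set()
    for seg in segments:
        scores = _segment_cluster_scores(seg)
        if not scores:
            continue
        best = max(scores.values())
        winners = sorted(cid for cid, s in scores.items() if s == best)
        assigned[winners[0]].append(seg)
        if len(winners) > 1:
            tied.add(winners[0])

    fragmentable = genome.assembly_level in ("contig", "scaffold")
    calls = []
    for cid in sorted(refs.clusters):
        segs = assigned[cid]
        required = params.required_roles(refs, cid)
        ref_order = refs.clusters[cid].roles

        # candidate loci: each segment alone; plus, on fragmented
        # assemblies, the union of edge-touching segments from different
        # contigs (a cluster truncated at contig boundaries)
        units: list[list[Segment]] = [[s] for s in segs]
        if fragmentable:
            edge_segs = [s for s in segs
                         if _near_edge(s, genome, params.edge_tolerance)]
            if len({s.subject_id for s in edge_segs}) > 1:
                units.append(edge_segs)

        best_unit: list[Segment] = []
        best_roles: set = set()
        best_pos: dict = {}
        for unit in units:
            roles, positions = _roles_in_segments(
                unit, cid, refs, params, query_lengths)
            if (len(roles), sum(s.total_bitscore for s in unit)) > \
               (len(best_roles), sum(s.total_bitscore for s in best_unit)):
                best_unit, best_roles, best_pos = unit, roles, positions

        fragmented = (len(best_unit) > 1
                      or (fragmentable and any(
                          _near_edge(s, genome, params.edge_tolerance)
                          for s in best_unit)))

        if best_roles >= required and len(best_unit) == 1 \
                and not _order_conserved(best_roles, best_pos, ref_order,
                                         params.order_tolerance):
            status = "partial"
        elif best_roles >= required:
            status = "complete"
        elif len(best_roles) >= params.min_partial_roles:
            status = "partial"
        else:
            status = "absent"

        rep_segment = None
        if status != "absent" and best_unit:
            rep_segment = max(best_unit, key=lambda s: s.total_bitscore)
        calls.append(ClusterCall(
            genome_id=genome.id, cluster_id=cid, status=status,
            segment=rep_segment, roles_found=best_roles,
            fragmented_assembly=bool(fragmented and status != "absent"),
            n_segments=len(segs), assignment_tied=cid in tied,
        ))
    return calls


def protein_fallback(genome: Genome, refs: ReferenceSet,
                     params: CallParams | None = None,
                     roles=PSEUDOPILIN_ROLES) -> dict[str, bool]:
    """Presence of pseudopilin proteins anywhere in the genome.

    A role is present iff some genome protein is a reciprocal best hit of
    that reference role at the fallback thresholds, regardless of segment
    membership. Genomes without annotated CDS (plain FASTA input) fall
    back to a nucleotide search of the pseudopilin genes.
    """
    params = params or CallParams()
    presence = {role: False for role in roles}
    proteome = extract_proteome(genome)
    if not proteome:
        queries = [(qid, seq) for qid, seq in refs.nucleotide_queries()
                   if any(qid.endswith(f"|{r}") for r in roles)]
        if not queries:
            return presence
        scheme = ScoringScheme.nucleotide(word_size=params.word_size)
        hits = seeded_search(queries, genome, scheme,
                             min_bitscore=params.min_hsp_bitscore,
                             max_evalue=params.max_hsp_evalue)
        for h in hits:
            role = h.query_id.split("|", 1)[1]
            coverage = (h.q_end - h.q_start) / len(dict(queries)[h.query_id])
            if h.pct_identity >= params.min_role_identity \
                    and coverage >= params.min_role_coverage:
                presence[role] = True
        return presence
    refs_prot = refs.protein_refs()
    assignments = reciprocal_best_hits(
        proteome, refs_prot,
        min_pct_id=params.fallback_min_pct_id,
        max_evalue=params.fallback_max_evalue,
        min_coverage=params.fallback_min_coverage)
    name_with_suffix(assignments, refs.role_clusters())
    for a in assignments:
        if a.reciprocal and a.reference_gene in presence:
            presence[a.reference_gene] = True
    return presence


FALLBACK_COLUMNS = {"tadE": "TadE", "tadF": "TadF", "tadG": "TadG"}


@dataclass
class PresenceMatrix:
    """Genome × cluster status matrix plus pseudopilin fallback columns."""

    table: pd.DataFrame

    @property
    def cluster_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("cluster_")]

    @property
    def fallback_columns(self) -> list[str]:
        return [c for c in self.table.columns if not c.startswith("cluster_")]

    def reorder(self, row_order: list[str]) -> "PresenceMatrix":
        missing = [r for r in self.table.index if r not in row_order]
        order = [r for r in row_order if r in self.table.index] \
            + sorted(missing)
        return PresenceMatrix(self.table.loc[order])

    def summary(self) -> dict:
        """Per-cluster percentages over the scanned genomes."""
        n = len(self.table)
        out: dict = {"n_genomes": n, "clusters": {}, "fallback": {}}
        if n == 0:
            return out
        for col in self.cluster_columns:
            counts = self.table[col].value_counts()
            complete = int(counts.get("complete", 0))
            partial = int(counts.get("partial", 0))
            absent = int(counts.get("absent", 0))
            out["clusters"][col] = {
                "pct_complete": 100.0 * complete / n,
                "pct_partial": 100.0 * partial / n,
                "pct_absent": 100.0 * absent / n,
                "pct_fully_or_partially": 100.0 * (complete + partial) / n,
            }
        for col in self.fallback_columns:
            present = int((self.table[col] == "present").sum())
            out["fallback"][col] = {"pct_present": 100.0 * present / n}
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="genome_id")

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"matrix": self.table.to_dict(orient="index"),
                       "summary": self.summary()},
                      fh, indent=1, sort_keys=True)


def build_matrix(calls_by_genome: dict,
                 fallback_by_genome: dict | None = None) -> PresenceMatrix:
    """Assemble the presence–absence matrix from per-genome calls.

    ``calls_by_genome`` maps genome id to its list of ClusterCalls;
    ``fallback_by_genome`` maps genome id to the pseudopilin presence
    dict. Every genome gets exactly one cell per cluster and per fallback
    column.
    """
    if not calls_by_genome:
        raise ValueError("no genomes scanned")
    fallback_by_genome = fallback_by_genome or {}
    cluster_ids = sorted({c.cluster_id for calls in calls_by_genome.values()
                          for c in calls})
    rows = {}
    for gid in sorted(calls_by_genome):
        row = {f"cluster_{cid}": "absent" for cid in cluster_ids}
        for call in calls_by_genome[gid]:
            row[f"cluster_{call.cluster_id}"] = call.status
        fb = fallback_by_genome.get(gid, {})
        for role, col in FALLBACK_COLUMNS.items():
            row[col] = "present" if fb.get(role) else "absent"
        rows[gid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    cols = [f"cluster_{cid}" for cid in cluster_ids] \
        + list(FALLBACK_COLUMNS.values())
    return PresenceMatrix(table[cols])
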