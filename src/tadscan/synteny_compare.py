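"""Pairwise gene-cluster comparison: identity links and colinearity.

Two annotated clusters are compared the way cluster-comparison tools such
as clinker do: every protein of cluster A is globally aligned against
every protein of cluster B, mutual best matches above an identity
threshold become links (each gene in at most one link), and a
colinearity score measures how well the linked genes preserve order and
orientation — the length of the longest orientation-consistent common
subsequence of linked gene orders divided by the number of links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import ScoringScheme, global_identity
from .orthology import mutual_best_indices


@dataclass
class ClusterView:
    """An ordered, stranded, translated gene cluster."""

    id: str
    genes: list  # of (name, strand, protein sequence)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"cluster {self.id!r} has no genes")
        for name, strand, seq in self.genes:
            if strand not in "+-":
                raise ValueError(f"{self.id}/{name}: bad strand {strand!r}")
            if not seq:
                raise ValueError(f"{self.id}/{name}: empty protein")

    @classmethod
    def from_reference(cls, refs, cluster_id: int) -> "ClusterView":
        from .references import ROLE_STRAND

        c = refs.clusters[cluster_id]
        return cls(id=f"cluster_{cluster_id}",
                   genes=[(r, ROLE_STRAND.get(r, "+"), c.proteins[r])
                          for r in c.roles])

    def reversed_view(self) -> "ClusterView":
        flipped = [(n, "+" if s == "-" else "-", p)
                   for n, s, p in reversed(self.genes)]
        return ClusterView(id=f"{self.id}_rev", genes=flipped)


@dataclass
class LinkSet:
    cluster_a: str
    cluster_b: str
    links: list  # of (index_in_a, index_in_b, pct_identity)
    link_fraction: float
    colinearity: float
    names_a: list = field(default_factory=list)
    names_b: list = field(default_factory=list)


def read_cluster_fasta(path, cluster_id: str | None = None) -> ClusterView:
    """Protein FASTA in genomic order; an optional '+'/'-' token in the
    description gives the strand (default '+')."""
    from pathlib import Path

    from Bio import SeqIO

    path = Path(path)
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()[1:]
        strand = "-" if "-" in tokens else "+"
        genes.append((rec.id, strand, str(rec.seq)))
    return ClusterView(id=cluster_id or path.stem, genes=genes)


def _longest_ordered_chain(values: list[int], decreasing: bool) -> int:
    """Longest strictly monotone subsequence (clusters are small: O(n^2))."""
    if not values:
        return 0
    if decreasing:
        values = [-v for v in values]
    best = [1] * len(values)
    for i in range(len(values)):
        for j in range(i):
            if values[j] < values[i]:
                best[i] = max(best[i], best[j] + 1)
    return max(best)


def link_clusters(a: ClusterView, b: ClusterView,
                  min_identity: float = 30.0,
                  scheme: ScoringScheme | None = None) -> LinkSet:
    """Mutual-best identity links between two clusters plus scores.

    Identity is matches over the full extent of an end-gap-free global
    alignment (unaligned terminal overhangs count as columns).
    ``link_fraction`` is 2·|links|/(|A|+|B|); ``colinearity`` is the
    longest orientation-consistent chain of links (same relative
    orientation and increasing order, or opposite orientation and
    decreasing order) divided by |links|, and 0 when there are no links.
    """
    import numpy as np

    scheme = scheme or ScoringScheme.protein()
    n_a, n_b = len(a.genes), len(b.genes)
    ident = np.zeros((n_a, n_b))
    for i, (_, _, seq_a) in enumerate(a.genes):
        for j, (_, _, seq_b) in enumerate(b.genes):
            ident[i, j] = 100.0 * global_identity(seq_a, seq_b, scheme)

    links = []
    for i, j, reciprocal, _ in mutual_best_indices(ident):
        if reciprocal and ident[i, j] >= min_identity:
            links.append((i, j, float(ident[i, j])))
    links.sort()

    link_fraction = 2.0 * len(links) / (n_a + n_b)
    if not links:
        colinearity = 0.0
    else:
        same = [j for i, j, _ in links if a.genes[i][1] == b.genes[j][1]]
        opposite = [j for i, j, _ in links if a.genes[i][1] != b.genes[j][1]]
        chain = max(_longest_ordered_chain(same, decreasing=False),
                    _longest_ordered_chain(opposite, decreasing=True))
        colinearity = chain / len(links)

    return LinkSet(cluster_a=a.id, cluster_b=b.id, links=links,
                   link_fraction=link_fraction, colinearity=colinearity,
                   names_a=[g[0] for g in a.genes],
                   names_b=[g[0] for g in b.genes])


def write_links_tsv(linkset: LinkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("clusterA\tgeneA\tclusterB\tgeneB\tpct_identity\n")
        for i, j, ident in linkset.links:
            fh.write(f"{linkset.cluster_a}\t{linkset.names_a[i]}\t"
                     f"{linkset.cluster_b}\t{linkset.names_b[j]}\t"
                     f"{ident:.1f}\n")


def summary_dict(linkset: LinkSet) -> dict:
    return {
        "cluster_a": linkset.cluster_a,
        "cluster_b": linkset.cluster_b,
        "n_links": len(linkset.links),
        "link_fraction": round(linkset.link_fraction, 4),
        "colinearity": round(linkset.colinearity, 4),
    }
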