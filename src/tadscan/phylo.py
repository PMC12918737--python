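"""Distance-based phylogenetics: marker p-distances, fragment-mapping
average nucleotide identity (ANI), neighbor joining, and Newick I/O.

Two distance sources feed the same tree machinery:

* concatenated TadA+TadB+TadC protein p-distances (uncorrected by
  default; a Poisson correction is available via flag), mirroring the
  marker-based approach used for Tad system phylogenies;
* whole-genome ANI computed by chopping one genome into fixed-length
  fragments and mapping each against the other — the fragment-mapping
  strategy of FastANI-style estimators. ANI is asymmetric; trees use the
  symmetrised distance 1 − (ANI(a,b)+ANI(b,a))/200.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align_core import ScoringScheme, global_alignment, seeded_search


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if np.any(np.abs(np.diagonal(self.d)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for name, row in zip(self.taxa, self.d):
                fh.write(name + "  " +
                         "  ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list:
        return [l.name for l in self.leaves()]

    def min_leaf(self) -> str:
        return min(self.leaf_names())

    def n_leaves(self) -> int:
        return len(self.leaves())

    def ladderize(self) -> None:
        """Sort children by subtree size then lexicographically smallest
        leaf; deterministic display order."""
        for c in self.children:
            c.ladderize()
        self.children.sort(key=lambda c: (c.n_leaves(), c.min_leaf()))


def ladderized_leaf_order(tree: TreeNode) -> list:
    import copy

    t = copy.deepcopy(tree)
    t.ladderize()
    return t.leaf_names()


def write_newick(tree: TreeNode) -> str:
    def fmt(node, top=False):
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" \
                + node.name
        return body if top else f"{body}:{node.length:.6f}"

    return fmt(tree, top=True) + ";"


_TOKEN = re.compile(r"\(|\)|,|;|:[-+0-9.eE]+|[^():,;]+")


def read_newick(text: str) -> TreeNode:
    tokens = _TOKEN.findall(text.strip())
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if tokens[pos] == "(":
            pos += 1
            node.children.append(parse())
            while tokens[pos] == ",":
                pos += 1
                node.children.append(parse())
            if tokens[pos] != ")":
                raise ValueError("unbalanced parentheses in newick")
            pos += 1
        if pos < len(tokens) and tokens[pos] not in "(),;" \
                and not tokens[pos].startswith(":"):
            node.name = tokens[pos]
            pos += 1
        if pos < len(tokens) and tokens[pos].startswith(":"):
            node.length = float(tokens[pos][1:])
            pos += 1
        return node

    if not tokens:
        raise ValueError("empty newick string")
    try:
        root = parse()
    except IndexError:
        raise ValueError("truncated newick string") from None
    if pos >= len(tokens) or tokens[pos] != ";":
        raise ValueError("newick string must end with ';'")
    names = root.leaf_names()
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels")
    return root


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

MARKER_ROLES = ("tadA", "tadB", "tadC")


def p_distance(aligned_a: str, aligned_b: str,
               poisson: bool = False) -> float:
    """Fraction of non-identical columns among gap-free aligned columns."""
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b)
             if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no gap-free aligned columns")
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if poisson:
        if p >= 1.0:
            raise ValueError("saturated distance")
        return -math.log(1.0 - p)
    return p


def concat_distance(markers_by_taxon: dict,
                    roles=MARKER_ROLES,
                    poisson: bool = False,
                    scheme: ScoringScheme | None = None) -> DistanceMatrix:
    """p-distance matrix of concatenated marker proteins.

    ``markers_by_taxon`` maps taxon -> {role -> protein}; taxa missing
    any marker are dropped with a warning. Proteins are concatenated in
    the fixed role order before pairwise global alignment.
    """
    scheme = scheme or ScoringScheme.protein()
    concat = {}
    for taxon in sorted(markers_by_taxon):
        markers = markers_by_taxon[taxon]
        if any(r not in markers or not markers[r] for r in roles):
            warnings.warn(f"{taxon}: missing marker protein(s), dropped")
            continue
        concat[taxon] = "".join(markers[r] for r in roles)
    taxa = sorted(concat)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa with all markers")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, pa, pb = global_alignment(concat[taxa[i]], concat[taxa[j]],
                                         scheme)
            d[i, j] = d[j, i] = p_distance(pa, pb, poisson=poisson)
    return DistanceMatrix(taxa=taxa, d=d)


def ani(genome_a, genome_b, fragment_len: int = 1020,
        min_fragment_identity: float = 70.0,
        min_fragment_coverage: float = 0.7,
        min_fragments: int = 5) -> float | None:
    """Fragment-mapping average nucleotide identity of A against B.

    A's replicons are chopped into consecutive ``fragment_len`` windows
    (final tails shorter than half a window are discarded); each
    fragment's best hit in B is kept when it passes the identity and
    coverage floors, and ANI is the mean identity of kept fragments —
    undefined (None) when fewer than ``min_fragments`` survive.
    """
    fragments = {}
    idx = 0
    for rep in genome_a.replicons:
        seq = rep.sequence
        for start in range(0, len(seq), fragment_len):
            frag = seq[start:start + fragment_len]
            if len(frag) < fragment_len / 2:
                continue
            fragments[f"frag{idx:05d}"] = frag
            idx += 1
    if not fragments:
        return None

    scheme = ScoringScheme.nucleotide()
    hits = seeded_search(fragments, genome_b, scheme,
                         min_bitscore=50.0, max_evalue=1e-6)
    best: dict[str, object] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.query_id] = h

    kept = []
    for qid, h in best.items():
        coverage = (h.q_end - h.q_start) / len(fragments[qid])
        if h.pct_identity >= min_fragment_identity \
                and coverage >= min_fragment_coverage:
            kept.append(h.pct_identity)
    if len(kept) < min_fragments:
        return None
    return float(np.mean(kept))


def ani_distance_matrix(genomes: list, **ani_kwargs) -> DistanceMatrix:
    """Symmetrised ANI distances: 1 − (ANI(a,b)+ANI(b,a))/200.

    Pairs with undefined ANI in either direction get distance 1.0 with a
    warning.
    """
    genomes = sorted(genomes, key=lambda g: g.id)
    taxa = [g.id for g in genomes]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ab = ani(genomes[i], genomes[j], **ani_kwargs)
            ba = ani(genomes[j], genomes[i], **ani_kwargs)
            if ab is None or ba is None:
                warnings.warn(f"ANI undefined for {taxa[i]}/{taxa[j]}; "
                              f"distance set to 1.0")
                dist = 1.0
            else:
                dist = 1.0 - (ab + ba) / 200.0
            d[i, j] = d[j, i] = max(dist, 0.0)
    return DistanceMatrix(taxa=taxa, d=d)


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def _clamp_pair(bl_u: float, bl_v: float) -> tuple[float, float]:
    """Move a negative branch-length deficit onto the sibling branch."""
    if bl_u < 0:
        bl_v += bl_u
        bl_u = 0.0
    if bl_v < 0:
        bl_u += bl_v
        bl_v = 0.0
    return max(bl_u, 0.0), max(bl_v, 0.0)


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Canonical NJ with deterministic tie-breaking.

    The minimum-Q pair is chosen with ties broken by the lexicographic
    pair of subtree labels (smallest leaf under each node), so repeated
    runs on equal-distance inputs give identical trees. The final three
    nodes are joined by the three-point closed form. Negative branch
    lengths are clamped to zero, the deficit moved to the sibling.
    """
    n = len(m.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in m.taxa]
    labels = [t for t in m.taxa]
    d = m.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        na = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(na):
            for aj in range(ai + 1, na):
                i, j = active[ai], active[aj]
                q = (na - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bl_i = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (na - 2))
        bl_j = d[i, j] - bl_i
        bl_i, bl_j = _clamp_pair(bl_i, bl_j)
        nodes[i].length = bl_i
        nodes[j].length = bl_j
        new = TreeNode(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = \
                0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    bl_i = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bl_j = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bl_k = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(bl_i, 0.0)
    nodes[j].length = max(bl_j, 0.0)
    nodes[k].length = max(bl_k, 0.0)
    order = sorted((i, j, k), key=lambda x: labels[x])
    return TreeNode(children=[nodes[x] for x in order])


def upgma(m: DistanceMatrix) -> TreeNode:
    """Average-linkage clustering tree (ultrametric alternative to NJ)."""
    n = len(m.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=t) for t in m.taxa]
    heights = [0.0] * n
    sizes = [1] * n
    labels = list(m.taxa)
    d = m.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (d[i, j], tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = d[i, j] / 2.0
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        new = TreeNode(children=[nodes[i], nodes[j]])
        idx = len(nodes)
        nodes.append(new)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        labels.append(min(labels[i], labels[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[idx, k] = d[k, idx] = \
                (d[i, k] * sizes[i] + d[j, k] * sizes[j]) \
                / (sizes[i] + sizes[j])
        active = [k for k in active if k not in (i, j)] + [idx]
    return nodes[active[0]]


def tree_path_lengths(tree: TreeNode) -> dict:
    """Pairwise leaf-to-leaf path lengths (for additivity checks)."""
    out = {}

    def walk(node, dists):
        if node.is_leaf:
            for name, dist in dists.items():
                out[tuple(sorted((name, node.name)))] = dist
            dists[node.name] = 0.0
            return {node.name: 0.0}
        below = {}
        for child in node.children:
            sub = walk(child, {})
            for name in sub:
                sub[name] += child.length
            for n1, d1 in below.items():
                for n2, d2 in sub.items():
                    out[tuple(sorted((n1, n2)))] = d1 + d2
            below.update(sub)
        return below

    walk(tree, {})
    return out


def order_matrix_by_tree(matrix, tree: TreeNode):
    """Reorder presence-matrix rows by the ladderized leaf order; rows
    absent from the tree are appended alphabetically."""
    order = ladderized_leaf_order(tree)
    missing = sorted(set(matrix.table.index) - set(order))
    if missing:
        warnings.warn(f"{len(missing)} genome(s) not in tree, appended "
                      f"alphabetically: {missing[:5]}")
    return matrix.reorder(order)
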