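"""Seeded generator of reference clusters, genomes with implanted Tad
clusters, and ground-truth manifests.

The generator emulates the situations a genus-wide survey encounters:

* genomes carrying 0–4 implanted clusters at configurable protein
  identity to the references;
* *partial* clusters (core genes deleted before implanting);
* a degraded duplicate of one cluster implanted as another (the
  cluster-1-from-cluster-2 scenario);
* clusters split across two contigs (fragmented assemblies);
* pseudopilin genes (tadE/tadF/tadG) scattered far away from any
  canonical locus.

All randomness is driven by ``numpy.random.default_rng`` streams derived
from a single integer seed, so two runs with the same configuration are
byte-identical, and every emitted genome is accompanied by a manifest
recording implant positions, per-gene realised identities and the
intended status of every cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import Genome, GeneFeature, Replicon, write_fasta, write_genbank
from .references import (CLUSTER_ROLES, PSEUDOPILIN_ROLES, ReferenceCluster,
                         ReferenceSet, ROLE_LENGTHS, ROLE_STRAND)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# spatial layout constants (nt)
IMPLANT_SEPARATION = 10_000   # minimum background between implanted clusters
SCATTER_SEPARATION = 50_000   # minimum distance of scattered genes from implants
SCATTER_GAP = 8_000           # between scattered genes: beyond chaining reach
DECOY_GAP = 2_000


def _codon_tables():
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    stops = sorted(table.stop_codons)
    return by_aa, stops


_CODONS_BY_AA, _STOP_CODONS = _codon_tables()


_WEIGHT_CACHE: dict = {}


def _codon_weights(codons: list[str], gc: float) -> np.ndarray:
    key = (tuple(codons), gc)
    cached = _WEIGHT_CACHE.get(key)
    if cached is not None:
        return cached
    pg = gc / 2.0
    pa = (1.0 - gc) / 2.0
    w = np.array([np.prod([pg if b in "GC" else pa for b in c])
                  for c in codons])
    w = w / w.sum()
    _WEIGHT_CACHE[key] = w
    return w


_NT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _NT_CODES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(AA_ALPHABET[i]
                   for i in rng.integers(0, len(AA_ALPHABET), length - 1))
    return "M" + body


def back_translate(protein: str, gc: float, rng: np.random.Generator,
                   stop: bool = True) -> str:
    """Uniformly-seeded synonymous back-translation at the requested GC."""
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        codons.append(options[rng.choice(len(options),
                                         p=_codon_weights(options, gc))])
    if stop:
        codons.append(_STOP_CODONS[rng.choice(
            len(_STOP_CODONS), p=_codon_weights(_STOP_CODONS, gc))])
    return "".join(codons)


def mutate_to_identity(seq: str, target_identity: float, seed,
                       alphabet: str = AA_ALPHABET) -> str:
    """Substitute uniformly-random positions until the gapless identity to
    the input is within ±0.02 of the target (target 1.0 -> unchanged)."""
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if target_identity >= 1.0:
        return seq
    n_mut = int(round((1.0 - target_identity) * len(seq)))
    n_mut = min(n_mut, len(seq))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in sorted(positions):
        choices = [c for c in alphabet if c != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitutions at the given rate (binomially distributed)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    subs = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}
    idx = np.flatnonzero(hit)
    for i in idx:
        opts = subs[arr[i]]
        arr[i] = opts[rng.integers(0, 3)]
    return "".join(arr)


def _mutate_gene(nt_ref: str, aa_ref: str, target_identity: float, gc: float,
                 rng: np.random.Generator) -> tuple[str, str, float]:
    """Diverge one gene to a protein-identity target, keeping synonymous
    positions untouched so the nucleotide sequence stays alignable."""
    if target_identity >= 1.0:
        return nt_ref, aa_ref, 1.0
    L = len(aa_ref)
    n_mut = min(int(round((1.0 - target_identity) * L)), L - 1)
    positions = sorted(rng.choice(np.arange(1, L), size=min(n_mut, L - 1),
                                  replace=False))
    codons = [nt_ref[3 * i:3 * i + 3] for i in range(len(nt_ref) // 3)]
    aa = list(aa_ref)
    for p in positions:
        choices = [c for c in AA_ALPHABET if c != aa[p]]
        new = choices[rng.integers(0, len(choices))]
        aa[p] = new
        options = _CODONS_BY_AA[new]
        codons[p] = options[rng.choice(len(options),
                                       p=_codon_weights(options, gc))]
    realized = 1.0 - len(positions) / L
    return "".join(codons), "".join(aa), realized


# ---------------------------------------------------------------------------
# reference set
# ---------------------------------------------------------------------------

def make_reference_set(seed: int, gc: float = 0.64,
                       duplicate_identity: float = 0.85) -> ReferenceSet:
    """Stand-in reference clusters 1–4 with realistic protein lengths.

    Clusters 2 and 3 carry the full export-apparatus gene set with
    mutually independent random sequences; cluster 1 is a diverged
    duplicate of cluster 2 (default 85% protein identity) missing the
    pilin and secretin genes; cluster 4 holds the three pseudopilins.
    Deterministic under the seed.
    """
    rng2 = np.random.default_rng([int(seed), 2])
    rng3 = np.random.default_rng([int(seed), 3])
    rng4 = np.random.default_rng([int(seed), 4])
    rng1 = np.random.default_rng([int(seed), 1])

    def fresh_cluster(cid, rng):
        roles = CLUSTER_ROLES[cid]
        proteins = {r: random_protein(ROLE_LENGTHS[r], rng) for r in roles}
        nts = {r: back_translate(proteins[r], gc, rng) for r in roles}
        return ReferenceCluster(cluster_id=cid, roles=list(roles),
                                proteins=proteins, nucleotides=nts,
                                source=f"synthetic stand-in (seed {seed})")

    c2 = fresh_cluster(2, rng2)
    c3 = fresh_cluster(3, rng3)
    c4 = fresh_cluster(4, rng4)

    roles1 = CLUSTER_ROLES[1]
    prot1, nt1 = {}, {}
    for r in roles1:
        nt, aa, _ = _mutate_gene(c2.nucleotides[r], c2.proteins[r],
                                 duplicate_identity, gc, rng1)
        prot1[r], nt1[r] = aa, nt
    c1 = ReferenceCluster(cluster_id=1, roles=list(roles1), proteins=prot1,
                          nucleotides=nt1,
                          source=f"synthetic duplicate of cluster 2 "
                                 f"(seed {seed})")

    refs = ReferenceSet(clusters={1: c1, 2: c2, 3: c3, 4: c4})
    refs.validate_canonical()
    return refs


def default_reference_set() -> ReferenceSet:
    """The packaged stand-in reference fixture (fixed generator seed)."""
    return make_reference_set(seed=20110)


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class ImplantSpec:
    cluster_id: int
    status_target: str = "complete"        # complete | partial | absent
    protein_identity: float = 0.9
    fragmented: bool = False
    scattered_pseudopilins: bool = False   # emit tadE/F/G far from loci
    degraded_duplicate_of: int | None = None
    drop_roles: tuple = ()                 # roles removed for partial targets

    def __post_init__(self):
        if self.status_target not in ("complete", "partial", "absent"):
            raise ValueError(f"bad status_target {self.status_target!r}")
        if not 0.0 < self.protein_identity <= 1.0:
            raise ValueError("protein_identity must be in (0, 1]")


# default role removed to realise a 'partial' target, per cluster
_DEFAULT_DROP = {1: ("tadA",), 2: ("rcpA",), 3: ("rcpA",), 4: ("tadG",)}


@dataclass
class GenomeSpec:
    genome_id: str
    implants: list = field(default_factory=list)
    genome_len: int = 180_000
    gc: float = 0.64
    assembly_level: str = "complete"
    n_decoy_genes: int = 6


@dataclass
class SimConfig:
    seed: int
    genomes: list = field(default_factory=list)

    @classmethod
    def uniform(cls, seed: int, n_genomes: int, implants,
                genome_len: int = 180_000, gc: float = 0.64) -> "SimConfig":
        genomes = [
            GenomeSpec(genome_id=f"g{i:04d}",
                       implants=[ImplantSpec(**asdict(s)) for s in implants],
                       genome_len=genome_len, gc=gc)
            for i in range(n_genomes)
        ]
        return cls(seed=seed, genomes=genomes)


def survey_config(seed: int, n_genomes: int = 100,
                  genome_len: int = 180_000) -> SimConfig:
    """Study conditions of the genus-wide survey, as composition fractions.

    95% of genomes carry clusters 1 and 2; cluster 3 is present in half;
    the canonical cluster-4 locus is present in 48.5% while scattered
    pseudopilin genes bring TadG (and TadE/TadF) presence to 95%; the 5%
    of genomes without Tad loci are contig-level assemblies, and 10% of
    cluster-2 carriers have that cluster split across two contigs.
    """
    rng = np.random.default_rng([int(seed), 999])
    n_detect = int(round(0.95 * n_genomes))
    detectable = list(rng.permutation(n_genomes)[:n_detect])
    n_c3 = int(round(0.50 * n_genomes))
    c3_set = set(np.array(detectable)[rng.permutation(n_detect)[:n_c3]])
    n_c4 = int(round(0.485 * n_genomes))
    order4 = rng.permutation(n_detect)
    c4_set = set(np.array(detectable)[order4[:n_c4]])
    n_tadg = int(round(0.95 * n_genomes))
    scatter_set = set(np.array(detectable)[order4[n_c4:n_tadg]])
    n_frag = int(round(0.10 * n_genomes))
    frag_set = set(np.array(detectable)[rng.permutation(n_detect)[:n_frag]])

    genomes = []
    for i in range(n_genomes):
        gid = f"g{i:04d}"
        if i not in set(detectable):
            genomes.append(GenomeSpec(genome_id=gid, implants=[],
                                      genome_len=genome_len,
                                      assembly_level="contig"))
            continue
        implants = [
            ImplantSpec(cluster_id=1,
                        protein_identity=float(rng.uniform(0.85, 1.0))),
            ImplantSpec(cluster_id=2, fragmented=(i in frag_set),
                        protein_identity=float(rng.uniform(0.85, 1.0))),
        ]
        if i in c3_set:
            implants.append(ImplantSpec(
                cluster_id=3, protein_identity=float(rng.uniform(0.85, 1.0))))
        if i in c4_set:
            implants.append(ImplantSpec(
                cluster_id=4, protein_identity=float(rng.uniform(0.85, 1.0))))
        elif i in scatter_set:
            implants.append(ImplantSpec(
                cluster_id=4, status_target="absent",
                scattered_pseudopilins=True,
                protein_identity=float(rng.uniform(0.85, 1.0))))
        level = "contig" if i in frag_set else "complete"
        genomes.append(GenomeSpec(genome_id=gid, implants=implants,
                                  genome_len=genome_len,
                                  assembly_level=level))
    return SimConfig(seed=seed, genomes=genomes)


def recovery_config(seed: int, n_genomes: int = 100,
                    genome_len: int = 180_000,
                    min_identity: float = 0.7) -> SimConfig:
    """Mixed-status benchmark: per genome and cluster, complete, partial
    or absent targets at protein identities drawn from
    [min_identity, 1.0], with occasional fragmentation and scattered
    pseudopilins."""
    rng = np.random.default_rng([int(seed), 777])
    genomes = []
    for i in range(n_genomes):
        implants = []
        for cid in (1, 2, 3, 4):
            status = ("complete", "partial", "absent")[rng.integers(0, 3)]
            ident = float(rng.uniform(min_identity, 1.0))
            frag = bool(status != "absent" and cid == 2
                        and rng.random() < 0.15)
            scattered = bool(cid == 4 and status == "absent"
                             and rng.random() < 0.5)
            implants.append(ImplantSpec(
                cluster_id=cid, status_target=status,
                protein_identity=ident, fragmented=frag,
                scattered_pseudopilins=scattered))
        level = "contig" if any(s.fragmented for s in implants) \
            else "complete"
        genomes.append(GenomeSpec(genome_id=f"g{i:04d}", implants=implants,
                                  genome_len=genome_len,
                                  assembly_level=level))
    return SimConfig(seed=seed, genomes=genomes)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _build_implant_block(spec: ImplantSpec, refs: ReferenceSet, gc: float,
                         rng: np.random.Generator):
    """Sequence of one implanted cluster plus gene sub-features.

    Returns (sequence, genes) with genes as (role, offset_start,
    offset_end, strand, realized_identity).
    """
    from .align_core import revcomp

    source_cid = spec.degraded_duplicate_of or spec.cluster_id
    cluster = refs.clusters[spec.cluster_id]
    source = refs.clusters[source_cid]
    roles = [r for r in cluster.roles if r in source.roles]
    if spec.status_target == "partial":
        drop = spec.drop_roles or _DEFAULT_DROP.get(spec.cluster_id, ())
        roles = [r for r in roles if r not in drop]

    parts = []
    genes = []
    pos = 0
    for idx, role in enumerate(roles):
        if idx > 0:
            spacer = int(rng.integers(20, 121))
            parts.append(random_dna(spacer, gc, rng))
            pos += spacer
        nt, aa, realized = _mutate_gene(
            source.nucleotides[role], source.proteins[role],
            spec.protein_identity, gc, rng)
        strand = ROLE_STRAND.get(role, "+")
        insert = revcomp(nt) if strand == "-" else nt
        parts.append(insert)
        genes.append((role, pos, pos + len(insert), strand, realized))
        pos += len(insert)
    return "".join(parts), genes


def _scattered_genes(spec: ImplantSpec, refs: ReferenceSet, gc: float,
                     rng: np.random.Generator):
    """Lone pseudopilin genes to be placed far from any cluster locus."""
    cluster = refs.clusters[spec.cluster_id]
    out = []
    for role in PSEUDOPILIN_ROLES:
        if role not in cluster.roles:
            continue
        nt, aa, realized = _mutate_gene(
            cluster.nucleotides[role], cluster.proteins[role],
            spec.protein_identity, gc, rng)
        out.append((role, nt, realized))
    return out


def build_genome(spec: GenomeSpec, refs: ReferenceSet, seed: int,
                 index: int = 0) -> tuple[Genome, dict]:
    """Assemble one genome and its truth record."""
    rng = np.random.default_rng([int(seed), 101, index])
    gc = spec.gc

    blocks = []  # (kind, payload) in genomic order
    active = [s for s in spec.implants if s.status_target != "absent"]
    scattered_specs = [s for s in spec.implants if s.scattered_pseudopilins]

    layout = []  # (start, end, kind, payload) on the assembled chromosome
    seq_parts = []
    pos = 0

    def append_bg(n):
        nonlocal pos
        if n <= 0:
            return
        seq_parts.append(random_dna(int(n), gc, rng))
        pos += int(n)

    append_bg(rng.integers(4000, 8001))
    implant_records = []
    for spec_i in active:
        if implant_records:
            append_bg(IMPLANT_SEPARATION + rng.integers(0, 2001))
        block_seq, genes = _build_implant_block(spec_i, refs, gc, rng)
        start = pos
        seq_parts.append(block_seq)
        pos += len(block_seq)
        implant_records.append({
            "spec": spec_i, "start": start, "end": pos, "genes": genes,
        })

    scatter_records = []
    if scattered_specs:
        append_bg(SCATTER_SEPARATION + rng.integers(0, 2001))
        for spec_i in scattered_specs:
            for role, nt, realized in _scattered_genes(spec_i, refs, gc, rng):
                start = pos
                seq_parts.append(nt)
                pos += len(nt)
                scatter_records.append({
                    "cluster_id": spec_i.cluster_id, "role": role,
                    "start": start, "end": pos, "identity": realized,
                })
                append_bg(SCATTER_GAP + rng.integers(0, 4001))

    decoy_records = []
    append_bg(DECOY_GAP)
    for d in range(spec.n_decoy_genes):
        aa = random_protein(int(rng.integers(150, 401)), rng)
        nt = back_translate(aa, gc, rng)
        start = pos
        seq_parts.append(nt)
        pos += len(nt)
        decoy_records.append({"start": start, "end": pos})
        append_bg(DECOY_GAP + rng.integers(0, 1001))

    if pos > spec.genome_len:
        raise ValueError(
            f"{spec.genome_id}: genome_len {spec.genome_len} too short for "
            f"requested implants (need {pos})")
    append_bg(spec.genome_len - pos)
    chromosome = "".join(seq_parts)

    # fragmentation: split the chromosome between two genes of the first
    # fragmented implant, yielding two contigs with no sequence loss
    cut = None
    for rec in implant_records:
        if rec["spec"].fragmented and len(rec["genes"]) >= 2:
            mid = len(rec["genes"]) // 2
            cut = rec["start"] + (rec["genes"][mid - 1][2]
                                  + rec["genes"][mid][1]) // 2
            break

    if cut is None:
        replicons = [Replicon(id=f"{spec.genome_id}_r1",
                              sequence=chromosome)]
        offsets = [(f"{spec.genome_id}_r1", 0, len(chromosome))]
    else:
        replicons = [
            Replicon(id=f"{spec.genome_id}_r1", sequence=chromosome[:cut]),
            Replicon(id=f"{spec.genome_id}_r2", sequence=chromosome[cut:]),
        ]
        offsets = [(f"{spec.genome_id}_r1", 0, cut),
                   (f"{spec.genome_id}_r2", cut, len(chromosome))]

    def locate(start, end):
        for rid, off, lim in offsets:
            if start >= off and end <= lim:
                return rid, start - off, end - off
        return None  # straddles the contig break

    features = []
    counter = 0

    def add_feature(start, end, strand, product, translation):
        nonlocal counter
        loc = locate(start, end)
        if loc is None:
            return None
        counter += 1
        tag = f"{spec.genome_id}_{counter:04d}"
        rid, s, e = loc
        features.append(GeneFeature(
            locus_tag=tag, replicon_id=rid, start=s, end=e, strand=strand,
            product=product, translation=translation))
        return {"locus_tag": tag, "replicon": rid, "start": s, "end": e,
                "strand": strand}

    truth_implants = []
    for rec in implant_records:
        spec_i = rec["spec"]
        gene_entries = []
        for role, g0, g1, strand, realized in rec["genes"]:
            start, end = rec["start"] + g0, rec["start"] + g1
            src = refs.clusters[spec_i.degraded_duplicate_of
                                or spec_i.cluster_id]
            aa = None
            placed = add_feature(start, end, strand, f"Tad pilus {role}",
                                 aa)
            entry = {"role": role, "protein_identity": realized,
                     "global_start": start, "global_end": end}
            if placed:
                entry.update(placed)
            gene_entries.append(entry)
        truth_implants.append({
            "cluster_id": spec_i.cluster_id,
            "status_target": spec_i.status_target,
            "protein_identity_target": spec_i.protein_identity,
            "fragmented": bool(spec_i.fragmented and cut is not None),
            "degraded_duplicate_of": spec_i.degraded_duplicate_of,
            "start": rec["start"], "end": rec["end"],
            "genes": gene_entries,
        })
    for spec_i in (s for s in spec.implants if s.status_target == "absent"
                   and not s.scattered_pseudopilins):
        truth_implants.append({
            "cluster_id": spec_i.cluster_id, "status_target": "absent",
            "fragmented": False, "genes": [],
        })

    truth_scattered = []
    for rec in scatter_records:
        placed = add_feature(rec["start"], rec["end"], "+",
                             f"pseudopilin {rec['role']}", None)
        entry = {"cluster_id": rec["cluster_id"], "role": rec["role"],
                 "protein_identity": rec["identity"]}
        if placed:
            entry.update(placed)
        truth_scattered.append(entry)
        # a scattered-only cluster 4 is canonically absent
    for spec_i in scattered_specs:
        truth_implants.append({
            "cluster_id": spec_i.cluster_id, "status_target": "absent",
            "fragmented": False, "genes": [],
            "scattered_pseudopilins": True,
        })

    for rec in decoy_records:
        add_feature(rec["start"], rec["end"], "+", "hypothetical protein",
                    None)

    genome = Genome(id=spec.genome_id, replicons=replicons,
                    features=features, assembly_level=spec.assembly_level)
    truth = {
        "genome_id": spec.genome_id,
        "assembly_level": spec.assembly_level,
        "genome_len": spec.genome_len,
        "gc": gc,
        "n_features": len(features),
        "implants": truth_implants,
        "scattered": truth_scattered,
    }
    return genome, truth


def build_genomes(cfg: SimConfig, refs: ReferenceSet | None = None,
                  out_dir=None):
    """Build all genomes of a configuration; optionally write GenBank,
    FASTA and the truth manifest to ``out_dir``.

    Returns (genomes, manifest).
    """
    refs = refs or default_reference_set()
    genomes = []
    manifest = {"seed": cfg.seed, "genomes": {}}
    for index, spec in enumerate(cfg.genomes):
        genome, truth = build_genome(spec, refs, cfg.seed, index)
        genomes.append(genome)
        manifest["genomes"][spec.genome_id] = truth
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for genome, spec in zip(genomes, cfg.genomes):
            gbk = out_dir / f"{genome.id}.gbk"
            fna = out_dir / f"{genome.id}.fna"
            write_genbank(genome, gbk)
            write_fasta(genome, fna)
            manifest["genomes"][genome.id]["files"] = {
                "genbank": gbk.name, "fasta": fna.name}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return genomes, manifest
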