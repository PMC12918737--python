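"""Reference Tad cluster definitions: ordered gene roles plus sequences.

The Tad (type IVc) pilus locus layout modelled here follows the four
clusters found in *Bradyrhizobium diazoefficiens* USDA 110, numbered by
chromosomal order:

* **cluster 1** — a degraded duplicate of cluster 2 lacking the pilin
  (``flp``) and secretin (``rcpA``) genes, so it cannot encode a complete
  export apparatus on its own;
* **cluster 2** — the major cluster with the full set of export-apparatus
  genes (pilin ``flp``, prepilin peptidase ``tadV``, secretin ``rcpA``
  with its partner ``rcpC``, localisation factor ``tadZ``, ATPase
  ``tadA``, inner-membrane platform ``tadB``/``tadC``);
* **cluster 3** — a second complete cluster of independent evolutionary
  origin (sequences unrelated to cluster 2 beyond chance);
* **cluster 4** — the pseudopilin cluster ``tadE``/``tadF``/``tadG``,
  whose genes are frequently scattered around the genome instead of
  forming a canonical locus.

Role flags drive completeness calls: a cluster is *complete* when every
one of its non-accessory roles is found at the locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

ROLE_FLAGS = {
    "flp": "pilin",
    "tadV": "core_export",
    "rcpC": "accessory",
    "rcpA": "core_export",
    "tadZ": "core_export",
    "tadA": "core_export",
    "tadB": "core_export",
    "tadC": "core_export",
    "tadE": "pseudopilin",
    "tadF": "pseudopilin",
    "tadG": "pseudopilin",
}

# genomic order of roles within each canonical cluster
CLUSTER_ROLES = {
    1: ["tadV", "rcpC", "tadZ", "tadA", "tadB", "tadC"],
    2: ["flp", "tadV", "rcpC", "rcpA", "tadZ", "tadA", "tadB", "tadC"],
    3: ["flp", "tadV", "rcpC", "rcpA", "tadZ", "tadA", "tadB", "tadC"],
    4: ["tadE", "tadF", "tadG"],
}

# realistic protein lengths (aa); Flp pilins are small (~6-8 kDa)
ROLE_LENGTHS = {
    "flp": 62, "tadV": 190, "rcpC": 310, "rcpA": 455, "tadZ": 350,
    "tadA": 400, "tadB": 305, "tadC": 290, "tadE": 180, "tadF": 205,
    "tadG": 545,
}

# coding strand of each gene within its cluster (locus-level detection
# must tolerate strand switches, so one role is placed antisense)
ROLE_STRAND = {role: "+" for role in ROLE_FLAGS}
ROLE_STRAND["rcpC"] = "-"

PSEUDOPILIN_ROLES = ("tadE", "tadF", "tadG")


@dataclass
class ReferenceCluster:
    """One canonical Tad cluster: ordered roles plus per-role sequences."""

    cluster_id: int
    roles: list[str]
    proteins: dict[str, str]
    nucleotides: dict[str, str]
    source: str = ""
    role_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.role_flags:
            self.role_flags = {r: ROLE_FLAGS.get(r, "accessory")
                               for r in self.roles}
        missing = [r for r in self.roles
                   if r not in self.proteins or r not in self.nucleotides]
        if missing:
            raise ValueError(
                f"cluster {self.cluster_id}: sequences missing for {missing}")

    def required_roles(self) -> set[str]:
        """Roles that must be found for a 'complete' call (non-accessory)."""
        return {r for r in self.roles
                if self.role_flags.get(r) != "accessory"}


@dataclass
class ReferenceSet:
    clusters: dict[int, ReferenceCluster]

    def validate_canonical(self) -> None:
        """Check the invariants of the canonical four-cluster layout."""
        core = {r for r, f in ROLE_FLAGS.items() if f == "core_export"}
        for cid in (2, 3):
            if cid in self.clusters:
                have = set(self.clusters[cid].roles)
                if not core <= have:
                    raise ValueError(f"cluster {cid} lacks core roles "
                                     f"{core - have}")
        if 1 in self.clusters and 2 in self.clusters:
            r1 = set(self.clusters[1].roles)
            r2 = set(self.clusters[2].roles)
            if not (r1 < r2):
                raise ValueError("cluster 1 roles must be a proper subset "
                                 "of cluster 2 roles")
            if not (core - r1):
                raise ValueError("cluster 1 must lack at least one core "
                                 "export role")
        if 4 in self.clusters:
            if set(self.clusters[4].roles) - set(PSEUDOPILIN_ROLES):
                raise ValueError("cluster 4 roles must be pseudopilins")

    def nucleotide_queries(self) -> list[tuple[str, str]]:
        """Per-gene nucleotide queries, ids 'c<cluster>|<role>'."""
        out = []
        for cid in sorted(self.clusters):
            c = self.clusters[cid]
            for role in c.roles:
                out.append((f"c{cid}|{role}", c.nucleotides[role]))
        return out

    def protein_refs(self) -> list[tuple[str, str]]:
        out = []
        for cid in sorted(self.clusters):
            c = self.clusters[cid]
            for role in c.roles:
                out.append((f"c{cid}|{role}", c.proteins[role]))
        return out

    def role_clusters(self) -> dict[str, set]:
        """Map role -> set of clusters encoding it (for paralog naming)."""
        out: dict[str, set] = {}
        for cid, c in self.clusters.items():
            for role in c.roles:
                out.setdefault(role, set()).add(cid)
        return out


def save_reference_set(refs: ReferenceSet, directory) -> None:
    """Write a reference set as protein + nucleotide FASTA plus a JSON
    manifest of ordered roles and flags."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    with open(directory / "references_protein.faa", "w") as pfh, \
            open(directory / "references_nt.fna", "w") as nfh:
        for cid in sorted(refs.clusters):
            c = refs.clusters[cid]
            manifest[str(cid)] = {
                "roles": c.roles,
                "flags": c.role_flags,
                "source": c.source,
            }
            for role in c.roles:
                pfh.write(f">c{cid}|{role}\n{c.proteins[role]}\n")
                nfh.write(f">c{cid}|{role}\n{c.nucleotides[role]}\n")
    with open(directory / "references.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_reference_set(directory) -> ReferenceSet:
    from Bio import SeqIO

    directory = Path(directory)
    with open(directory / "references.json") as fh:
        manifest = json.load(fh)
    prot = {rec.id: str(rec.seq) for rec in
            SeqIO.parse(str(directory / "references_protein.faa"), "fasta")}
    nt = {rec.id: str(rec.seq) for rec in
          SeqIO.parse(str(directory / "references_nt.fna"), "fasta")}
    clusters = {}
    for cid_str, entry in manifest.items():
        cid = int(cid_str)
        roles = entry["roles"]
        clusters[cid] = ReferenceCluster(
            cluster_id=cid, roles=roles,
            proteins={r: prot[f"c{cid}|{r}"] for r in roles},
            nucleotides={r: nt[f"c{cid}|{r}"] for r in roles},
            source=entry.get("source", ""),
            role_flags=entry.get("flags", {}),
        )
    return ReferenceSet(clusters=clusters)
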