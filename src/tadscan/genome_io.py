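"""Genome input/output: GenBank and FASTA parsing, proteome extraction.

Internal coordinates are 0-based half-open everywhere; conversion to and
from the 1-based inclusive GenBank convention happens only at the format
boundary (Biopython already stores locations half-open, so parsing is a
pass-through). Ambiguous IUPAC nucleotide codes are normalised to ``N``,
which all aligners in this package treat as a mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

ASSEMBLY_LEVELS = ("complete", "scaffold", "contig", "unknown")


class GenomeFormatError(ValueError):
    """Raised on malformed genome input files."""


def _normalise_nt(seq: str, context: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _IUPAC_NT - {"T"}
    if bad:
        raise GenomeFormatError(
            f"{context}: non-IUPAC nucleotide characters {sorted(bad)!r}")
    return seq.translate(_TO_N)


@dataclass
class Replicon:
    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r} has empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    locus_tag: str
    replicon_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    translation: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")


@dataclass
class Genome:
    id: str
    replicons: list[Replicon] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    assembly_level: str = "unknown"

    def __post_init__(self):
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValueError(f"bad assembly_level {self.assembly_level!r}")
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.id}: duplicate replicon ids")
        by_id = {r.id: r for r in self.replicons}
        tags = set()
        for f in self.features:
            rep = by_id.get(f.replicon_id)
            if rep is None:
                raise ValueError(
                    f"{f.locus_tag}: unknown replicon {f.replicon_id!r}")
            if f.end > len(rep):
                raise ValueError(
                    f"{f.locus_tag}: interval exceeds replicon length")
            if f.locus_tag in tags:
                raise ValueError(f"duplicate locus_tag {f.locus_tag!r}")
            tags.add(f.locus_tag)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Coding-strand nucleotide sequence of a feature."""
        from .align_core import revcomp

        seq = self.replicon(feat.replicon_id).sequence[feat.start:feat.end]
        return revcomp(seq) if feat.strand == "-" else seq


def translate_cds(nt_seq: str, table: int = 11) -> str:
    """Translate a coding-strand CDS; trailing stop removed.

    Raises ValueError on an internal stop codon (pseudogene).
    """
    aa = str(Seq(nt_seq[: len(nt_seq) - len(nt_seq) % 3]).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon")
    return aa


def _parse_assembly_level(record) -> str:
    comment = str(record.annotations.get("comment", "")).lower()
    for level in ("complete", "scaffold", "contig"):
        if f"assembly level: {level}" in comment:
            return level
    return "unknown"


def read_genbank(path) -> Genome:
    """Parse a GenBank flat file into a Genome (one Replicon per LOCUS).

    CDS features become GeneFeatures; a CDS without /translation is
    translated from its coordinates (bacterial code, table 11). Compound
    (join) locations are kept only when colinear on one replicon.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeFormatError(f"{path}: GenBank parse error: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no LOCUS records found")

    replicons, features = [], []
    level = "unknown"
    for rec in records:
        seq = _normalise_nt(str(rec.seq), f"{path}:{rec.id}")
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        replicons.append(Replicon(id=rec.id, sequence=seq, topology=topology))
        lvl = _parse_assembly_level(rec)
        if lvl != "unknown":
            level = lvl
        n_anon = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            loc = feat.location
            parts = getattr(loc, "parts", [loc])
            if len(parts) > 1:
                strands = {p.strand for p in parts}
                starts = [int(p.start) for p in parts]
                colinear = (len(strands) == 1 and starts == sorted(starts))
                if not colinear:
                    warnings.warn(
                        f"{rec.id}: skipping non-colinear compound CDS at "
                        f"{loc}")
                    continue
            start, end = int(loc.start), int(loc.end)
            if end > len(seq) and topology == "linear":
                warnings.warn(
                    f"{rec.id}: CDS [{start},{end}) extends past linear "
                    f"replicon end; skipped")
                continue
            tag = feat.qualifiers.get("locus_tag", [None])[0]
            if tag is None:
                n_anon += 1
                tag = f"{rec.id}_cds{n_anon:04d}"
            strand = "-" if loc.strand == -1 else "+"
            translation = feat.qualifiers.get("translation", [None])[0]
            features.append(GeneFeature(
                locus_tag=tag, replicon_id=rec.id, start=start, end=end,
                strand=strand,
                product=feat.qualifiers.get("product", [""])[0],
                translation=translation,
            ))
    return Genome(id=path.stem, replicons=replicons, features=features,
                  assembly_level=level)


def read_fasta(path, genome_id: str | None = None) -> Genome:
    """Parse a nucleotide FASTA into a featureless Genome."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"{path}: empty FASTA file")
    replicons = [
        Replicon(id=rec.id, sequence=_normalise_nt(str(rec.seq), rec.id))
        for rec in records
    ]
    return Genome(id=genome_id or path.stem, replicons=replicons)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in genome.replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, len(rep.sequence), width):
                fh.write(rep.sequence[i:i + width] + "\n")


def write_protein_fasta(proteome, genome_id: str, path,
                        width: int = 70) -> None:
    """Write (locus_tag, aa_sequence) pairs with '<genome_id>|<locus_tag>'
    headers."""
    with open(path, "w") as fh:
        for tag, aa in proteome:
            fh.write(f">{genome_id}|{tag}\n")
            for i in range(0, len(aa), width):
                fh.write(aa[i:i + width] + "\n")


def write_genbank(genome: Genome, path) -> None:
    """Emit one GenBank record per replicon with CDS features."""
    records = []
    for rep in genome.replicons:
        rec = SeqRecord(Seq(rep.sequence), id=rep.id, name=rep.id[:16],
                        description=f"{genome.id} {rep.id}")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        rec.annotations["comment"] = (
            f"Assembly level: {genome.assembly_level}")
        for f in genome.features:
            if f.replicon_id != rep.id:
                continue
            qualifiers = {"locus_tag": [f.locus_tag]}
            if f.product:
                qualifiers["product"] = [f.product]
            if f.translation:
                qualifiers["translation"] = [f.translation]
            rec.features.append(SeqFeature(
                FeatureLocation(f.start, f.end,
                                strand=1 if f.strand == "+" else -1),
                type="CDS", qualifiers=qualifiers))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def extract_proteome(genome: Genome) -> list[tuple[str, str]]:
    """Amino-acid sequences of all CDS features, as (locus_tag, protein).

    Features with a /translation qualifier are taken as annotated;
    otherwise the CDS is translated from its coordinates with the standard
    bacterial code (table 11), reverse-complementing minus-strand genes
    first. CDS with internal stop codons are flagged pseudo and excluded.
    """
    out = []
    for feat in genome.features:
        if feat.translation:
            out.append((feat.locus_tag, feat.translation))
            continue
        nt = genome.feature_sequence(feat)
        try:
            aa = translate_cds(nt)
        except ValueError:
            warnings.warn(
                f"{genome.id}:{feat.locus_tag}: internal stop codon, "
                f"excluded as pseudogene")
            continue
        if aa:
            out.append((feat.locus_tag, aa))
    return out
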