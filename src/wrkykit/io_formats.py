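"""Readers and writers for the external formats the pipeline touches.

Protein FASTA, a gene-model subset of GFF3 (gene/mRNA/CDS), the curated
family table (TSV, one row per gene with a ``chrom:start:end`` locus
string), and Newick trees.  All genomic coordinates are 1-based inclusive
throughout the package; any half-open arithmetic is internal.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: 20 canonical amino acids plus X (unknown residue).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

FAMILY_TABLE_COLUMNS = [
    "name", "gene_id", "locus", "protein_length", "mw", "pi",
    "localization", "est_number", "heptapeptide", "zf_type",
    "domain_number", "subgroup", "homolog",
]

SUBGROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "IIx", "III")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: canonical residues plus X, always uppercase."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FamilyMember:
    """One curated gene record — the in-memory form of a family-table row.

    ``zf_type`` is the zinc-finger class (C2H2 or C2HC), ``domain_number``
    the number of WRKY domains (1 or 2), and ``subgroup`` the published
    label (I, IIa-e, IIx, III).  Coordinates are 1-based inclusive bp on
    ``chromosome`` (a linkage group Pa1..Pa8 or a scaffold).
    """

    name: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    protein_length: int
    mw: float
    pi: float
    localization: str
    heptapeptide: str
    zf_type: str
    domain_number: int
    subgroup: str
    homolog: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.name}: start {self.start} >= end {self.end}"
            )
        if self.domain_number not in (1, 2):
            raise ValidationError(
                f"{self.name}: domain_number {self.domain_number} not in {{1,2}}"
            )
        if len(self.heptapeptide) != 7:
            raise ValidationError(f"{self.name}: heptapeptide not 7 aa")
        if self.zf_type not in ("C2H2", "C2HC"):
            raise ValidationError(f"{self.name}: bad zinc-finger type {self.zf_type}")
        if self.subgroup not in SUBGROUPS:
            raise ValidationError(f"{self.name}: unknown subgroup {self.subgroup}")


@dataclass
class GeneModel:
    """Gene model: CDS exon intervals on a chromosome, 1-based inclusive.

    Exons are stored in genomic order regardless of strand; translation
    order is derived from ``strand``.  ``cds_phase_offset`` is the number
    of bases to skip before the first complete codon.
    """

    id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_phase_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.id}: no exons")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"{self.id}: overlapping CDS intervals ({s1},{e1}) and ({s2},{e2})"
                )
        self.exons = exons

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons) - self.cds_phase_offset


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved.  An empty file or
    an illegal residue raises :class:`FormatError` naming the record.
    """
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Family table

def _parse_locus(locus: str) -> tuple[str, int, int]:
    parts = locus.split(":")
    if len(parts) != 3:
        raise FormatError(f"malformed locus string {locus!r}")
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    return chrom, start, end


def read_family_table(path: str | Path | None = None) -> list[FamilyMember]:
    """Read a curated family table (TSV); defaults to the bundled fixture.

    Locus strings like ``Pa1:1070280:1072953`` are split into
    chromosome/start/end.  A missing column raises :class:`FormatError`;
    start >= end raises :class:`ValidationError`.
    """
    if path is None:
        source = resources.files("wrkykit.data").joinpath("family_table.tsv")
        df = pd.read_csv(io.StringIO(source.read_text()), sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(FAMILY_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"family table missing column(s): {sorted(missing)}")
    members = []
    for _, row in df.iterrows():
        chrom, start, end = _parse_locus(row["locus"])
        homolog = row["homolog"]
        members.append(FamilyMember(
            name=row["name"],
            gene_id=row["gene_id"],
            chromosome=chrom,
            start=start,
            end=end,
            protein_length=int(row["protein_length"]),
            mw=float(row["mw"]),
            pi=float(row["pi"]),
            localization=row["localization"],
            heptapeptide=row["heptapeptide"],
            zf_type=row["zf_type"],
            domain_number=int(row["domain_number"]),
            subgroup=row["subgroup"],
            homolog="" if pd.isna(homolog) or homolog == "-" else homolog,
        ))
    return members


# ---------------------------------------------------------------------------
# GFF3 subset (gene / mRNA / CDS)

_GFF_KEPT = {"gene", "mRNA", "CDS"}


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 subset (gene/mRNA/CDS features only).

    CDS intervals are grouped per parent mRNA and sorted; minus-strand
    models keep genomic interval order with the strand flag set.  Other
    feature types are ignored with a logged warning.  A CDS without a
    parent raises :class:`FormatError`.
    """
    mrna_meta: dict[str, tuple[str, str]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    phase0: dict[str, int] = {}
    order: list[str] = []
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, phase, attrs = fields
            if ftype not in _GFF_KEPT:
                skipped.add(ftype)
                continue
            a = _gff_attributes(attrs)
            if ftype == "mRNA":
                mid = a.get("ID")
                if mid is None:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID")
                mrna_meta[mid] = (chrom, strand)
                order.append(mid)
            elif ftype == "CDS":
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: CDS without parent mRNA")
                iv = (int(start), int(end))
                cds.setdefault(parent, []).append(iv)
                if parent not in phase0 and phase.isdigit():
                    phase0[parent] = int(phase)
    if skipped:
        logger.warning("ignored GFF3 feature types: %s", ", ".join(sorted(skipped)))
    models = []
    for mid in order:
        if mid not in cds:
            continue
        chrom, strand = mrna_meta[mid]
        models.append(GeneModel(
            id=mid, chromosome=chrom, strand=strand, exons=cds[mid],
            cds_phase_offset=phase0.get(mid, 0),
        ))
    orphans = set(cds) - set(mrna_meta)
    for mid in sorted(orphans):
        chrom = "?"
        models.append(GeneModel(id=mid, chromosome=chrom, strand="+", exons=cds[mid]))
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a GFF3 subset (mRNA + CDS lines)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            fh.write(f"{m.chromosome}\twrkykit\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={m.id}\n")
            for s, e in m.exons:
                fh.write(
                    f"{m.chromosome}\twrkykit\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\tParent={m.id}\n"
                )


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree) -> str:
    """Serialise a :class:`~wrkykit.classification.PhyloTree` to Newick.

    Branch lengths are always written; internal bootstrap supports, when
    present, are emitted as internal node labels.  An unlabeled leaf is an
    error.
    """

    def render(node) -> str:
        if not node.children:
            if not node.name:
                raise ValidationError("unlabeled leaf in tree")
            return f"{node.name}:{node.length:g}"
        inner = ",".join(render(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}:{node.length:g}"

    root = tree.root
    inner = ",".join(render(c) for c in root.children)
    return f"({inner});"


def read_newick(text: str):
    """Parse Newick text with Bio.Phylo (used for round-trip validation)."""
    from Bio import Phylo

    return Phylo.read(io.StringIO(text), "newick")
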