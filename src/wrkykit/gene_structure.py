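"""Exon/intron inference and conserved-intron typing inside WRKY domains.

Two conserved intron positions occur inside the DNA-binding domain of
this family: the R-type intron, spliced exactly after the codon of an
arginine upstream of the zinc finger, and the V-type intron, spliced
immediately before the codon of the valine six residues after the zinc
finger's second cysteine.  Typing is done in translation coordinates
(strand-aware); genomic spans stay genomic.  Splices that split a codon
(phase 1/2) never match either conserved position and are reported as
"other".
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain_scan import WRKYDomain
from .errors import ValidationError
from .io_formats import GeneModel


@dataclass(frozen=True)
class IntronRecord:
    """An intron between two exons.

    ``phase`` is (CDS bases before the splice) mod 3; ``protein_context``
    is the 0-based index of the last residue with any coding base before
    the splice.
    """

    gene: str
    index: int
    genomic_span: tuple[int, int]
    phase: int
    protein_context: int


def _translation_order_exons(model: GeneModel) -> list[tuple[int, int]]:
    exons = list(model.exons)
    return exons if model.strand == "+" else exons[::-1]


def infer_introns(model: GeneModel) -> list[IntronRecord]:
    """Introns as gaps between consecutive exons, phases in translation order.

    A single-exon model yields an empty list.
    """
    exons_tx = _translation_order_exons(model)
    introns = []
    cds_before = -model.cds_phase_offset
    for idx, (exon, nxt) in enumerate(zip(exons_tx, exons_tx[1:])):
        cds_before += exon[1] - exon[0] + 1
        if model.strand == "+":
            span = (exon[1] + 1, nxt[0] - 1)
        else:
            span = (nxt[1] + 1, exon[0] - 1)
        introns.append(IntronRecord(
            gene=model.id,
            index=idx,
            genomic_span=span,
            phase=cds_before % 3,
            protein_context=(cds_before - 1) // 3,
        ))
    return introns


def protein_to_genome(model: GeneModel, aa_index: int) -> list[tuple[int, int]]:
    """Genomic span(s) of the codon encoding residue ``aa_index``.

    Returns one fragment for a contiguous codon or two when the codon is
    split across an intron; fragments are (start, end) 1-based inclusive
    in genomic orientation.
    """
    cds_len = model.cds_length
    if not 0 <= aa_index < cds_len // 3:
        raise ValidationError(
            f"{model.id}: residue index {aa_index} outside CDS of {cds_len // 3} codons"
        )
    want = set(range(3 * aa_index + model.cds_phase_offset,
                     3 * aa_index + model.cds_phase_offset + 3))
    fragments: list[tuple[int, int]] = []
    cds_pos = 0
    for exon in _translation_order_exons(model):
        length = exon[1] - exon[0] + 1
        hits = sorted(p for p in want if cds_pos <= p < cds_pos + length)
        if hits:
            offs = [p - cds_pos for p in hits]
            if model.strand == "+":
                genomic = [exon[0] + o for o in offs]
            else:
                genomic = [exon[1] - o for o in offs]
            fragments.append((min(genomic), max(genomic)))
        cds_pos += length
    return sorted(fragments)


def type_domain_intron(
    domain: WRKYDomain, model: GeneModel, sequence: str
) -> str:
    """Classify the conserved intron of a WRKY domain: R, V, other or none.

    Considers every intron whose splice boundary falls inside the domain
    span (heptapeptide start through zinc-finger terminal residue).  A
    phase-0 splice immediately after an R codon upstream of the zinc
    finger's first cysteine is R-type; a phase-0 splice immediately
    before the codon six residues after the second cysteine, when that
    residue is V, is V-type; anything else is "other".  The first
    in-domain intron in translation order decides the label.
    """
    n_codons = model.cds_length // 3
    if domain.zf.terminal >= n_codons or len(sequence) < n_codons:
        raise ValidationError(
            f"{model.id}: domain coordinates outside the CDS"
        )
    span_lo = domain.hepta.position
    span_hi = domain.zf.terminal
    for intron in infer_introns(model):
        # residue boundary: splice sits after protein_context (phase 0)
        # or inside the codon of protein_context (phase 1/2)
        boundary = intron.protein_context + (1 if intron.phase == 0 else 0)
        if not (span_lo < boundary <= span_hi):
            continue
        if intron.phase != 0:
            return "other"
        before = intron.protein_context
        if sequence[before] == "R" and before < domain.zf.c1:
            return "R"
        v_index = domain.zf.c2 + 6
        if boundary == v_index and v_index < len(sequence) and sequence[v_index] == "V":
            return "V"
        return "other"
    return "none"
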