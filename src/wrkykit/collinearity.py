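"""Simplified MCscan-style segmental-duplication detection.

Protein-similarity anchors come from Smith-Waterman alignment (BLOSUM62,
gap open 11 / extend 1) with a Karlin-Altschul E-value using fixed
(lambda = 0.267, K = 0.041) and a declared search-space size — a
calibrated proxy for a BLASTP E-value, never compared against published
raw E-values.  Anchors are chained per chromosome pair into collinear
blocks by dynamic programming over gene ranks (ordinal position on the
chromosome, matching MCscan semantics), requiring strictly monotone ranks
on both axes; a block is significant when the product of its anchor
E-values falls below 1e-10.  Family members linked by anchors inside
significant blocks become segmental-duplication events, grouped by
connected components so A-B plus B-C yields one triplet event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ValidationError
from .genome_map import DuplicationEvent
from .io_formats import ProteinRecord

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

DEFAULT_ANCHOR_EMAX = 1e-6
DEFAULT_BLOCK_EMAX = 1e-10
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_RANK_GAP = 25

_MIN_EVALUE = 1e-300  # cap for products near machine minimum


@dataclass(frozen=True)
class GenePosition:
    """Genomic placement of a gene: chromosome plus ordinal rank."""

    chromosome: str
    rank: int


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    score: float
    evalue: float


@dataclass(frozen=True)
class CollinearBlock:
    anchors: tuple[Anchor, ...]
    chromosomes: tuple[str, str]
    orientation: str  # same | inverted
    block_evalue: float

    @property
    def significant(self) -> bool:
        return self.block_evalue < DEFAULT_BLOCK_EMAX


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def local_align(
    a: str, b: str, search_space: float | None = None
) -> tuple[float, float]:
    """Smith-Waterman score and Karlin-Altschul E-value.

    ``search_space`` is m*n; by default the product of the two sequence
    lengths.  E = K * mn * exp(-lambda * S).
    """
    if not a or not b:
        raise ValidationError("local_align requires non-empty sequences")
    score = float(_ALIGNER.score(a, b))
    mn = search_space if search_space is not None else len(a) * len(b)
    evalue = KARLIN_K * mn * math.exp(-KARLIN_LAMBDA * score)
    return score, evalue


def find_anchors(
    proteins: Sequence[ProteinRecord],
    positions: Mapping[str, GenePosition],
    e_max: float = DEFAULT_ANCHOR_EMAX,
) -> list[Anchor]:
    """All unordered protein pairs with E-value below ``e_max``.

    The search space for every comparison is declared as
    n_proteins x total database residues.  Every protein must have a
    genomic position; reciprocal pairs are stored once (a before b in
    input order).
    """
    for rec in proteins:
        if rec.id not in positions:
            raise ValidationError(f"protein {rec.id!r} has no genomic position")
    db_residues = sum(len(rec) for rec in proteins)
    search_space = len(proteins) * db_residues
    anchors = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            score, evalue = local_align(a.sequence, b.sequence, search_space)
            if evalue < e_max:
                anchors.append(Anchor(a.id, b.id, score, evalue))
    return anchors


def _best_chain(
    pts: list[tuple[int, int, int]], direction: int, max_rank_gap: int
) -> list[int]:
    """Longest strictly monotone chain over (rank_a, rank_b, anchor_idx).

    ``direction`` +1 chains rank_b increasing, -1 decreasing; consecutive
    rank gaps on both axes must not exceed ``max_rank_gap``.
    """
    pts = sorted(pts)
    n = len(pts)
    best_len = [1] * n
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            da = pts[i][0] - pts[j][0]
            db = direction * (pts[i][1] - pts[j][1])
            if 0 < da <= max_rank_gap and 0 < db <= max_rank_gap:
                if best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    back[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -i))
    chain = []
    while end != -1:
        chain.append(pts[end][2])
        end = back[end]
    return chain[::-1]


def chain_blocks(
    anchors: Sequence[Anchor],
    positions: Mapping[str, GenePosition],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_rank_gap: int = DEFAULT_MAX_RANK_GAP,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Chains are extracted greedily (best chain first, its anchors removed,
    repeat) in both orientations; chains shorter than ``min_anchors`` are
    discarded.  The block E-value is the product of member anchor
    E-values, capped at 1e-300.
    """
    by_pair: dict[tuple[str, str], list[tuple[Anchor, int, int]]] = defaultdict(list)
    for anc in anchors:
        pa, pb = positions[anc.gene_a], positions[anc.gene_b]
        key = (pa.chromosome, pb.chromosome)
        ra, rb = pa.rank, pb.rank
        if key[0] > key[1]:
            key = (key[1], key[0])
            ra, rb = rb, ra
        by_pair[key].append((anc, ra, rb))

    blocks = []
    for key in sorted(by_pair):
        pool = by_pair[key]
        while True:
            pts = [(ra, rb, idx) for idx, (_, ra, rb) in enumerate(pool)]
            if len(pts) < min_anchors:
                break
            best, orient = [], "same"
            for direction, name in ((1, "same"), (-1, "inverted")):
                chain = _best_chain(pts, direction, max_rank_gap)
                if len(chain) > len(best):
                    best, orient = chain, name
            if len(best) < min_anchors:
                break
            chosen = [pool[i][0] for i in best]
            log_e = sum(math.log(max(a.evalue, _MIN_EVALUE)) for a in chosen)
            block_e = max(math.exp(max(log_e, math.log(_MIN_EVALUE))), _MIN_EVALUE)
            blocks.append(CollinearBlock(tuple(chosen), key, orient, block_e))
            used = set(best)
            pool = [p for i, p in enumerate(pool) if i not in used]
    return blocks


def call_segmental(
    blocks: Sequence[CollinearBlock],
    family_members: Iterable[str],
    positions: Mapping[str, GenePosition] | None = None,
) -> list[DuplicationEvent]:
    """Segmental-duplication events for family members.

    A member qualifies when it sits in an anchor inside a significant
    block whose partner is also a family member; related members are
    merged by connected components (A-B and B-C give one triplet).
    """
    family = set(family_members)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        for g in (x, y):
            parent.setdefault(g, g)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for block in blocks:
        if not block.significant:
            continue
        for anc in block.anchors:
            if anc.gene_a in family and anc.gene_b in family:
                union(anc.gene_a, anc.gene_b)

    groups: dict[str, list[str]] = defaultdict(list)
    for g in parent:
        groups[find(g)].append(g)
    events = []
    for root in sorted(groups):
        members = tuple(sorted(groups[root]))
        if len(members) < 2:
            continue
        chroms = (
            tuple(sorted({positions[m].chromosome for m in members}))
            if positions
            else ()
        )
        events.append(
            DuplicationEvent(kind="segmental", members=members, chromosomes=chroms, span=0)
        )
    return events
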