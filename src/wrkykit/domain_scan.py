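"""WRKY domain detection by motif grammar.

A WRKY domain is the conserved heptapeptide (canonically WRKYGQK) followed
by a metal-chelating zinc finger.  The zinc finger is matched against four
explicit spacing grammars — CX4CX23HXH, CX4CX22HXH, CX5CX23HXH (all C2H2)
and CX7CX23HXC (C2HC) — rather than a profile HMM, which keeps detection
exact and oracle-checkable.  The heptapeptide scan uses one wildcard slot
(WRKYG-X-K) so the known Q->K variant (WRKYGKK) is captured and flagged
rather than filtered.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"
_HEPTA_RE = re.compile(r"WRKYG.K")

#: Grammar name -> (residues between the two Cs, residues between second C
#: and first H, terminal residue).  ``HXH``/``HXC`` means exactly one
#: residue between the two terminal positions.  Listed in matching order:
#: most constrained spacing first; ties broken by this order.
ZF_GRAMMARS: dict[str, tuple[int, int, str]] = {
    "CX4CX23HXH": (4, 23, "H"),
    "CX4CX22HXH": (4, 22, "H"),
    "CX5CX23HXH": (5, 23, "H"),
    "CX7CX23HXC": (7, 23, "C"),
}

#: Default maximum spacing (residues) between heptapeptide end and the
#: zinc finger's first cysteine when pairing the two into a domain.  The
#: full domain is ~60 aa: 7 (heptapeptide) + gap + up to 33 (grammar).
DEFAULT_MAX_PAIR_GAP = 40


@dataclass(frozen=True)
class HeptaMatch:
    """A heptapeptide hit: 0-based position of the W, the matched 7-mer,
    and whether it is the canonical WRKYGQK."""

    position: int
    peptide: str
    canonical: bool


@dataclass(frozen=True)
class ZincFingerMatch:
    """A zinc-finger hit with the four chelating residue indices.

    ``c1``/``c2`` are the cysteines, ``h1`` the first histidine and
    ``terminal`` the last chelator (H for C2H2, C for C2HC).
    """

    c1: int
    c2: int
    h1: int
    terminal: int
    zf_type: str
    grammar: str


@dataclass(frozen=True)
class WRKYDomain:
    """A paired heptapeptide + zinc finger.

    ``terminal_tag`` is N/C for the two domains of a two-domain protein
    (in sequence order) and "single" otherwise.
    """

    hepta: HeptaMatch
    zf: ZincFingerMatch
    terminal_tag: str

    @property
    def zf_type(self) -> str:
        return self.zf.zf_type


def scan_heptapeptide(sequence: str) -> list[HeptaMatch]:
    """Find all non-overlapping WRKYG-X-K matches, left to right.

    The canonical flag is set iff the wildcard slot is Q; the variant
    peptide (e.g. WRKYGKK) is recorded verbatim.
    """
    out = []
    for m in _HEPTA_RE.finditer(sequence):
        pep = m.group(0)
        out.append(HeptaMatch(m.start(), pep, pep == CANONICAL_HEPTAPEPTIDE))
    return out


def match_zinc_finger(sequence: str, start: int = 0) -> ZincFingerMatch | None:
    """Earliest zinc-finger grammar match at or after ``start``.

    At each candidate position the grammars are tried in declaration
    order; the first hit wins.  Returns None when nothing matches.
    """
    n = len(sequence)
    for c1 in range(start, n):
        if sequence[c1] != "C":
            continue
        for grammar, (gap1, gap2, term_res) in ZF_GRAMMARS.items():
            c2 = c1 + gap1 + 1
            h1 = c2 + gap2 + 1
            terminal = h1 + 2
            if terminal >= n:
                continue
            if sequence[c2] == "C" and sequence[h1] == "H" and sequence[terminal] == term_res:
                zf_type = "C2HC" if term_res == "C" else "C2H2"
                return ZincFingerMatch(c1, c2, h1, terminal, zf_type, grammar)
    return None


def scan_domains(
    protein: ProteinRecord, max_pair_gap: int = DEFAULT_MAX_PAIR_GAP
) -> list[WRKYDomain]:
    """Detect complete WRKY domains in a protein.

    Each heptapeptide is paired with the nearest downstream zinc finger
    whose first cysteine starts within ``max_pair_gap`` residues of the
    heptapeptide end; unpaired heptapeptides are dropped with a warning.
    """
    seq = protein.sequence
    pairs: list[tuple[HeptaMatch, ZincFingerMatch]] = []
    for hepta in scan_heptapeptide(seq):
        hepta_end = hepta.position + 7
        zf = match_zinc_finger(seq, hepta_end)
        if zf is None or zf.c1 - hepta_end > max_pair_gap:
            logger.warning(
                "%s: heptapeptide at %d has no zinc finger within %d aa",
                protein.id, hepta.position, max_pair_gap,
            )
            continue
        pairs.append((hepta, zf))
    if len(pairs) == 1:
        tags = ["single"]
    else:
        # first domain is N-terminal, the rest C-terminal by order
        tags = ["N"] + ["C"] * (len(pairs) - 1)
    return [
        WRKYDomain(hepta, zf, tag) for (hepta, zf), tag in zip(pairs, tags)
    ]


def domain_sequences(
    protein: ProteinRecord, max_pair_gap: int = DEFAULT_MAX_PAIR_GAP
) -> list[str]:
    """Subsequences spanning each detected domain (heptapeptide through
    the zinc finger's terminal residue) — the unit the family's
    phylogenetic comparisons operate on."""
    return [
        protein.sequence[d.hepta.position : d.zf.terminal + 1]
        for d in scan_domains(protein, max_pair_gap)
    ]
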