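"""Chromosome localisation and coordinate-based duplication calling.

Tandem duplicates are maximal chains of family genes on one chromosome
whose inter-gene distance (end of the upstream gene to start of the
downstream gene) stays within 100 kb; a gene cluster is three or more
family genes spanning at most 200 kb.  Both rules operate on coordinates
alone — phylogenetic agreement between tandem partners is deliberately
not required (an optional knob enforces same-subgroup chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from typing import Iterable, Sequence

DEFAULT_TANDEM_GAP = 100_000
DEFAULT_CLUSTER_WINDOW = 200_000
DEFAULT_CLUSTER_MIN_GENES = 3


@dataclass(frozen=True)
class DuplicationEvent:
    """A typed duplication call: tandem, cluster or segmental."""

    kind: str
    members: tuple[str, ...]
    chromosomes: tuple[str, ...]
    span: int

    def __post_init__(self) -> None:
        assert self.kind in ("tandem", "cluster", "segmental")


def _sorted_by_chromosome(members) -> dict[str, list]:
    per_chrom: dict[str, list] = defaultdict(list)
    for m in members:
        per_chrom[m.chromosome].append(m)
    for chrom in per_chrom:
        per_chrom[chrom].sort(key=lambda m: (m.start, m.end, m.name))
    return per_chrom


def per_chromosome_counts(members: Iterable) -> dict[str, int]:
    """Family gene count per chromosome (scaffolds counted as themselves)."""
    counts: dict[str, int] = defaultdict(int)
    for m in members:
        counts[m.chromosome] += 1
    return dict(counts)


def find_tandem(
    members: Iterable,
    max_gap: int = DEFAULT_TANDEM_GAP,
    require_same_subgroup: bool = False,
) -> list[DuplicationEvent]:
    """Maximal chains of consecutive family genes within ``max_gap`` bp.

    The inter-gene distance is measured from the end of the upstream gene
    to the start of the downstream one.  Chains of >= 2 genes become
    tandem events; with ``require_same_subgroup`` a chain additionally
    breaks where consecutive genes carry different subgroup labels.
    """
    events = []
    for chrom, genes in sorted(_sorted_by_chromosome(members).items()):
        chain = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            gap = cur.start - prev.end
            same_sub = (
                not require_same_subgroup
                or getattr(prev, "subgroup", None) == getattr(cur, "subgroup", None)
            )
            if gap <= max_gap and same_sub:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    events.append(_event("tandem", chain, chrom))
                chain = [cur]
        if len(chain) >= 2:
            events.append(_event("tandem", chain, chrom))
    return events


def _event(kind: str, chain: Sequence, chrom: str) -> DuplicationEvent:
    return DuplicationEvent(
        kind=kind,
        members=tuple(g.name for g in chain),
        chromosomes=(chrom,),
        span=max(g.end for g in chain) - min(g.start for g in chain) + 1,
    )


def find_clusters(
    members: Iterable,
    window: int = DEFAULT_CLUSTER_WINDOW,
    min_genes: int = DEFAULT_CLUSTER_MIN_GENES,
) -> list[DuplicationEvent]:
    """Maximal same-chromosome runs of >= ``min_genes`` genes whose total
    span (first start to last end) fits within ``window`` bp.

    Maximality is per run: extending a reported run by one gene on either
    side would exceed the window, so two reported clusters may overlap.
    """
    events = []
    for chrom, genes in sorted(_sorted_by_chromosome(members).items()):
        n = len(genes)
        runs = []
        for i in range(n):
            j = i
            while (
                j + 1 < n
                and genes[j + 1].end - genes[i].start + 1 <= window
            ):
                j += 1
            if j - i + 1 >= min_genes:
                runs.append((i, j))
        for i, j in runs:
            contained = any(
                a <= i and j <= b and (a, b) != (i, j) for a, b in runs
            )
            if not contained:
                events.append(_event("cluster", genes[i : j + 1], chrom))
    return events


@dataclass
class DuplicationSummary:
    """Family-level duplication percentages (1 decimal place).

    Counts are summed per list — a gene appearing in both the tandem and
    segmental lists contributes to both, so the involvement percentage is
    the count-sum convention; the set-union involvement is also kept.
    """

    tandem_pct: float
    segmental_pct: float
    monogene_pct: float
    involvement_pct: float
    involvement_pct_union: float
    tandem_genes: int
    segmental_genes: int
    total: int


def duplication_summary(
    tandem_events: Sequence[DuplicationEvent],
    segmental_members: Sequence[str],
    total: int,
) -> DuplicationSummary:
    """Tandem / segmental / monogene percentages of the family."""
    if total < 1:
        raise ValueError("total must be >= 1")
    tandem_genes = [g for ev in tandem_events for g in ev.members]
    n_tandem = len(tandem_genes)
    n_seg = len(segmental_members)
    union = len(set(tandem_genes) | set(segmental_members))
    pct = lambda x: round(100.0 * x / total, 1)
    return DuplicationSummary(
        tandem_pct=pct(n_tandem),
        segmental_pct=pct(n_seg),
        monogene_pct=pct(total - n_tandem - n_seg),
        involvement_pct=pct(n_tandem + n_seg),
        involvement_pct_union=pct(union),
        tandem_genes=n_tandem,
        segmental_genes=n_seg,
        total=total,
    )
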