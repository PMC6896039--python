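"""Group/subgroup classification and protein statistics.

The broad group follows the domain rule used throughout the WRKY
literature: two WRKY domains -> group I; one domain with a C2HC zinc
finger -> group III; one domain with C2H2 -> group II.  Subgroups IIa-e
are refined phylogenetically: a neighbour-joining tree is built from
p-distances on pairwise-aligned domain sequences against labelled
reference proteins, and the query inherits the label of the references in
the smallest clade around it.  A query whose clade references conflict,
or whose nearest reference is too distant, falls back to the IIx label
(an "unplaced group II" bin).

The NJ construction, bootstrap resampling and pairwise aligner are
implemented from scratch with fully specified tie-breaking so results are
bit-reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError, NumericalError, ValidationError
from .domain_scan import WRKYDomain
from .io_formats import FamilyMember

# ---------------------------------------------------------------------------
# Group rule


def classify_group(member_domains: list[WRKYDomain]) -> str:
    """Assign the broad group (I/II/III) from detected domains."""
    zf_types = [d.zf_type for d in member_domains]
    return group_rule(len(member_domains), zf_types)


def group_rule(n_domains: int, zf_types: list[str] | str) -> str:
    """Domain-count + zinc-finger rule shared by scan and table paths.

    Two domains -> I; one domain -> III when the zinc finger is C2HC,
    otherwise II.  Zero or more than two domains cannot be classified
    automatically and raise :class:`ClassificationError`.
    """
    if isinstance(zf_types, str):
        zf_types = [zf_types] * n_domains
    if n_domains == 0:
        raise ClassificationError("no WRKY domain: cannot classify")
    if n_domains > 2:
        raise ClassificationError(
            f"{n_domains} WRKY domains: flagged for manual review"
        )
    if n_domains == 2:
        return "I"
    return "III" if zf_types[0] == "C2HC" else "II"


def classify_member(member: FamilyMember) -> str:
    """Apply the group rule to a curated family-table row."""
    return group_rule(member.domain_number, member.zf_type)


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh, affine gaps)

GAP = "-"


def align_pair(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> tuple[str, str]:
    """Global alignment with affine gaps and deterministic traceback.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``.  Traceback
    ties prefer diagonal over up (gap in ``b``) over left (gap in ``a``),
    which pins down a single optimal alignment.
    """
    if not a or not b:
        raise ValidationError("align_pair requires non-empty sequences")
    n, m = len(a), len(b)
    NEG = float("-inf")
    # Gotoh three-state DP over plain Python lists (fast enough for the
    # ~60-aa domain sequences this package aligns)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            diag = Mp[j - 1]
            if Xp[j - 1] > diag:
                diag = Xp[j - 1]
            if Yp[j - 1] > diag:
                diag = Yp[j - 1]
            Mi[j] = diag + s
            Xi[j] = max(Mp[j] + gap_open, Xp[j] + gap_extend)
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend)
    # traceback; state preference M > X > Y on ties
    i, j = n, m
    state = "M"
    best = M[i][j]
    if X[i][j] > best:
        state, best = "X", X[i][j]
    if Y[i][j] > best:
        state = "Y"
    eps = 1e-9
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i][j] - prev) < eps:
                state = "M"
            elif abs(X[i][j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            came_open = abs(X[i][j] - (M[i - 1][j] + gap_open)) < eps
            i -= 1
            state = "M" if came_open else "X"
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            came_open = abs(Y[i][j] - (M[i][j - 1] + gap_open)) < eps
            j -= 1
            state = "M" if came_open else "Y"
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of mismatched residues over gap-free columns."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences differ in length")
    compared = mismatches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise NumericalError("no gap-free columns: p-distance undefined")
    return mismatches / compared


# ---------------------------------------------------------------------------
# Distance matrix and trees


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValidationError("negative distances")
        self.values = v

    @classmethod
    def from_sequences(cls, named_seqs: list[tuple[str, str]]) -> "DistanceMatrix":
        """p-distance matrix from pairwise global alignments."""
        labels = [name for name, _ in named_seqs]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aa, bb = align_pair(named_seqs[i][1], named_seqs[j][1])
                d[i, j] = d[j, i] = p_distance(aa, bb)
        return cls(labels, d)


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary root (the final NJ join)."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf splits, one per internal edge.

        Each split is canonicalised as the side NOT containing the first
        leaf name (sorted order), so splits compare across rerootings.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        splits = set()
        for node in self.nodes():
            if node is self.root or not node.children:
                continue
            side = frozenset(l.name for l in node.leaves())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""
        by_name = {l.name: l for l in self.root.leaves()}
        if a not in by_name or b not in by_name:
            raise ValidationError(f"leaf not in tree: {a!r} or {b!r}")

        def path_to_root(node: TreeNode) -> list[TreeNode]:
            path = [node]
            while path[-1].parent is not None:
                path.append(path[-1].parent)
            return path

        pa = path_to_root(by_name[a])
        pb = path_to_root(by_name[b])
        in_pb = {id(n) for n in pb}
        lca = next(n for n in pa if id(n) in in_pb)
        dist = 0.0
        for node in pa:
            if node is lca:
                break
            dist += node.length
        for node in pb:
            if node is lca:
                break
            dist += node.length
        return dist


def build_nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining.

    Iteratively joins the pair minimising the Q criterion; branch lengths
    come from the standard two-point formula with negatives clamped to 0.
    Ties are broken by the lowest (i, j) index pair in the current node
    order, making the topology deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise ValidationError("NJ needs at least 2 taxa")
    nodes = [TreeNode(name=lab) for lab in d.labels]
    dist = d.values.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        """Join active nodes i, j with given branch lengths; return new index."""
        ni, nj = nodes[i], nodes[j]
        ni.length = max(0.0, li)
        nj.length = max(0.0, lj)
        new = TreeNode(children=[ni, nj])
        ni.parent = nj.parent = new
        nodes.append(new)
        return len(nodes) - 1

    # matrix indexed by position in `active`
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        new_idx = join(active[i], active[j], li, lj)
        # distances from the new node to the remaining actives
        new_d = np.zeros(len(nodes))
        for k in range(m):
            if k in (i, j):
                continue
            ak = active[k]
            new_d[ak] = 0.5 * (sub[i, k] + sub[j, k] - dij)
        grown = np.zeros((len(nodes), len(nodes)))
        grown[: dist.shape[0], : dist.shape[1]] = dist
        grown[new_idx, :] = new_d
        grown[:, new_idx] = new_d
        dist = grown
        active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [new_idx]

    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
        la = 0.5 * (dab + dac - dbc)
        lb = 0.5 * (dab + dbc - dac)
        lc = 0.5 * (dac + dbc - dab)
        root = TreeNode()
        for idx, length in zip((a, b, c), (la, lb, lc)):
            nodes[idx].length = max(0.0, length)
            nodes[idx].parent = root
            root.children.append(nodes[idx])
    else:
        a, b = active
        half = max(0.0, dist[a, b] / 2)
        root = TreeNode()
        for idx in (a, b):
            nodes[idx].length = half
            nodes[idx].parent = root
            root.children.append(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap

def _distances_from_alignment(names, rows: np.ndarray) -> DistanceMatrix:
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            ok = (a != GAP) & (b != GAP)
            compared = int(ok.sum())
            d[i, j] = d[j, i] = (
                float((a[ok] != b[ok]).sum()) / compared if compared else 0.0
            )
    return DistanceMatrix(list(names), d)


def bootstrap_support(
    alignment: list[tuple[str, str]], n_reps: int, seed: int
) -> PhyloTree:
    """NJ tree with per-edge bootstrap support from column resampling.

    ``alignment`` is a pre-aligned, equal-length set of (name, sequence)
    rows.  For each replicate the columns are resampled with replacement,
    p-distances recomputed and the NJ tree rebuilt; an internal edge's
    support is the percentage of replicates containing its bipartition.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValidationError("bootstrap requires equal-length aligned rows")
    names = [name for name, _ in alignment]
    rows = np.array([list(s) for _, s in alignment])
    n_cols = rows.shape[1]
    tree = build_nj_tree(_distances_from_alignment(names, rows))
    counts: Counter[frozenset[str]] = Counter()
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = build_nj_tree(_distances_from_alignment(names, rows[:, cols]))
        counts.update(rep_tree.bipartitions())
    all_leaves = frozenset(names)
    anchor = min(all_leaves)
    for node in tree.nodes():
        if node is tree.root or not node.children:
            continue
        side = frozenset(l.name for l in node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = 100.0 * counts[side] / n_reps
    return tree


# ---------------------------------------------------------------------------
# Subgroup assignment

DEFAULT_DISTANCE_CEILING = 0.8


def assign_subgroup(
    tree: PhyloTree,
    query: str,
    reference_map: dict[str, str],
    distance_ceiling: float = DEFAULT_DISTANCE_CEILING,
) -> str:
    """Subgroup of a query leaf from its placement among references.

    The label comes from the references in the smallest clade (an
    edge-bounded subtree of the unrooted tree) containing the query and at
    least one reference, provided those references agree.  On conflict, or
    when the nearest reference is farther than ``distance_ceiling`` in
    patristic distance, the unplaced label IIx is returned.
    """
    leaf_names = set(tree.leaf_names)
    if query not in leaf_names:
        raise ValidationError(f"query {query!r} not in tree")
    refs = [r for r in reference_map if r in leaf_names]
    if not refs:
        raise ValidationError("no reference leaves in tree")

    all_leaves = frozenset(tree.leaf_names)
    clades: list[frozenset[str]] = []
    for node in tree.nodes():
        if node is tree.root:
            continue
        side = frozenset(l.name for l in node.leaves())
        clades.append(side)
        clades.append(all_leaves - side)
    candidates = [
        c for c in clades if query in c and any(r in c for r in refs)
    ]
    best = min(candidates, key=lambda c: (len(c), tuple(sorted(c))))
    labels = {reference_map[r] for r in refs if r in best}
    nearest = min(tree.patristic_distance(query, r) for r in refs)
    if len(labels) != 1 or nearest > distance_ceiling:
        return "IIx"
    return labels.pop()


# ---------------------------------------------------------------------------
# Protein statistics

WATER_DA = 18.0153

#: Bjellqvist pKa values used by the ExPASy Compute pI tool.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def protein_mw(sequence: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    from Bio.SeqUtils import molecular_weight

    if not sequence:
        raise ValidationError("empty sequence has no molecular weight")
    if "X" in sequence:
        raise ValidationError("residue X has undefined mass")
    try:
        return molecular_weight(sequence, seq_type="protein") / 1000.0
    except ValueError as exc:  # non-canonical residue
        raise ValidationError(str(exc)) from exc


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    counts = Counter(sequence)
    pos = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    for res in "KRH":
        pos += counts[res] / (1.0 + 10 ** (ph - PKA_POSITIVE[res]))
    neg = 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for res in "DECY":
        neg += counts[res] / (1.0 + 10 ** (PKA_NEGATIVE[res] - ph))
    return pos - neg


def protein_pi(sequence: str, tol: float = 1e-4, max_iter: int = 200) -> float:
    """Isoelectric point by bisection on the net charge.

    Uses the Bjellqvist pKa set (N/C termini plus D, E, C, Y, H, K, R side
    chains) and bisects until |charge| < ``tol``.
    """
    if not sequence:
        raise ValidationError("empty sequence has no pI")
    if set(sequence) - set("ACDEFGHIKLMNPQRSTVWY"):
        raise ValidationError("non-canonical residue in sequence")
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    raise NumericalError("pI bisection did not converge")


# ---------------------------------------------------------------------------
# Family summary


@dataclass
class SummaryStats:
    n_members: int
    group_counts: dict[str, int]
    subgroup_counts: dict[str, int]
    length_range: tuple[int, int]
    mw_range: tuple[float, float]
    pi_range: tuple[float, float]
    n_variant_heptapeptide: int


def family_summary(members: list[FamilyMember]) -> SummaryStats:
    """Counts and ranges over a curated family table."""
    if not members:
        raise ValidationError("empty member list")
    groups = Counter(classify_member(m) for m in members)
    subgroups = Counter(m.subgroup for m in members)
    lengths = [m.protein_length for m in members]
    mws = [m.mw for m in members]
    pis = [m.pi for m in members]
    variants = sum(
        1 for m in members if m.heptapeptide != "WRKYGQK"
    )
    return SummaryStats(
        n_members=len(members),
        group_counts=dict(groups),
        subgroup_counts=dict(subgroups),
        length_range=(min(lengths), max(lengths)),
        mw_range=(min(mws), max(mws)),
        pi_range=(min(pis), max(pis)),
        n_variant_heptapeptide=variants,
    )
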