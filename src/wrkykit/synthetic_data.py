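"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec plus a seed and returns the
generated data together with machine-readable ground truth, so planted
structure (domain positions, tandem arrays, duplicated segments, intron
types, fold changes, relative quantities) can be checked exactly.

Background residues are drawn uniformly from the 17 amino acids excluding
C, H and W, which makes accidental heptapeptide or zinc-finger grammar
matches impossible; an adversarial mode draws from all 20 letters for
robustness checks.  RNA-seq-like counts use negative-binomial noise
(variance m + dispersion * m^2); qPCR tables use Gaussian cycle noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import CtTable, ExpressionMatrix
from .io_formats import GeneModel, ProteinRecord

#: Alphabet for background residues: no C/H (zinc-finger chelators), no W
#: (heptapeptide start).
BACKGROUND_ALPHABET = "ADEFGIKLMNPQRSTVY"
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Zinc-finger grammar used for the single (or C-terminal) domain of each
#: subgroup, following the family's conserved spacing conventions.
SUBGROUP_GRAMMAR = {
    "I": "CX4CX23HXH",      # C-terminal domain; N-terminal may use 22 or 23
    "IIa": "CX5CX23HXH",
    "IIb": "CX5CX23HXH",
    "IIc": "CX4CX23HXH",
    "IId": "CX5CX23HXH",
    "IIe": "CX5CX23HXH",
    "IIx": "CX4CX23HXH",
    "III": "CX7CX23HXC",
}

#: Conserved-intron convention: R-type before the zinc finger in I, IIc,
#: IId, IIe and III; V-type in IIa and IIb.
SUBGROUP_INTRON = {
    "I": "R", "IIc": "R", "IId": "R", "IIe": "R", "III": "R",
    "IIa": "V", "IIb": "V",
}

_GRAMMAR_SPACING = {
    "CX4CX22HXH": (4, 22, "H"),
    "CX4CX23HXH": (4, 23, "H"),
    "CX5CX23HXH": (5, 23, "H"),
    "CX7CX23HXC": (7, 23, "C"),
}


def _bg(rng: np.random.Generator, n: int, alphabet: str = BACKGROUND_ALPHABET) -> str:
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=n)) if n > 0 else ""


def perturb_sequence(
    sequence: str, rate: float, rng: np.random.Generator,
    alphabet: str = BACKGROUND_ALPHABET,
) -> str:
    """Substitute each residue with probability ``rate``."""
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = alphabet[rng.integers(len(alphabet))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Family proteins


@dataclass(frozen=True)
class PlantedDomain:
    hepta_pos: int
    zf_c1: int
    grammar: str
    zf_type: str


@dataclass(frozen=True)
class MemberTruth:
    name: str
    subgroup: str
    variant: bool
    domains: tuple[PlantedDomain, ...]


@dataclass
class FamilySpec:
    """Composition of a synthetic family.

    ``counts`` gives members per subgroup; ``perturbation`` is a global
    residue substitution rate (0-0.3) applied after planting (used for
    phylogenetic experiments, not domain-recovery ones).
    """

    counts: dict[str, int]
    perturbation: float = 0.0
    length_range: tuple[int, int] = (150, 300)
    variant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbation <= 0.3:
            raise ValidationError("perturbation must be in [0, 0.3]")
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("negative member count")


def _zf_string(rng: np.random.Generator, grammar: str, v_at_c2_plus_6: bool = False) -> str:
    gap1, gap2, term = _GRAMMAR_SPACING[grammar]
    inner1 = _bg(rng, gap1)
    inner2 = list(_bg(rng, gap2))
    if v_at_c2_plus_6:
        inner2[5] = "V"  # residue c2 + 6 sits 6 after the second C
    middle = _bg(rng, 1)
    return "C" + inner1 + "C" + "".join(inner2) + "H" + middle + term


def _domain_block(
    rng: np.random.Generator, grammar: str, variant: bool, v_mark: bool = False
) -> tuple[str, int]:
    """Return (block string, zf offset within block)."""
    hepta = "WRKYGKK" if variant else "WRKYGQK"
    gap = int(rng.integers(8, 21))
    zf = _zf_string(rng, grammar, v_at_c2_plus_6=v_mark)
    return hepta + _bg(rng, gap) + zf, 7 + gap


def make_member_sequence(
    rng: np.random.Generator,
    subgroup: str,
    length: int,
    variant: bool = False,
    v_mark: bool = False,
) -> tuple[str, tuple[PlantedDomain, ...]]:
    """One synthetic protein with subgroup-appropriate planted domain(s)."""
    blocks = []
    if subgroup == "I":
        n_grammar = "CX4CX22HXH" if rng.random() < 0.5 else "CX4CX23HXH"
        blocks.append(_domain_block(rng, n_grammar, variant, v_mark=False))
        blocks.append(_domain_block(rng, "CX4CX23HXH", False, v_mark=v_mark))
        grammars = [n_grammar, "CX4CX23HXH"]
    else:
        grammar = SUBGROUP_GRAMMAR[subgroup]
        blocks.append(_domain_block(rng, grammar, variant, v_mark=v_mark))
        grammars = [grammar]
    total_block = sum(len(b) for b, _ in blocks)
    n_spacers = len(blocks) + 1
    slack = length - total_block
    if slack < n_spacers * 4:
        raise ValidationError(
            f"length {length} too short for {subgroup} domain layout"
        )
    cuts = sorted(rng.integers(0, slack + 1, size=n_spacers - 1))
    spacer_lens = (
        [cuts[0]] + [b - a for a, b in zip(cuts, cuts[1:])] + [slack - cuts[-1]]
    )
    seq_parts = []
    domains = []
    pos = 0
    for (block, zf_off), grammar, sp in zip(blocks, grammars, spacer_lens):
        seq_parts.append(_bg(rng, sp))
        pos += sp
        seq_parts.append(block)
        zf_type = "C2HC" if grammar.endswith("C") else "C2H2"
        domains.append(PlantedDomain(pos, pos + zf_off, grammar, zf_type))
        pos += len(block)
    seq_parts.append(_bg(rng, spacer_lens[-1]))
    return "".join(seq_parts), tuple(domains)


def gen_family_proteins(
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], list[MemberTruth]]:
    """Synthetic family proteins with planted domains and ground truth."""
    rng = np.random.default_rng(spec.seed)
    proteins, truths = [], []
    idx = 0
    for subgroup in sorted(spec.counts):
        for _ in range(spec.counts[subgroup]):
            idx += 1
            name = f"SYN{idx:03d}"
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            variant = bool(rng.random() < spec.variant_rate)
            seq, domains = make_member_sequence(rng, subgroup, length, variant)
            if spec.perturbation > 0:
                seq = perturb_sequence(seq, spec.perturbation, rng)
            proteins.append(ProteinRecord(name, seq))
            truths.append(MemberTruth(name, subgroup, variant, domains))
    return proteins, truths


#: Accession -> subgroup for the 12 reference proteins used to anchor
#: subgroup assignment; a best-effort reconstruction shipped as editable
#: configuration (see data/at_refmap.yaml).
REFERENCE_SUBGROUPS = {
    "AEE85928.1": "IId",  # AtWRKY11
    "AAP21276.1": "IIe",  # AtWRKY14
    "AAM78067.1": "IIa",  # AtWRKY18
    "ANM67410.1": "I",    # AtWRKY20
    "AAB63078.1": "IId",  # AtWRKY21
    "ABH04558.1": "IIe",  # AtWRKY27
    "AEE84006.1": "IIc",  # AtWRKY28
    "AEE84546.1": "IIb",  # AtWRKY31
    "AEE82969.1": "III",  # AtWRKY41
    "AEC10646.1": "IIc",  # AtWRKY43
    "ABD57509.1": "I",    # AtWRKY45
    "AAQ62425.1": "IIc",  # AtWRKY49
}


def gen_reference_set(seed: int = 20190911) -> list[tuple[str, str, str]]:
    """Synthetic stand-ins for the 12 reference proteins.

    Returns (accession, subgroup, sequence) triples; sequences are
    independently generated with subgroup-appropriate domain structure.
    They are synthetic — stand-ins for reference proteins whose real
    sequences live in external databases.
    """
    rng = np.random.default_rng(seed)
    out = []
    for accession, subgroup in REFERENCE_SUBGROUPS.items():
        seq, _ = make_member_sequence(rng, subgroup, int(rng.integers(180, 260)))
        out.append((accession, subgroup, seq))
    return out


# ---------------------------------------------------------------------------
# Genome layout


@dataclass(frozen=True)
class Locus:
    """Minimal coordinate record consumed by the duplication rules."""

    name: str
    chromosome: str
    start: int
    end: int
    subgroup: str | None = None


@dataclass(frozen=True)
class GeneTruth:
    name: str
    chromosome: str
    start: int
    end: int
    subgroup: str | None
    intron_type: str  # R | V | none
    domains: tuple[PlantedDomain, ...]


@dataclass
class GenomeTruth:
    genes: dict[str, GeneTruth]
    tandem_arrays: list[tuple[str, ...]]
    segmental_pairs: list[tuple[str, str]]

    @property
    def family_loci(self) -> list[Locus]:
        return [
            Locus(g.name, g.chromosome, g.start, g.end, g.subgroup)
            for g in self.genes.values()
            if g.subgroup is not None
        ]


@dataclass
class GenomeSpec:
    """Layout of a synthetic genome.

    ``tandem_arrays`` holds (chromosome index, array size, (gap lo, gap
    hi)) triples; the array genes are consecutive family members whose
    inter-gene gaps are drawn from the stated range.  ``segment`` plants
    a duplicated run of genes: (source chromosome index, destination
    chromosome index, number of genes, per-residue divergence).
    ``family_fraction`` of the non-array genes carry a WRKY domain.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 12
    background_gap: tuple[int, int] = (150_000, 400_000)
    tandem_arrays: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    segment: tuple[int, int, int, float] | None = None
    family_fraction: float = 0.6
    length_range: tuple[int, int] = (120, 220)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment is not None and self.segment[3] > 0.3:
            raise ValidationError("segment divergence must be <= 0.3")
        for chrom_idx, size, _ in self.tandem_arrays:
            if chrom_idx >= self.n_chromosomes or size < 2:
                raise ValidationError("invalid tandem array spec")


_SINGLE_SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe", "III")


def _build_model(
    rng: np.random.Generator,
    name: str,
    chrom: str,
    start: int,
    protein_len: int,
    intron_boundary: int | None,
) -> GeneModel:
    """Gene model with an optional phase-0 intron after ``intron_boundary``
    codons (in translation order), strand chosen at random."""
    strand = "+" if rng.random() < 0.5 else "-"
    total = 3 * protein_len
    if intron_boundary is None:
        exons = [(start, start + total - 1)]
    else:
        ilen = int(rng.integers(100, 501))
        first = 3 * intron_boundary  # bases before the splice, translation order
        second = total - first
        if strand == "+":
            exons = [
                (start, start + first - 1),
                (start + first + ilen, start + total + ilen - 1),
            ]
        else:
            exons = [
                (start, start + second - 1),
                (start + second + ilen, start + total + ilen - 1),
            ]
    return GeneModel(id=name, chromosome=chrom, strand=strand, exons=exons)


def _plan_gene(
    rng: np.random.Generator, spec: GenomeSpec, name: str, family: bool
) -> tuple[str, tuple[PlantedDomain, ...], str | None, str, int | None]:
    """Plan sequence + intron for one gene.

    Returns (sequence, domains, subgroup, intron_type, intron_boundary).
    """
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    if not family:
        seq = _bg(rng, length)
        boundary = 2 if length > 4 else None
        return seq, (), None, "none", boundary
    subgroup = _SINGLE_SUBGROUPS[rng.integers(len(_SINGLE_SUBGROUPS))]
    itype = SUBGROUP_INTRON[subgroup]
    seq, domains = make_member_sequence(
        rng, subgroup, length, v_mark=(itype == "V")
    )
    dom = domains[0]
    if itype == "R":
        boundary = dom.hepta_pos + 2  # splice right after the heptapeptide R
    else:
        c2 = dom.zf_c1 + _GRAMMAR_SPACING[dom.grammar][0] + 1
        boundary = c2 + 6  # splice right before the conserved V codon
    return seq, domains, subgroup, itype, boundary


def gen_genome_layout(
    spec: GenomeSpec,
) -> tuple[list[GeneModel], list[ProteinRecord], GenomeTruth]:
    """Synthetic genome: gene models, proteome and planted-event truth."""
    rng = np.random.default_rng(spec.seed)
    models: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    genes: dict[str, GeneTruth] = {}
    tandem_truth: list[tuple[str, ...]] = []
    segmental_pairs: list[tuple[str, str]] = []
    counter = 0

    plans: dict[int, list[dict]] = {c: [] for c in range(spec.n_chromosomes)}
    for c in range(spec.n_chromosomes):
        for _ in range(spec.genes_per_chromosome):
            counter += 1
            family = bool(rng.random() < spec.family_fraction)
            plans[c].append({"name": f"G{counter:04d}", "family": family, "gap": None})
    for chrom_idx, size, gap_range in spec.tandem_arrays:
        slot = int(rng.integers(0, len(plans[chrom_idx]) + 1))
        array_names = []
        entries = []
        for k in range(size):
            counter += 1
            name = f"G{counter:04d}"
            array_names.append(name)
            gap = None if k == 0 else int(rng.integers(gap_range[0], gap_range[1] + 1))
            entries.append({"name": name, "family": True, "gap": gap})
        plans[chrom_idx][slot:slot] = entries
        tandem_truth.append(tuple(array_names))

    seg_source: list[str] = []
    if spec.segment is not None:
        src, _, n_genes, _ = spec.segment
        fam_slots = [p["name"] for p in plans[src]]
        if n_genes > len(fam_slots):
            raise ValidationError("segment longer than source chromosome")
        start_slot = int(rng.integers(0, len(fam_slots) - n_genes + 1))
        seg_source = fam_slots[start_slot : start_slot + n_genes]

    seg_copies: list[dict] = []
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(50_000, 150_000))
        for plan in plans[c]:
            seq, domains, subgroup, itype, boundary = _plan_gene(
                rng, spec, plan["name"], plan["family"]
            )
            gap = plan["gap"]
            if gap is None:
                gap = int(rng.integers(*spec.background_gap))
            start = pos + gap
            model = _build_model(rng, plan["name"], chrom, start, len(seq), boundary)
            end = max(e for _, e in model.exons)
            pos = end
            models.append(model)
            proteins.append(ProteinRecord(plan["name"], seq))
            genes[plan["name"]] = GeneTruth(
                plan["name"], chrom, start, end, subgroup, itype, domains
            )
            if plan["name"] in seg_source:
                seg_copies.append({
                    "orig": plan["name"], "seq": seq, "subgroup": subgroup,
                    "domains": domains, "itype": itype, "boundary": boundary,
                })

    if spec.segment is not None and seg_copies:
        _, dst, _, divergence = spec.segment
        chrom = f"chr{dst + 1}"
        existing = [g for g in genes.values() if g.chromosome == chrom]
        pos = max((g.end for g in existing), default=100_000)
        for copy in seg_copies:
            counter += 1
            name = f"G{counter:04d}"
            seq = perturb_sequence(copy["seq"], divergence, rng, FULL_ALPHABET)
            gap = int(rng.integers(*spec.background_gap))
            start = pos + gap
            model = _build_model(rng, name, chrom, start, len(seq), copy["boundary"])
            end = max(e for _, e in model.exons)
            pos = end
            models.append(model)
            proteins.append(ProteinRecord(name, seq))
            genes[name] = GeneTruth(
                name, chrom, start, end, copy["subgroup"], copy["itype"], copy["domains"]
            )
            if copy["subgroup"] is not None:
                segmental_pairs.append((copy["orig"], name))

    return models, proteins, GenomeTruth(genes, tandem_truth, segmental_pairs)


# ---------------------------------------------------------------------------
# Expression data


def gen_expression_data(
    n_genes: int,
    effects: dict[str, float] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    conditions: tuple[str, ...] = ("before", "after"),
    baseline_range: tuple[float, float] = (20.0, 500.0),
    length_range: tuple[int, int] = (600, 3000),
) -> tuple[ExpressionMatrix, dict[str, int], pd.DataFrame]:
    """Negative-binomial count matrix with planted fold changes.

    ``effects`` maps gene name -> multiplier applied to every condition
    after the first (the baseline).  Returns (counts, gene lengths,
    truth) where truth has per-gene effect and direction labels
    ("up" when effect >= 2, "down" when <= 0.5, else "flat").
    """
    rng = np.random.default_rng(seed)
    names = [f"G{i + 1:04d}" for i in range(n_genes)]
    effects = effects or {}
    unknown = set(effects) - set(names)
    if unknown:
        raise ValidationError(f"effects for unknown genes: {sorted(unknown)[:5]}")
    base = rng.uniform(*baseline_range, size=n_genes)
    lengths = {g: int(rng.integers(*length_range)) for g in names}
    n = 1.0 / dispersion
    data = {}
    for k, cond in enumerate(conditions):
        means = np.array([
            base[i] * (effects.get(g, 1.0) if k > 0 else 1.0)
            for i, g in enumerate(names)
        ])
        p = n / (n + means)
        data[cond] = rng.negative_binomial(n, p)
    counts = pd.DataFrame(data, index=names)
    truth = pd.DataFrame({
        "gene": names,
        "effect": [effects.get(g, 1.0) for g in names],
    })
    truth["direction"] = np.where(
        truth["effect"] >= 2.0, "up", np.where(truth["effect"] <= 0.5, "down", "flat")
    )
    return ExpressionMatrix(counts, kind="counts"), lengths, truth


# ---------------------------------------------------------------------------
# qPCR data


def gen_ct_data(
    genes: list[str],
    samples: list[str],
    planted_rq: dict[tuple[str, str], float],
    replicate_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "Actin",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> CtTable:
    """Ct table with planted relative quantities.

    The reference gene cycles around ``reference_ct`` in every sample;
    a target's Ct is ``base_ct - log2(RQ)`` plus Gaussian noise, with the
    first sample as calibrator (its planted RQ should be 1).
    """
    rng = np.random.default_rng(seed)
    for (g, s), rq in planted_rq.items():
        if rq <= 0:
            raise ValidationError(f"planted RQ must be > 0 ({g}, {s})")
    rows = []
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            rows.append({
                "gene": reference_gene, "sample": sample, "replicate": rep,
                "ct": reference_ct + rng.normal(0.0, replicate_sd),
            })
        for gene in genes:
            rq = planted_rq.get((gene, sample), 1.0)
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "gene": gene, "sample": sample, "replicate": rep,
                    "ct": base_ct - np.log2(rq) + rng.normal(0.0, replicate_sd),
                })
    return CtTable(
        data=pd.DataFrame(rows),
        reference_gene=reference_gene,
        calibrator_sample=samples[0],
    )
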