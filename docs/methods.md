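# Methods

This note records the models behind each pipeline stage, the parameters
that matter, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Domain model

A WRKY domain is detected as a heptapeptide match followed by a
zinc-finger grammar match:

- **Heptapeptide.** The scan pattern is `WRKYG-X-K` with one wildcard
  slot, because the known natural variant (WRKYGKK) is a point
  substitution at the Q position. Canonicality is recorded as a flag,
  never used as a filter; unrelated 7-mers are still rejected by the six
  fixed positions.
- **Zinc finger.** Four explicit spacing grammars are matched, tried in
  the order CX4CX23HXH, CX4CX22HXH, CX5CX23HXH, CX7CX23HXC at each
  candidate position; the earliest position wins and, within a position,
  the first grammar in that order. `HXH`/`HXC` means exactly one residue
  between the last two chelators. Grammars ending in C define the C2HC
  type found in group III; the others are C2H2.
- **Pairing.** A heptapeptide pairs with the nearest downstream zinc
  finger whose first cysteine starts within `max_pair_gap` residues of
  the heptapeptide end. The default is **40 aa** (config-overridable):
  the full domain is ~60 aa, and 7 (heptapeptide) + 40 (gap ceiling) +
  33 (longest grammar) brackets that comfortably. Sources describing the
  family do not state the spacing ceiling they used; 40 is this
  package's choice. Unpaired heptapeptides are dropped with a warning.

Profile-HMM scoring is deliberately out of scope: the grammar scanner is
exact, fully specified, and oracle-checkable.

## Classification

The broad group is a deterministic rule — two domains → I; one domain
with C2HC → III; one with C2H2 → II. Zero or more than two domains raise
an error for manual review.

Subgroups IIa–e come from a neighbour-joining tree of domain sequences:

- **Alignment.** Global Gotoh alignment with match +1, mismatch 0, gap
  open −5, gap extend −1 (a gap of length k costs −5 −(k−1)). Traceback
  ties are resolved diagonal > up > left, pinning a single optimum so
  distances are bit-reproducible.
- **Distance.** p-distance (mismatches over gap-free columns). It is the
  common default for NJ on protein domains and the simplest model to
  verify independently; an undefined distance (no comparable columns) is
  an error rather than a silent zero.
- **NJ.** Saitou–Nei with the Q criterion; ties broken by the lowest
  (i, j) pair in current node order; negative branch lengths clamped
  to 0. On additive matrices the implementation reproduces the
  generating topology, verified in tests against exhaustive topology
  enumeration with least-squares scoring (up to 7 taxa) and
  cross-checked against scikit-bio's NJ.
- **Bootstrap.** Columns of a pre-aligned, equal-length matrix are
  resampled with replacement; support is the percentage of replicates
  containing each original bipartition. The MSA is an input: published
  family surveys rarely state their alignment parameters, so the package
  does not pretend to reproduce any particular program's alignment.
- **Subgroup rule.** The query inherits the label of the references in
  the smallest edge-bounded clade containing it and at least one
  reference, provided those references agree and the nearest reference
  is within a patristic-distance ceiling (default **0.8**, roughly the
  p-distance between unrelated domains being 0.9+). Conflict or
  excessive distance yields the unplaced label IIx — mirroring how
  surveys handle members that refuse to join any subgroup clade.
- **References.** The packaged reference FASTA
  (`data/at_refs_synthetic.faa`) contains *synthetic* stand-ins keyed by
  the accessions of twelve Arabidopsis WRKY proteins, because the real
  sequences live in external databases; the accession → subgroup map
  (`data/at_refmap.yaml`) is an editable best-effort reconstruction.
  Swap in real sequences for production use; all code paths are
  indifferent to the substitution.

Molecular weight sums average residue masses plus one water (reported in
kDa); X is an error, not a guess. The isoelectric point bisects the
Henderson–Hasselbalch net charge over N/C termini and D, E, C, Y, H, K,
R with the Bjellqvist pKa set (the set behind ExPASy's Compute pI) to
|charge| < 1e−4. Per-gene MW/pI replication against the curated table is
best-effort only — the underlying protein sequences are not part of the
table — so the table's printed values are treated as data, not as a
target the calculators must hit.

## Duplication rules

- **Tandem**: maximal chains of consecutive family genes on one
  chromosome with end-to-start distance ≤ **100 kb**. Start-to-start
  would reproduce the same nine genes on the curated table; end-to-start
  is the stricter reading of "within 100 kb" between genes. Phylogenetic
  agreement between partners is *not* required — the curated table
  prints a tandem pair whose members sit in different subgroups (IIc and
  IIe) — but `--require-same-subgroup` exposes the stricter variant.
- **Cluster**: ≥3 family genes spanning ≤ **200 kb**, reported as all
  maximal runs (extending a reported run one gene either way would break
  the window); overlapping maximal runs are therefore all reported.
- **Summary percentages** use the count-sum convention (a gene in both
  the tandem and segmental lists contributes to both), which is how the
  published 27.6% involvement figure arises from 9 + 7 of 58; the
  set-union percentage is also computed and carried alongside.

## Collinearity

Anchors are Smith–Waterman alignments (BLOSUM62, gap open 11 / extend 1)
with a Karlin–Altschul E-value using fixed λ = 0.267, K = 0.041 and a
declared search space of n_proteins × total database residues. This is a
calibrated proxy for BLASTP, adequate for thresholding at E < 1e−6;
raw E-values are never compared against published ones. Blocks chain
anchors per chromosome pair by dynamic programming over gene ranks
(ordinal position on the chromosome — MCscan semantics, insensitive to
bp scale) requiring strict monotonicity on both axes, consecutive rank
gaps ≤ **25**, and ≥ **5** anchors (both config knobs; common MCscan
practice). Block significance multiplies member anchor E-values and
thresholds at 1e−10. Family members joined by anchors inside significant
blocks are merged into events by connected components, so A–B plus B–C
yields one triplet event.

## Gene structure

Introns are the gaps between CDS exons; phases are computed in
translation order (reversed exon order on the minus strand). Typing of
the conserved domain introns:

- **R-type**: phase-0 splice immediately after a codon encoding R that
  lies upstream of the zinc finger's first cysteine. Any such R
  qualifies (the heptapeptide's own R included); splices that split an R
  codon (phase 1/2) are classified "other" rather than guessed.
- **V-type**: phase-0 splice immediately before the codon of the residue
  six positions after the zinc finger's second cysteine, when that
  residue is V (0-based arithmetic: the splice sits between residues
  c2+5 and c2+6).
- No intron inside the domain span → "none"; anything else → "other".

The generators follow the family convention — R-type in subgroups I,
IIc, IId, IIe, III; V-type in IIa and IIb — and typing recovers 100% of
planted types over 300 seeded models, both strands.

## Expression and qPCR

- RPKM = count × 1e9 / (length × column total).
- Heatmap transform: value → log10(25 × RPKM + 1). The +1 pseudocount
  makes undetected genes map exactly to 0; the alternative reading
  (log10(25x) with a floor) is config-overridable.
- Two-fold filter: FC = (after + 1)/(before + 1) on RPKM (pseudocount 1
  because zero-expression denominators must be handled somehow), up at
  FC ≥ 2, down at FC ≤ 0.5. Under negative-binomial noise at dispersion
  0.1 the log-ratio noise sd is ≈0.45, so a planted 3-fold effect sits
  only ~1.5 sd from the threshold: simulation gives a median recovery of
  14 of 17 planted genes over 50 seeds, with exact recovery in the
  low-noise regime (dispersion 0.001). Two-fold filtering on noisy
  before/after designs without replicates is intrinsically blunt; the
  tests document that honestly rather than assuming it away.
- Clustering: agglomerative, Euclidean distance, average linkage, cut to
  k = 6 — the common heatmap default; the linkage behind published
  heatmaps is rarely stated.
- qPCR: mean Ct per (gene, sample), ΔCt against the reference gene,
  ΔΔCt against the calibrator sample, RQ = 2^−ΔΔCt; replicate scatter is
  propagated as the standard error of ΔCt and reported alongside. The
  calibrator's RQ is exactly 1 by construction. With 3 replicates and
  0.2-cycle noise, log2 RQ is recovered within 0.5 in ≥95% of 1,000
  seeded trials.

## Synthetic data: what it shows and what it does not

Generators are pure functions of spec + seed (byte-identical reruns).
Background residues exclude C, H and W so that planted motifs are the
only grammar matches — unit tests therefore measure the scanner's
agreement with the planted truth, not its false-positive rate on real
proteomes (an adversarial full-alphabet mode exists for robustness
checks). Genome layouts draw background inter-gene gaps from 150–400 kb
so that planted tandem arrays are the only sub-100-kb structure; real
gene spacing is burstier. Expression counts are negative-binomial with a
single dispersion and no batch structure; Ct noise is Gaussian and
homoscedastic. Passing these tests shows the rules and estimators are
implemented correctly under their own assumptions; it does not certify
performance on real RNA-seq or real genome annotations.

Problem sizes used by the test suite: 1,000 proteins for domain
recovery, additive matrices of 4–7 taxa against the exhaustive topology
oracle, 500 subgroup queries at 5–15% perturbation, 500 genome layouts
for the coordinate rules, 200 genomes (segments of 8–15 genes at 5–20%
divergence) for segmental recovery, 300 models for intron typing and
1,000 qPCR trials — sizes chosen so the whole suite runs in about a
minute on one core while keeping every rate estimate stable to a couple
of percentage points.

## Known limitations

- Segmental-duplication calls on the real *P. mume* genome would require
  the full proteome and annotation (external data); the packaged survey
  reproduces the published tandem/cluster/percentage arithmetic exactly
  but exercises collinearity only on synthetic genomes.
- The E-value calibration is not NCBI-BLAST-exact (fixed λ, K; no
  composition adjustment, no gapped-statistics refit).
- The NJ stage does not attempt to reproduce any published tree figure —
  alignment programs and substitution models behind such figures are
  underdetermined — only topology-level recovery on planted data is
  claimed.
- The curated table carries one internal inconsistency: its minimum pI
  column value is 4.90 while the narrative range starts at 4.92. The
  package reports what the table contains.
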