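"""Expression-matrix processing and qPCR relative quantification.

RPKM normalisation, the heatmap transform log10(25 * RPKM + 1) (so
undetected genes map exactly to 0), two-fold up/down candidate filtering
with a pseudocount of 1 RPKM, average-linkage hierarchical clustering of
expression profiles, and 2^-ddCt relative quantification against a
reference gene and calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ValidationError

HEAT_SCALE = 25.0
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_FC_PSEUDOCOUNT = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix tagged with its unit kind."""

    values: pd.DataFrame
    kind: str = "counts"  # counts | rpkm | heat

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def compute_rpkm(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    RPKM = count * 1e9 / (gene length in bp * column library size).
    """
    if counts.kind != "counts":
        raise ValidationError("compute_rpkm expects a counts matrix")
    df = counts.values
    missing = set(df.index) - set(lengths)
    if missing:
        raise ValidationError(f"missing gene lengths: {sorted(missing)[:5]}")
    lens = pd.Series({g: lengths[g] for g in df.index}, dtype=float)
    if (lens <= 0).any():
        raise ValidationError("gene lengths must be positive")
    totals = df.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("zero column total: RPKM undefined")
    rpkm = df * 1e9
    rpkm = rpkm.div(lens, axis=0).div(totals, axis=1)
    return ExpressionMatrix(rpkm, kind="rpkm")


def heat_normalize(rpkm: ExpressionMatrix) -> ExpressionMatrix:
    """Heatmap transform: value -> log10(25 * RPKM + 1); zeros stay 0."""
    if rpkm.kind != "rpkm":
        raise ValidationError("heat_normalize expects an RPKM matrix")
    if (rpkm.values.to_numpy() < 0).any():
        raise ValidationError("negative RPKM")
    return ExpressionMatrix(np.log10(HEAT_SCALE * rpkm.values + 1.0), kind="heat")


def fold_change_candidates(
    before: pd.Series,
    after: pd.Series,
    threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_FC_PSEUDOCOUNT,
) -> tuple[list[str], list[str]]:
    """Two-fold (by default) up/down candidate lists.

    FC = (after + p) / (before + p) on RPKM with pseudocount p; a gene is
    up when FC >= threshold and down when FC <= 1/threshold.
    """
    before, after = before.align(after, join="inner")
    fc = (after + pseudocount) / (before + pseudocount)
    up = sorted(fc.index[fc >= threshold])
    down = sorted(fc.index[fc <= 1.0 / threshold])
    return up, down


def hcluster_genes(matrix: ExpressionMatrix, k: int = 6) -> dict[str, int]:
    """Agglomerative clustering of gene rows (Euclidean, average linkage),
    cut to ``k`` clusters.  Deterministic given input order."""
    genes = matrix.genes
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds {len(genes)} genes")
    Z = linkage(matrix.values.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return {g: int(lab) for g, lab in zip(genes, labels)}


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class CtTable:
    """Long-format Ct table: one row per (gene, sample, replicate).

    ``reference_gene`` is the internal control (e.g. Actin) and
    ``calibrator_sample`` the baseline condition (e.g. the 0 h time
    point) whose relative quantity is 1 by definition.
    """

    data: pd.DataFrame  # columns: gene, sample, replicate, ct
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct"}
        if not required <= set(self.data.columns):
            raise ValidationError(f"Ct table needs columns {sorted(required)}")
        samples = set(self.data["sample"])
        ref_samples = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "sample"]
        )
        if samples - ref_samples:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} missing in sample(s) "
                f"{sorted(samples - ref_samples)}"
            )
        if self.calibrator_sample not in samples:
            raise ValidationError(
                f"calibrator sample {self.calibrator_sample!r} not present"
            )


def relative_expression(ct: CtTable) -> pd.DataFrame:
    """2^-ddCt relative quantification.

    Per (gene, sample): dCt = mean Ct(gene) - mean Ct(reference);
    ddCt = dCt(sample) - dCt(calibrator); RQ = 2^-ddCt.  Replicate
    scatter is propagated as sd(dCt) = sqrt(se_gene^2 + se_ref^2) and
    reported alongside.  Returns a tidy frame with columns gene, sample,
    rq, log2_rq, sd_dct.
    """
    agg = ct.data.groupby(["gene", "sample"])["ct"].agg(["mean", "std", "count"])
    agg["std"] = agg["std"].fillna(0.0)
    ref = agg.loc[ct.reference_gene]
    rows = []
    for gene in agg.index.get_level_values("gene").unique():
        if gene == ct.reference_gene:
            continue
        sub = agg.loc[gene]
        if ct.calibrator_sample not in sub.index:
            raise ValidationError(
                f"{gene}: calibrator sample {ct.calibrator_sample!r} missing"
            )
        dct = sub["mean"] - ref.loc[sub.index, "mean"]
        dct_cal = dct.loc[ct.calibrator_sample]
        se = np.sqrt(
            sub["std"] ** 2 / sub["count"]
            + ref.loc[sub.index, "std"] ** 2 / ref.loc[sub.index, "count"]
        )
        for sample in sub.index:
            ddct = dct.loc[sample] - dct_cal
            rows.append({
                "gene": gene,
                "sample": sample,
                "rq": 2.0 ** (-ddct),
                "log2_rq": -ddct,
                "sd_dct": float(se.loc[sample]),
            })
    return pd.DataFrame(rows)
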