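"""RNA-seq normalization, signature scoring and paired fold changes.

Counts are normalized to RPKM = count × 1e9 / (gene length in bp × library
size); signature scores are geometric means of RPKM over the member genes
(e.g. the 6-gene IFN-γ signature IDO1, CXCL10, CXCL9, HLA-DRA, STAT1, IFNG,
or a 44-gene STING-pathway list). Fold changes are computed per participant
between the on-treatment and baseline samples on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, PairedDesign

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDefinition",
    "IFN_GAMMA_SIGNATURE",
    "ExpressionMatrix",
    "rpkm",
    "signature_score",
    "paired_fold_change",
    "paired_signature_fold_change",
    "paired_gene_test",
    "m1_m2_ratio",
    "set_upregulation_count",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene set used for geometric-mean signature scoring."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate symbols")

    def present_in(self, expr: "ExpressionMatrix") -> list:
        return [g for g in self.genes if g in expr.rpkm.index]


#: The 6-gene IFN-γ signaling signature used for molecular-responder scoring.
IFN_GAMMA_SIGNATURE = SignatureDefinition(
    "IFN_gamma", ("IDO1", "CXCL10", "CXCL9", "HLA-DRA", "STAT1", "IFNG")
)


@dataclass
class ExpressionMatrix:
    """Gene × sample RPKM with a lazily derived log2 view."""

    rpkm: pd.DataFrame
    pseudocount: float = 1.0
    log2rpkm: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("RPKM must be non-negative")
        self.log2rpkm = np.log2(self.rpkm + self.pseudocount)


def rpkm(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count × 1e9 / (length_bp × library_size); the log2 view is
    log2(RPKM + pseudocount).
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        bad = counts.counts.columns[lib == 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    vals = counts.counts.to_numpy(dtype=float) * 1e9 / (
        counts.lengths.to_numpy(dtype=float)[:, None] * lib[None, :]
    )
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns),
        pseudocount=pseudocount,
    )


def signature_score(expr: ExpressionMatrix, sig: SignatureDefinition, offset: float = 0.1) -> pd.Series:
    """Geometric mean of RPKM (+ offset) over the signature genes, per sample.

    Missing genes are logged and skipped; an error is raised when no
    signature gene is present in the expression matrix.
    """
    present = sig.present_in(expr)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in expression matrix")
    missing = set(sig.genes) - set(present)
    if missing:
        logger.warning("signature %s: %d genes absent from expression matrix", sig.name, len(missing))
    x = expr.rpkm.loc[present].to_numpy(dtype=float) + offset
    score = np.exp(np.log(x).mean(axis=0))
    return pd.Series(score, index=expr.rpkm.columns, name=sig.name)


def paired_fold_change(
    expr: ExpressionMatrix, design: PairedDesign, offset: float = 0.1
) -> pd.DataFrame:
    """Per-gene, per-participant linear fold change
    (on-treatment RPKM + offset) / (baseline RPKM + offset)."""
    base = expr.rpkm[design.baseline_samples].to_numpy(dtype=float) + offset
    on = expr.rpkm[design.on_treatment_samples].to_numpy(dtype=float) + offset
    out = pd.DataFrame(on / base, index=expr.rpkm.index, columns=design.participants)
    out.index.name = "gene"
    out.columns.name = "participant"
    return out


def paired_signature_fold_change(
    expr: ExpressionMatrix, sig: SignatureDefinition, design: PairedDesign, offset: float = 0.1
) -> pd.Series:
    """Per-participant fold change of the signature score (ratio of
    on-treatment to baseline geometric-mean scores)."""
    score = signature_score(expr, sig, offset=offset)
    base = score[design.baseline_samples].to_numpy()
    on = score[design.on_treatment_samples].to_numpy()
    return pd.Series(on / base, index=pd.Index(design.participants, name="participant"), name=sig.name)


def paired_gene_test(expr: ExpressionMatrix, design: PairedDesign) -> pd.DataFrame:
    """Per-gene paired t test on log2RPKM across participants.

    Returns log2 fold change (mean paired difference), t statistic and
    two-sided p; used as the gene ranking fed to enrichment.
    """
    base = expr.log2rpkm[design.baseline_samples].to_numpy(dtype=float)
    on = expr.log2rpkm[design.on_treatment_samples].to_numpy(dtype=float)
    d = on - base
    n = d.shape[1]
    mean_d = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(sd == 0, 1.0, p)
    return pd.DataFrame(
        {"log2_fc": mean_d, "statistic": np.where(sd == 0, 0.0, t), "p_value": p},
        index=expr.rpkm.index,
    )


def m1_m2_ratio(
    expr: ExpressionMatrix,
    m1: SignatureDefinition,
    m2: SignatureDefinition,
    design: PairedDesign | None = None,
    offset: float = 0.1,
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Per-sample M1/M2 macrophage polarization ratio (ratio of geometric-mean
    signature scores); when a design is given, also the per-participant paired
    fold change of that ratio."""
    ratio = signature_score(expr, m1, offset=offset) / signature_score(expr, m2, offset=offset)
    ratio.name = f"{m1.name}/{m2.name}"
    if design is None:
        return ratio
    base = ratio[design.baseline_samples].to_numpy()
    on = ratio[design.on_treatment_samples].to_numpy()
    fc = pd.Series(on / base, index=pd.Index(design.participants, name="participant"), name="ratio_fc")
    return ratio, fc


def set_upregulation_count(
    fc: pd.DataFrame, sig: SignatureDefinition, fc_cut: float = 2.0
) -> pd.DataFrame:
    """Per-participant count of signature genes with fold change strictly
    above ``fc_cut``, plus the mean fold change over the set."""
    present = [g for g in sig.genes if g in fc.index]
    if not present:
        logger.warning("set %s has empty intersection with the fold-change table", sig.name)
        zero = pd.DataFrame(
            {"n_upregulated": 0, "mean_fc": np.nan}, index=pd.Index(fc.columns, name="participant")
        )
        return zero
    sub = fc.loc[present]
    return pd.DataFrame(
        {"n_upregulated": (sub > fc_cut).sum(axis=0).astype(int), "mean_fc": sub.mean(axis=0)},
        index=pd.Index(fc.columns, name="participant"),
    )
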