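"""Trial molecular endpoints and clinical summaries.

The endpoint rules implemented here are deliberately simple, printed
predicates:

* **Molecular responder** — participant with a strictly >2-fold on-treatment
  increase in both the IFN-γ signature score and CD274 (PD-L1) expression.
* **Biologically effective dose (BED)** — a dose level achieving at least a
  10% decrease in the molecular marker from baseline to the week-8 biopsy in
  at least 50% of its participants (both thresholds inclusive).
* **TSG reversal** — a tumor-hypermethylated tumor-suppressor gene whose
  promoter methylation dropped by strictly more than 25% (Δβ < −0.25) with a
  strictly >2-fold expression increase on treatment.
* **NLR** — absolute neutrophils / absolute lymphocytes.
* **H-score** — IHC intensity-weighted percentage score,
  1×(%1) + 2×(%2) + 3×(%3), range 0–300.

Plus the supporting statistics: an exact two-sided Wilcoxon rank-sum test by
full enumeration of the permutation distribution (midranks for ties), and
Kaplan-Meier survival summaries with Greenwood/log-log confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sp_stats

logger = logging.getLogger(__name__)

__all__ = [
    "call_molecular_responders",
    "assess_bed",
    "tsg_hyper_dmps",
    "tsg_reversal",
    "nlr",
    "nlr_cohort_summary",
    "h_score",
    "wilcoxon_exact",
    "km_curve",
]


# ---------------------------------------------------------------------------
# Molecular responders
# ---------------------------------------------------------------------------

def call_molecular_responders(
    ifng_fc: pd.Series,
    cd274_fc: pd.Series,
    fc_cut: float = 2.0,
    require_both: bool = True,
) -> pd.DataFrame:
    """Classify participants as molecular responders.

    Default rule: strictly > ``fc_cut`` fold change in *both* the IFN-γ
    signature score and CD274 expression (configurable to either-or).
    """
    df = pd.DataFrame({"ifng_fc": ifng_fc, "cd274_fc": cd274_fc})
    if df.isna().any().any():
        missing = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing fold changes for participants {missing}")
    up_i = df["ifng_fc"] > fc_cut
    up_c = df["cd274_fc"] > fc_cut
    df["responder"] = (up_i & up_c) if require_both else (up_i | up_c)
    df.index.name = "participant"
    return df


# ---------------------------------------------------------------------------
# Biologically effective dose
# ---------------------------------------------------------------------------

def assess_bed(
    marker_decreases: pd.Series,
    dose_labels: pd.Series,
    decrease_cut: float = 0.10,
    participant_frac: float = 0.5,
) -> pd.DataFrame:
    """Apply the biologically-effective-dose rule per dose level.

    ``marker_decreases`` holds each participant's proportional marker decrease
    (positive = decrease). A participant qualifies when the decrease is
    ≥ ``decrease_cut``; a dose meets BED when the qualifying fraction is
    ≥ ``participant_frac`` (both comparisons inclusive).
    """
    dose_labels = dose_labels.reindex(marker_decreases.index)
    if dose_labels.isna().any():
        raise ValueError("dose label missing for some participants")
    rows = []
    for dose, grp in marker_decreases.groupby(dose_labels):
        n = len(grp)
        q = int((grp >= decrease_cut).sum())
        frac = q / n
        rows.append(
            {
                "dose": dose,
                "n_evaluable": n,
                "n_qualifying": q,
                "fraction": frac,
                "bed_met": frac >= participant_frac,
            }
        )
    return pd.DataFrame(rows).set_index("dose")


# ---------------------------------------------------------------------------
# Tumor-suppressor-gene hypermethylation and its reversal
# ---------------------------------------------------------------------------

def tsg_hyper_dmps(
    tumor_vs_normal: pd.DataFrame,
    tsg_list,
    delta_cut: float = 0.10,
    fdr_cut: float = 0.05,
) -> list:
    """Tumor-suppressor genes with ≥1 hypermethylated promoter probe in a
    tumor-vs-normal compendium.

    ``tumor_vs_normal`` has one row per promoter probe with columns
    ``gene``, ``delta_beta`` (tumor − normal) and ``fdr``. A TSG is retained
    when some promoter probe has Δβ ≥ ``delta_cut`` (hyper only) at
    FDR < ``fdr_cut``.
    """
    need = {"gene", "delta_beta", "fdr"}
    if not need.issubset(tumor_vs_normal.columns):
        raise ValueError(f"tumor_vs_normal needs columns {sorted(need)}")
    tsg = set(tsg_list)
    hits = tumor_vs_normal[
        tumor_vs_normal["gene"].isin(tsg)
        & (tumor_vs_normal["delta_beta"] >= delta_cut)
        & (tumor_vs_normal["fdr"] < fdr_cut)
    ]
    return sorted(hits["gene"].unique())


@dataclass
class TSGReversalResult:
    """Per-participant reversal counts over the hyper-DMP TSG list."""

    hyper_tsgs: list
    per_participant: pd.DataFrame  # n_reversed, mean_promoter_delta
    reversed_genes: dict  # participant -> list of genes


def tsg_reversal(
    hyper_tsgs,
    promoter_delta: pd.DataFrame,
    gene_fc: pd.DataFrame,
    meth_cut: float = 0.25,
    fc_cut: float = 2.0,
) -> TSGReversalResult:
    """Count, per participant, the hyper-methylated TSGs re-expressed on
    treatment: promoter Δβ < −``meth_cut`` and expression FC > ``fc_cut``
    (both strict)."""
    hyper_tsgs = sorted(set(hyper_tsgs))
    genes = [g for g in hyper_tsgs if g in promoter_delta.index]
    participants = list(promoter_delta.columns)
    rows = []
    reversed_genes = {}
    for part in participants:
        dmeth = promoter_delta.loc[genes, part]
        fc = gene_fc[part].reindex(genes)
        hit = (dmeth < -meth_cut) & (fc > fc_cut)
        reversed_genes[part] = sorted(pd.Index(genes)[hit.fillna(False)])
        rows.append(
            {
                "participant": part,
                "n_reversed": int(hit.sum()),
                "mean_promoter_delta": float(dmeth.mean()) if len(genes) else np.nan,
            }
        )
    return TSGReversalResult(hyper_tsgs, pd.DataFrame(rows).set_index("participant"), reversed_genes)


# ---------------------------------------------------------------------------
# Clinical summaries
# ---------------------------------------------------------------------------

def nlr(neutrophils, lymphocytes):
    """Neutrophil-to-lymphocyte ratio; missing (NaN) where lymphocytes = 0."""
    n = np.asarray(neutrophils, dtype=float)
    l = np.asarray(lymphocytes, dtype=float)
    zero = l == 0
    if zero.any():
        logger.warning("NLR undefined for %d records with zero lymphocytes", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, n / l)
    if np.isscalar(neutrophils) or out.ndim == 0:
        return float(out)
    return out


def nlr_cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean/SD of NLR at baseline and at the last treatment cycle.

    Expects columns ``neutrophils_baseline, lymphocytes_baseline,
    neutrophils_last, lymphocytes_last``; records with missing last-cycle
    counts contribute to the baseline summary only (available-case)."""
    base = nlr(clinical["neutrophils_baseline"], clinical["lymphocytes_baseline"])
    last = nlr(clinical["neutrophils_last"], clinical["lymphocytes_last"])
    rows = []
    for label, vals in (("baseline", base), ("last_cycle", last)):
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        rows.append({"timepoint": label, "n": len(v), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))})
    return pd.DataFrame(rows).set_index("timepoint")


def h_score(pct_intensity: pd.Series | dict) -> float:
    """IHC H-score: 1×(% intensity 1) + 2×(% intensity 2) + 3×(% intensity 3).

    ``pct_intensity`` maps intensity levels 0–3 to percentages summing to 100;
    the result ranges from 0 (all negative) to 300 (all intensity 3).
    """
    pct = {int(k): float(v) for k, v in dict(pct_intensity).items()}
    total = sum(pct.get(i, 0.0) for i in range(4))
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"intensity percentages must sum to 100 (got {total})")
    return 1.0 * pct.get(1, 0.0) + 2.0 * pct.get(2, 0.0) + 3.0 * pct.get(3, 0.0)


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_ranksum_p(ranks2: np.ndarray, n_a: int, w_obs2: int) -> float:
    """Two-sided exact p for the rank-sum statistic over all C(N, n_a)
    subsets, via a subset-sum count (ranks doubled to keep midranks integral).

    Two-sidedness is by distance from the null mean of the statistic.
    """
    N = len(ranks2)
    total = int(ranks2.sum())
    max_sum = total
    # counts[k, s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[1:, r:] += counts[:-1, : max_sum - r + 1]
    dist = counts[n_a]
    n_subsets = dist.sum()
    mean2 = n_a * total / N  # null mean of the doubled statistic
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mean2) >= abs(w_obs2 - mean2) - 1e-9
    return float(dist[extreme].sum() / n_subsets)


def wilcoxon_exact(group_a, group_b, exact_limit: int = 30) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact by enumeration.

    Uses midranks for ties and enumerates the full permutation distribution
    of the rank-sum of ``group_a`` whenever the combined sample size is
    ≤ ``exact_limit``; above that a tie-corrected normal approximation is
    used and flagged in the result.

    Returns a dict with ``p_value``, ``statistic`` (rank sum of group A),
    and ``exact`` (bool).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sp_stats.rankdata(combined)  # midranks
    w = float(ranks[: a.size].sum())
    N = combined.size
    if N <= exact_limit:
        ranks2 = np.round(2.0 * ranks).astype(int)
        p = _exact_ranksum_p(ranks2, a.size, int(round(2.0 * w)))
        return {"p_value": min(p, 1.0), "statistic": w, "exact": True}
    # tie-corrected normal approximation
    mu = a.size * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((N) * (N - 1))
    var = a.size * b.size / 12.0 * ((N + 1) - tie_term)
    z = (w - mu) / np.sqrt(var)
    return {"p_value": float(2.0 * sp_stats.norm.sf(abs(z))), "statistic": w, "exact": False}


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(times, events, rate_at: float | None = None, alpha: float = 0.05) -> dict:
    """Kaplan-Meier product-limit summary.

    Returns the survival function (with Greenwood-based log-log confidence
    band as fitted by lifelines), the median survival (first time S(t) ≤ 0.5;
    missing when never reached), and optionally the survival rate with CI at
    ``rate_at``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    median = kmf.median_survival_time_
    out = {
        "survival": kmf.survival_function_,
        "confidence": kmf.confidence_interval_,
        "median": float(median) if np.isfinite(median) else None,
    }
    if rate_at is not None:
        s = float(kmf.predict(rate_at))
        ci = kmf.confidence_interval_
        idx = ci.index[ci.index <= rate_at]
        band = ci.loc[idx[-1]] if len(idx) else ci.iloc[0]
        out["rate"] = {"t": rate_at, "survival": s, "ci": (float(band.iloc[0]), float(band.iloc[1]))}
    return out
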