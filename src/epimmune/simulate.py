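"""Synthetic paired-biopsy cohort generator.

Emulates the structure of a small dose-finding trial with paired baseline /
on-treatment tumor biopsies: a probe × sample methylome (beta values with
probe annotation and QC columns), a gene × sample RNA-seq count matrix,
cell-type reference profiles with known mixing fractions, clinical
neutrophil/lymphocyte counts and survival, and IHC intensity tables.

A subset of participants ("responders") carries planted treatment effects —
up-regulated IFN-γ / CD274 / STING signature genes, hypomethylated
tumor-suppressor-gene promoters with re-expression, a T-regulatory fraction
decrease and CD8+ T fraction increase, and a promoter-wide methylation
decrease — so that every downstream stage of the pipeline has a ground truth
to be checked against. All randomness flows from a single seed; identical
configurations produce byte-identical fixture files.

Noise model
-----------
β values are drawn from a beta distribution parameterized by (mean,
precision): observed β ~ Beta(m·φ, (1−m)·φ). Counts are marginally negative
binomial with dispersion ``nb_dispersion``: biological variation enters as a
gamma-distributed gene × participant latent shared by the two samples of a
pair, with Poisson sampling per sample on top — so between-participant
spread matches the stated dispersion while paired within-participant fold
changes carry only counting noise, as in a real paired design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CellTypeReference
from . import io as eio

__all__ = [
    "CELL_TYPES",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_reference",
    "mix_methylomes",
    "generate_cohort",
    "write_fixtures",
]

#: The 10 cell types whose fractions are estimated by deconvolution.
CELL_TYPES = (
    "Fibroblasts",
    "Neutrophils",
    "CD4_T",
    "CD8_T",
    "Treg",
    "CD14",
    "CD19",
    "CD56",
    "Eosinophils",
    "Cancer",
)

IFN_GAMMA_GENES = ("IDO1", "CXCL10", "CXCL9", "HLA-DRA", "STAT1", "IFNG")

#: Dirichlet concentration of baseline cell fractions (tumor-dominated).
_FRACTION_ALPHA = {
    "Fibroblasts": 8.0,
    "Neutrophils": 3.0,
    "CD4_T": 6.0,
    "CD8_T": 4.0,
    "Treg": 2.5,
    "CD14": 4.0,
    "CD19": 2.0,
    "CD56": 2.0,
    "Eosinophils": 1.0,
    "Cancer": 30.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with trial-scale defaults."""

    n_participants: int = 8
    n_probes: int = 20_000
    n_genes: int = 5_000
    responder_ids: tuple = None  # default: 3 of 8, set in __post_init__
    # planted multiplicative expression effects on responder on-treatment samples
    ifng_effect: float = 3.0
    cd274_effect: float = 2.8
    sting_effect: float = 1.8
    m1_effect: float = 1.3
    tsg_expression_effect: float = 3.0
    cta_effect: float = 3.0
    # planted methylation effects
    tsg_promoter_delta: float = -0.25
    global_promoter_delta: float = -0.08
    hypomethylated_ids: tuple = None  # default: responders + one 5-day non-responder
    dmr_delta: float = -0.30
    n_dmr_probes: int = 5
    # planted cell-fraction shifts (responder on-treatment, relative)
    treg_relative_change: float = -0.35
    cd8_relative_change: float = 0.50
    # noise
    beta_precision: float = 50.0
    nb_dispersion: float = 0.10
    library_size_range: tuple = (1_000_000, 3_000_000)
    fraction_jitter: float = 0.03
    # gene-set sizes (synthetic stand-ins at the published sizes)
    sting_size: int = 44
    m1_size: int = 188
    m2_size: int = 159
    apm_size: int = 15
    cta_size: int = 1_019
    tsg_size: int = 1_217
    n_planted_tsg_reversal: int = 20
    n_planted_cta: int = 12
    # deconvolution reference geometry
    n_reference_probes: int = 1_197
    n_reference_overlap: int = 933
    promoter_probes_per_gene: int = 3
    # clinical
    survival_rate_nonresponder: float = np.log(2) / 8.0  # per month
    survival_rate_ratio: float = 0.4
    censor_months: float = 36.0
    seed: int = 0

    participants: tuple = field(init=False)
    dose_of: dict = field(init=False)

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        self.participants = tuple(f"P{i + 1:02d}" for i in range(self.n_participants))
        if self.responder_ids is None:
            # 3 of 8 by default: two in the 5-day cohort, one in the 10-day
            picks = [1, 4, self.n_participants - 1]
            self.responder_ids = tuple(
                self.participants[i] for i in sorted(set(p % self.n_participants for p in picks))
            )
        self.responder_ids = tuple(self.responder_ids)
        unknown = set(self.responder_ids) - set(self.participants)
        if unknown:
            raise ValueError(f"responder_ids not among participants: {sorted(unknown)}")
        n_dose1 = int(np.ceil(self.n_participants * 5 / 8))
        self.dose_of = {
            p: ("5day" if i < n_dose1 else "10day") for i, p in enumerate(self.participants)
        }
        if self.hypomethylated_ids is None:
            extra = [
                p for p in self.participants
                if self.dose_of[p] == "5day" and p not in self.responder_ids
            ][:1]
            self.hypomethylated_ids = tuple(sorted(set(self.responder_ids) | set(extra)))
        self.hypomethylated_ids = tuple(self.hypomethylated_ids)
        unknown = set(self.hypomethylated_ids) - set(self.participants)
        if unknown:
            raise ValueError(f"hypomethylated_ids not among participants: {sorted(unknown)}")
        for name in ("ifng_effect", "cd274_effect", "sting_effect", "m1_effect",
                     "tsg_expression_effect", "cta_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0 (use np.inf for noiseless)")
        if not 0 < self.n_reference_overlap <= self.n_reference_probes:
            raise ValueError("need 0 < n_reference_overlap <= n_reference_probes")
        named = (
            len(IFN_GAMMA_GENES) + 1 + self.sting_size + self.m1_size + self.m2_size
            + self.apm_size + self.cta_size + self.tsg_size
        )
        if self.n_genes < named:
            raise ValueError(f"n_genes={self.n_genes} < {named} named signature/set genes")
        floor = (
            self.promoter_probes_per_gene * self.n_genes
            + self.n_reference_overlap + self.n_dmr_probes + 50
        )
        if self.n_probes < floor:
            raise ValueError(f"n_probes={self.n_probes} too small; need >= {floor}")

    @property
    def sample_ids(self) -> list:
        out = []
        for p in self.participants:
            out.extend([f"{p}_B", f"{p}_T"])
        return out

    def baseline_sample(self, part: str) -> str:
        return f"{part}_B"

    def on_treatment_sample(self, part: str) -> str:
        return f"{part}_T"


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

def _gene_table(config: SimulationConfig) -> tuple[pd.Index, dict]:
    """Gene symbols plus the named gene sets (synthetic stand-ins carry the
    published set sizes; membership is synthetic except the printed 6-gene
    IFN-γ list and CD274)."""
    sets = {"IFN_gamma": list(IFN_GAMMA_GENES)}
    genes = list(IFN_GAMMA_GENES) + ["CD274"]
    for name, size, prefix in (
        ("STING", config.sting_size, "STING_SYN_"),
        ("M1", config.m1_size, "M1_SYN_"),
        ("M2", config.m2_size, "M2_SYN_"),
        ("APM", config.apm_size, "APM_SYN_"),
        ("CTA", config.cta_size, "CTA_SYN_"),
        ("TSG", config.tsg_size, "TSG_SYN_"),
    ):
        members = [f"{prefix}{i + 1:04d}" for i in range(size)]
        sets[name] = members
        genes.extend(members)
    filler = [f"GENE_{i + 1:05d}" for i in range(config.n_genes - len(genes))]
    genes.extend(filler)
    return pd.Index(genes, name="gene"), sets


# ---------------------------------------------------------------------------
# reference + mixing
# ---------------------------------------------------------------------------

def _signature_profiles(rng: np.random.Generator, probe_ids, k: int) -> pd.DataFrame:
    """Marker-probe profiles: each probe is near-fully methylated in one cell
    type (round-robin) and lowly methylated in the rest — between-type spread
    well above 0.3, full column rank."""
    n = len(probe_ids)
    low = 0.15 + 0.10 * rng.random((n, k))
    prof = low
    marker = np.arange(n) % k
    prof[np.arange(n), marker] = 0.85 + 0.10 * rng.random(n)
    return pd.DataFrame(prof, index=probe_ids, columns=list(CELL_TYPES[:k]))


def generate_reference(config: SimulationConfig) -> CellTypeReference:
    """Cell-type reference profiles over the signature-CpG panel.

    The panel has ``n_reference_probes`` rows of which ``n_reference_overlap``
    carry probe IDs present in the cohort's beta matrix (the rest are
    reference-only CpGs, mimicking a reference built on a different array).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    overlap_ids = [f"sig{i + 1:05d}" for i in range(config.n_reference_overlap)]
    extra_ids = [
        f"refonly{i + 1:05d}"
        for i in range(config.n_reference_probes - config.n_reference_overlap)
    ]
    return CellTypeReference(
        _signature_profiles(rng, pd.Index(overlap_ids + extra_ids, name="probe_id"), len(CELL_TYPES))
    )


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, precision: float) -> np.ndarray:
    m = np.clip(mean, 0.01, 0.99)
    if np.isinf(precision):
        return m
    return rng.beta(m * precision, (1.0 - m) * precision)


def mix_methylomes(
    reference: CellTypeReference,
    fractions: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Forward model: expected β = reference · fractionsᵀ, observed β drawn
    from a beta distribution with that mean and concentration
    ``beta_precision`` (the mean is returned unchanged at precision ∞).

    ``fractions`` is sample × cell-type with rows summing to 1; the result is
    a probe × sample β DataFrame.
    """
    f = fractions[list(reference.cell_types)].to_numpy(dtype=float)
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("fraction rows must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    expected = reference.profiles.to_numpy(dtype=float) @ f.T
    return pd.DataFrame(
        _beta_noise(rng, expected, config.beta_precision),
        index=reference.probe_ids,
        columns=fractions.index,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A fully specified synthetic trial cohort with planted ground truth."""

    config: SimulationConfig
    beta: BetaMatrix
    counts: pd.DataFrame  # gene × sample integers
    gene_lengths: pd.Series
    reference: CellTypeReference
    true_fractions: pd.DataFrame  # sample × cell type
    sample_sheet: pd.DataFrame
    clinical: pd.DataFrame
    ihc: pd.DataFrame
    gene_sets: dict
    truth: dict


def _probe_layout(config: SimulationConfig, genes: pd.Index, rng: np.random.Generator):
    """Assign probes to chromosomes, positions, genes and region classes.

    Probes come in 'units' (a gene promoter, a signature CpG, the planted
    DMR run, a filler block); units are scattered across autosomes with
    large inter-unit gaps and small intra-unit gaps, yielding the clustered
    CpG geography that region detection relies on.
    """
    ppg = config.promoter_probes_per_gene
    units = []  # (kind, payload, n_probes)
    for g in genes:
        units.append(("promoter", g, ppg))
    for i in range(config.n_reference_overlap):
        units.append(("signature", f"sig{i + 1:05d}", 1))
    units.append(("dmr", None, config.n_dmr_probes))
    n_sex = max(4, config.n_probes // 400)
    used = ppg * len(genes) + config.n_reference_overlap + config.n_dmr_probes + n_sex
    n_filler = config.n_probes - used
    while n_filler > 0:
        size = int(min(n_filler, rng.integers(1, 4)))
        units.append(("other", None, size))
        n_filler -= size
    rng.shuffle(units)

    autosomes = [f"chr{i}" for i in range(1, 23)]
    per_chrom: dict = {c: [] for c in autosomes + ["chrX", "chrY"]}
    cursor = {c: 1_000 for c in per_chrom}
    sig_counter = 0
    probe_counter = 0
    dmr_coords = None
    for u_idx, (kind, payload, size) in enumerate(units):
        chrom = "chr1" if kind == "dmr" else autosomes[u_idx % len(autosomes)]
        pos = cursor[chrom] + int(rng.integers(2_000, 10_000))
        rows = []
        for j in range(size):
            if kind == "promoter":
                pid = f"cg{probe_counter:07d}"
                probe_counter += 1
                region = "TSS200" if j % 2 == 0 else "5UTR"
                gene = payload
            elif kind == "signature":
                pid = payload
                region = "Body"
                gene = ""
            elif kind == "dmr":
                pid = f"cg{probe_counter:07d}"
                probe_counter += 1
                region = "Body"
                gene = ""
            else:
                pid = f"cg{probe_counter:07d}"
                probe_counter += 1
                region = "Other" if j % 2 else "Body"
                gene = ""
            rows.append((pid, chrom, pos, gene, region, kind))
            pos += int(rng.integers(50, 300))
        cursor[chrom] = pos
        if kind == "dmr":
            dmr_coords = {"chrom": chrom, "start": rows[0][2], "end": rows[-1][2]}
        for r in rows:
            per_chrom[chrom].append(r)
        if kind == "signature":
            sig_counter += 1
    # sex-chromosome probes (excluded by QC)
    for i in range(n_sex):
        chrom = "chrX" if i % 2 == 0 else "chrY"
        pos = cursor[chrom] + int(rng.integers(2_000, 10_000))
        per_chrom[chrom].append((f"cg{probe_counter:07d}", chrom, pos, "", "Body", "sex"))
        probe_counter += 1
        cursor[chrom] = pos

    records = []
    for c in autosomes + ["chrX", "chrY"]:
        records.extend(per_chrom[c])
    ann = pd.DataFrame(records, columns=["probe_id", "chrom", "pos", "gene", "region", "kind"])
    ann = ann.set_index("probe_id")
    ann["cytoband"] = [
        f"{c.removeprefix('chr')}q{(p // 5_000_000) % 30 + 11}" for c, p in zip(ann["chrom"], ann["pos"])
    ]
    return ann, dmr_coords


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; see module docstring for the model."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    genes, gene_sets = _gene_table(config)
    ann, dmr_coords = _probe_layout(config, genes, rng)
    n_probes = len(ann)
    samples = config.sample_ids
    n_samples = len(samples)
    responders = set(config.responder_ids)

    # ---- planted gene subsets -------------------------------------------
    planted_tsg = gene_sets["TSG"][: config.n_planted_tsg_reversal]
    planted_cta = gene_sets["CTA"][: config.n_planted_cta]
    cta_participant = config.responder_ids[-1]
    gene_sets = dict(gene_sets)
    gene_sets["PLANTED_REVERSAL"] = list(planted_tsg)

    # ---- true cell fractions --------------------------------------------
    alpha = np.array([_FRACTION_ALPHA[t] for t in CELL_TYPES])
    frac_rows = {}
    for part in config.participants:
        base = rng.dirichlet(alpha)
        on = base.copy()
        if part in responders:
            ct = {t: i for i, t in enumerate(CELL_TYPES)}
            on[ct["Treg"]] *= 1.0 + config.treg_relative_change
            on[ct["CD8_T"]] *= 1.0 + config.cd8_relative_change
        if config.fraction_jitter > 0:
            on = on * np.exp(rng.normal(0.0, config.fraction_jitter, len(on)))
        on = on / on.sum()
        frac_rows[config.baseline_sample(part)] = base
        frac_rows[config.on_treatment_sample(part)] = on
    true_fractions = pd.DataFrame(
        [frac_rows[s] for s in samples], index=pd.Index(samples, name="sample_id"), columns=list(CELL_TYPES)
    )

    # ---- methylome -------------------------------------------------------
    reference = generate_reference(config)
    base_mean = 0.05 + 0.90 * rng.beta(0.4, 0.4, n_probes)
    # hypermethylated promoters for the planted reversal TSGs
    tsg_prom = (ann["region"].isin(["TSS200", "5UTR"]) & ann["gene"].isin(planted_tsg)).to_numpy()
    base_mean[tsg_prom] = 0.60 + 0.10 * rng.random(tsg_prom.sum())
    dmr_mask = (ann["kind"] == "dmr").to_numpy()
    base_mean[dmr_mask] = 0.60 + 0.05 * rng.random(dmr_mask.sum())

    profiles = np.tile(base_mean[:, None], (1, len(CELL_TYPES)))
    sig_mask = (ann["kind"] == "signature").to_numpy()
    sig_ids = ann.index[sig_mask]
    profiles[sig_mask] = reference.profiles.loc[sig_ids].to_numpy()

    expected = profiles @ true_fractions.to_numpy().T  # probe × sample
    prom_mask = ann["region"].isin(["TSS200", "5UTR"]).to_numpy()
    for j, s in enumerate(samples):
        part = s.rsplit("_", 1)[0]
        on_treat = s.endswith("_T")
        if not on_treat:
            continue
        if part in config.hypomethylated_ids:
            expected[prom_mask, j] += config.global_promoter_delta
        if part in responders:
            expected[tsg_prom, j] += config.tsg_promoter_delta
        expected[dmr_mask, j] += config.dmr_delta
    expected = np.clip(expected, 0.02, 0.98)
    beta_vals = _beta_noise(rng, expected, config.beta_precision)

    annotation = ann.drop(columns=["kind"]).copy()
    annotation["snp_flag"] = False
    annotation["multimap_flag"] = False
    plain = (ann["kind"] == "other").to_numpy()
    plain_idx = np.flatnonzero(plain)
    if len(plain_idx) >= 40:
        n_snp = max(1, len(plain_idx) // 100)
        snp_pick = rng.choice(plain_idx, size=n_snp, replace=False)
        rest = np.setdiff1d(plain_idx, snp_pick)
        mm_pick = rng.choice(rest, size=n_snp, replace=False)
        annotation.iloc[snp_pick, annotation.columns.get_loc("snp_flag")] = True
        annotation.iloc[mm_pick, annotation.columns.get_loc("multimap_flag")] = True
        rest = np.setdiff1d(rest, mm_pick)
    else:
        rest = plain_idx
    det = pd.DataFrame(
        0.001 + 0.004 * rng.random((n_probes, n_samples)),
        index=ann.index,
        columns=[f"detection_p_{s}" for s in samples],
    )
    beads = pd.DataFrame(
        True, index=ann.index, columns=[f"beads_ok_{s}" for s in samples]
    )
    if len(rest) >= 20:
        n_fail = max(1, len(rest) // 100)
        det_fail = rng.choice(rest, size=n_fail, replace=False)
        for i in det_fail:  # fails detection in one sample: 1/n > 5% when n <= 19
            det.iloc[i, int(rng.integers(n_samples))] = 0.5
        rest2 = np.setdiff1d(rest, det_fail)
        bead_fail = rng.choice(rest2, size=max(1, n_fail // 2), replace=False)
        for i in bead_fail:
            beads.iloc[i, int(rng.integers(n_samples))] = False
    annotation = pd.concat([annotation, det, beads], axis=1)

    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=ann.index, columns=samples), annotation
    )

    # ---- transcriptome ---------------------------------------------------
    n_genes = len(genes)
    lengths = pd.Series(
        np.maximum(200, np.round(np.exp(rng.normal(np.log(1500), 0.5, n_genes)))).astype(int),
        index=genes,
        name="length",
    )
    weight = np.exp(rng.normal(0.0, 1.0, n_genes))
    biomarker = list(IFN_GAMMA_GENES) + ["CD274"] + gene_sets["STING"] + gene_sets["M1"] \
        + gene_sets["M2"] + gene_sets["APM"] + planted_cta + planted_tsg
    bio_mask = genes.isin(biomarker)
    weight[bio_mask] = np.maximum(weight[bio_mask], 1.0)  # keep biomarker genes quantifiable

    # gene × participant biological latent, shared within a pair
    shape = 1.0 / config.nb_dispersion
    latent = rng.gamma(shape, scale=1.0 / shape, size=(n_genes, config.n_participants))
    eff = np.ones((n_genes, n_samples))
    idx_of = {g: i for i, g in enumerate(genes)}

    def bump(gene_list, factor, col):
        rows = [idx_of[g] for g in gene_list if g in idx_of]
        eff[rows, col] *= factor

    for pi, part in enumerate(config.participants):
        col = samples.index(config.on_treatment_sample(part))
        if part in responders:
            bump(IFN_GAMMA_GENES, config.ifng_effect, col)
            bump(["CD274"], config.cd274_effect, col)
            bump(gene_sets["STING"], config.sting_effect, col)
            bump(gene_sets["M1"], config.m1_effect, col)
            bump(planted_tsg, config.tsg_expression_effect, col)
        if part == cta_participant:
            bump(planted_cta, config.cta_effect, col)

    lib = rng.uniform(*config.library_size_range, n_samples)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j, s in enumerate(samples):
        pi = config.participants.index(s.rsplit("_", 1)[0])
        lam = weight * latent[:, pi] * eff[:, j]
        lam = lam / lam.sum() * lib[j]
        counts[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(counts, index=genes, columns=samples)

    # ---- sample sheet ----------------------------------------------------
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "participant_id": [s.rsplit("_", 1)[0] for s in samples],
            "timepoint": ["baseline" if s.endswith("_B") else "on_treatment" for s in samples],
            "dose": [config.dose_of[s.rsplit("_", 1)[0]] for s in samples],
        }
    )

    # ---- clinical --------------------------------------------------------
    clin_rows = []
    for part in config.participants:
        resp = part in responders
        neut_b = float(np.exp(rng.normal(np.log(6.0), 0.4)))
        lymph_b = float(np.exp(rng.normal(np.log(1.0), 0.3)))
        neut_l = float(np.exp(rng.normal(np.log(5.0), 0.4)))
        lymph_l = lymph_b * float(np.exp(rng.normal(np.log(1.6) if resp else 0.0, 0.2)))
        rate = config.survival_rate_nonresponder * (config.survival_rate_ratio if resp else 1.0)
        t = float(rng.exponential(1.0 / rate))
        event = t <= config.censor_months
        clin_rows.append(
            {
                "participant_id": part,
                "dose": config.dose_of[part],
                "neutrophils_baseline": round(neut_b, 3),
                "lymphocytes_baseline": round(lymph_b, 3),
                "neutrophils_last": round(neut_l, 3),
                "lymphocytes_last": round(lymph_l, 3),
                "survival_months": round(min(t, config.censor_months), 2),
                "event": bool(event),
            }
        )
    clinical = pd.DataFrame(clin_rows).set_index("participant_id")

    # ---- IHC -------------------------------------------------------------
    ihc_rows = []
    for s in samples:
        part = s.rsplit("_", 1)[0]
        hot = part in responders and s.endswith("_T")
        for marker in ("CD8", "FOXP3"):
            if marker == "CD8":
                alpha_i = (40, 20, 25, 15) if hot else (70, 15, 10, 5)
            else:
                alpha_i = (75, 12, 8, 5) if hot else (55, 20, 15, 10)
            pct = 100.0 * rng.dirichlet(alpha_i)
            pct = np.round(pct, 4)
            pct[0] = 100.0 - pct[1:].sum()  # exact sum to 100
            ihc_rows.append(
                {
                    "sample_id": s,
                    "marker": marker,
                    "pct_intensity_0": pct[0],
                    "pct_intensity_1": pct[1],
                    "pct_intensity_2": pct[2],
                    "pct_intensity_3": pct[3],
                }
            )
    ihc = pd.DataFrame(ihc_rows)

    truth = {
        "responders": sorted(responders),
        "dose_of": dict(config.dose_of),
        "planted_dmr": dmr_coords,
        "planted_reversed_tsgs": list(planted_tsg),
        "planted_cta_genes": list(planted_cta),
        "cta_participant": cta_participant,
        "expected_bed_dose": "5day",
        "planted_enriched_sets": ["PLANTED_REVERSAL"],
        "hypomethylated_participants": sorted(config.hypomethylated_ids),
    }

    return SyntheticCohort(
        config=config,
        beta=beta,
        counts=counts,
        gene_lengths=lengths,
        reference=reference,
        true_fractions=true_fractions,
        sample_sheet=sheet,
        clinical=clinical,
        ihc=ihc,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixtures(cohort: SyntheticCohort, directory) -> dict:
    """Write the 8 fixture files and return a manifest of paths + checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .containers import CountMatrix

    paths = {
        "beta": directory / "beta.csv",
        "counts": directory / "counts.tsv",
        "annotation": directory / "annotation.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "sample_sheet": directory / "sample_sheet.csv",
        "clinical": directory / "clinical.csv",
        "ihc": directory / "ihc.csv",
        "truth": directory / "truth.json",
    }
    eio.write_beta(cohort.beta, paths["beta"])
    eio.write_counts(CountMatrix(cohort.counts, cohort.gene_lengths), paths["counts"])
    eio.write_annotation(cohort.beta.annotation, paths["annotation"])
    eio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    cohort.sample_sheet.to_csv(paths["sample_sheet"], index=False)
    cohort.clinical.to_csv(paths["clinical"])
    cohort.ihc.to_csv(paths["ihc"], index=False)
    eio.write_json(cohort.truth, paths["truth"])
    return {
        name: {"path": str(p), "sha256": eio.sha256_of(p)} for name, p in paths.items()
    }
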