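"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: input validation → methylation (probe QC,
paired DMPs, optional DMRs, promoter deltas, global summaries) → expression
(RPKM, signature scores, paired fold changes) → deconvolution → enrichment →
endpoints (molecular responders, biologically effective dose, TSG reversal,
NLR, Kaplan-Meier). Identical configuration + seed yields an identical run
report (timestamps aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .containers import CountMatrix, PairedDesign
from .biomarkers import (
    assess_bed,
    call_molecular_responders,
    km_curve,
    nlr_cohort_summary,
    tsg_hyper_dmps,
    tsg_reversal,
)
from .deconvolution import deconvolve, fraction_change, intersect_reference
from .enrichment import directional_enrichment, joint_hypo_up, make_gene_stats
from .expression import (
    SignatureDefinition,
    m1_m2_ratio,
    paired_fold_change,
    paired_gene_test,
    paired_signature_fold_change,
    rpkm,
    set_upregulation_count,
)
from .methylation import (
    find_dmrs,
    gene_level_z,
    global_methylation_summary,
    paired_dmp,
    promoter_delta,
    promoter_probe_delta,
    qc_filter_probes,
    standardize_promoter_deltas,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and thresholds for a pipeline run.

    Threshold defaults are the trial's printed values: detection p 0.01 /
    3 beads / 5% sample-failure for probe QC, BH FDR 0.05, 2-fold responder
    rule, 25% promoter-methylation reversal, 10% marker decrease in ≥50% of
    a dose cohort for the BED call.
    """

    beta_path: str = ""
    annotation_path: str = ""
    counts_path: str = ""
    sample_sheet_path: str = ""
    clinical_path: str = ""
    ihc_path: str = ""
    gene_sets_path: str = ""
    reference_path: str = ""
    tumor_vs_normal_path: str = ""  # optional compendium DMP table for hyper-TSGs
    output_dir: str = "epimmune_out"
    seed: int = 0

    run_methylation: bool = True
    run_dmr: bool = False  # permutation scan; off by default for speed
    run_expression: bool = True
    run_deconvolution: bool = True
    run_enrichment: bool = True
    run_endpoints: bool = True

    detection_p_cut: float = 0.01
    min_beads: int = 3
    max_fail_fraction: float = 0.05
    fdr_cut: float = 0.05
    responder_fc_cut: float = 2.0
    reversal_meth_cut: float = 0.25
    reversal_fc_cut: float = 2.0
    bed_decrease_cut: float = 0.10
    bed_participant_frac: float = 0.5
    global_decrease_cut: float = 0.25
    enrichment_min_size: int = 10
    enrichment_max_size: int = 500
    dmr_max_gap_bp: int = 500
    dmr_min_probes: int = 3
    dmr_delta_cut: float = 0.1
    dmr_n_perm: int = 1000
    pseudocount: float = 1.0
    signature_offset: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _load_inputs(config: PipelineConfig) -> dict:
    beta = eio.read_beta(config.beta_path, config.annotation_path)
    sheet = eio.read_sample_sheet(config.sample_sheet_path)
    inputs = {"beta": beta, "sheet": sheet, "design": PairedDesign.from_sample_sheet(sheet)}
    if config.counts_path:
        inputs["counts"] = eio.read_counts(config.counts_path)
    if config.clinical_path:
        inputs["clinical"] = eio.read_clinical(config.clinical_path)
    if config.ihc_path:
        inputs["ihc"] = eio.read_ihc(config.ihc_path)
    if config.gene_sets_path:
        inputs["gene_sets"] = eio.read_gmt(config.gene_sets_path)
    if config.reference_path:
        inputs["reference"] = eio.read_reference(config.reference_path)
    if config.tumor_vs_normal_path:
        inputs["tumor_vs_normal"] = pd.read_csv(config.tumor_vs_normal_path, sep="\t")
    return inputs


def validate_inputs(config: PipelineConfig) -> list:
    """Cross-check matrices, annotation and sample sheet without running any
    analysis; returns a list of human-readable error strings (empty = clean).
    """
    errors: list[str] = []
    try:
        values = pd.read_csv(config.beta_path, index_col=0)
    except Exception as exc:
        return [f"cannot read beta matrix: {exc}"]
    arr = values.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    for i, j in bad[:10]:
        errors.append(
            f"beta value {arr[i, j]} out of [0,1] at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    try:
        ann = eio.read_annotation(config.annotation_path)
        missing = values.index.difference(ann.index)
        if len(missing):
            errors.append(f"{len(missing)} probes missing annotation (e.g. {missing[:3].tolist()})")
    except Exception as exc:
        errors.append(f"cannot read annotation: {exc}")
    try:
        sheet = eio.read_sample_sheet(config.sample_sheet_path)
        for part, grp in sheet.groupby("participant_id"):
            tps = set(grp["timepoint"])
            for needed in ("baseline", "on_treatment"):
                if needed not in tps:
                    errors.append(f"participant {part!r} missing {needed} sample")
        unknown = set(sheet["sample_id"]) - set(values.columns)
        if unknown:
            errors.append(f"sample sheet samples absent from beta matrix: {sorted(unknown)}")
    except Exception as exc:
        errors.append(f"cannot read sample sheet: {exc}")
    if config.counts_path:
        try:
            eio.read_counts(config.counts_path)
        except Exception as exc:
            errors.append(f"counts file invalid: {exc}")
    return errors


def _signatures_from_sets(gene_sets: dict) -> dict:
    out = {}
    for name in ("IFN_gamma", "STING", "M1", "M2", "APM", "CTA", "TSG"):
        if name in gene_sets:
            out[name] = SignatureDefinition(name, tuple(gene_sets[name]))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages and return the run report (also written to
    ``output_dir/report.json`` with stage outputs as TSVs)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": config.to_dict(), "stages": {}, "warnings": [], "endpoints": {}}

    errors = validate_inputs(config)
    if errors:
        raise ValueError("input validation failed: " + "; ".join(errors[:5]))
    inputs = _load_inputs(config)
    design: PairedDesign = inputs["design"]
    beta = inputs["beta"]

    def _stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    def _done(name, t0, **info):
        report["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}

    prom_delta = None
    gene_z = None
    if config.run_methylation:
        t0 = _stage("methylation")
        beta_qc, removal_log = qc_filter_probes(
            beta,
            max_fail_fraction=config.max_fail_fraction,
            detection_p_cut=config.detection_p_cut,
            min_beads=config.min_beads,
        )
        dmp = paired_dmp(beta_qc, design)
        dmp.table.to_csv(outdir / "dmp.tsv", sep="\t")
        prom_delta = promoter_delta(beta_qc, design)
        prom_delta.to_csv(outdir / "promoter_delta.tsv", sep="\t")
        probe_delta = promoter_probe_delta(beta_qc, design)
        z_probe = standardize_promoter_deltas(probe_delta)
        gene_z = {
            part: gene_level_z(z_probe[part], beta_qc.annotation["gene"])
            for part in design.participants
        }
        glob = global_methylation_summary(beta_qc, design, decrease_cut=config.global_decrease_cut)
        glob.to_csv(outdir / "global_methylation.tsv", sep="\t")
        n_dmrs = None
        if config.run_dmr:
            dmr = find_dmrs(
                beta_qc,
                design,
                max_gap_bp=config.dmr_max_gap_bp,
                min_probes=config.dmr_min_probes,
                delta_cut=config.dmr_delta_cut,
                n_perm=config.dmr_n_perm,
                seed=config.seed,
            )
            dmr.table.to_csv(outdir / "dmr.tsv", sep="\t", index=False)
            eio.write_dmrs_bed(dmr.table[dmr.table["p_adjusted"] < config.fdr_cut], outdir / "dmr.bed")
            n_dmrs = int((dmr.table["p_adjusted"] < config.fdr_cut).sum())
        _done(
            "methylation",
            t0,
            n_probes_in=int(len(beta.probe_ids)),
            n_probes_kept=int(len(beta_qc.probe_ids)),
            removal_log=removal_log.to_dict(),
            n_significant_dmps=int((dmp.table["p_adjusted"] < config.fdr_cut).sum()),
            n_significant_dmrs=n_dmrs,
        )
        report["endpoints"]["global_methylation"] = glob.reset_index().to_dict(orient="records")
        beta_for_deconv = beta_qc
    else:
        beta_for_deconv = beta

    sig_fc = {}
    gene_fc = None
    gene_test = None
    expr = None
    if config.run_expression and "counts" in inputs:
        t0 = _stage("expression")
        expr = rpkm(inputs["counts"], pseudocount=config.pseudocount)
        sigs = _signatures_from_sets(inputs.get("gene_sets", {}))
        gene_fc = paired_fold_change(expr, design, offset=config.signature_offset)
        gene_fc.to_csv(outdir / "gene_fc.tsv", sep="\t")
        for name in ("IFN_gamma", "STING"):
            if name in sigs:
                sig_fc[name] = paired_signature_fold_change(
                    expr, sigs[name], design, offset=config.signature_offset
                )
        if "M1" in sigs and "M2" in sigs:
            _, sig_fc["M1_M2_ratio"] = m1_m2_ratio(
                expr, sigs["M1"], sigs["M2"], design, offset=config.signature_offset
            )
        set_counts = {}
        for name in ("CTA", "APM"):
            if name in sigs:
                set_counts[name] = set_upregulation_count(gene_fc, sigs[name]).to_dict(orient="index")
        gene_test = paired_gene_test(expr, design)
        pd.DataFrame(sig_fc).to_csv(outdir / "signature_fc.tsv", sep="\t")
        _done("expression", t0, signatures=sorted(sig_fc), set_upregulation=set_counts)

    fractions = None
    if config.run_deconvolution and "reference" in inputs:
        t0 = _stage("deconvolution")
        ref = intersect_reference(inputs["reference"], beta_for_deconv)
        result = deconvolve(beta_for_deconv, ref)
        fractions = result.fractions
        fractions.to_csv(outdir / "cell_fractions.tsv", sep="\t")
        changes = fraction_change(result, design)
        changes["relative"].to_csv(outdir / "fraction_change_relative.tsv", sep="\t")
        _done(
            "deconvolution",
            t0,
            n_reference_probes=int(len(ref.probe_ids)),
            cohort_mean_relative=changes["cohort_mean_relative"].round(4).to_dict(),
        )
        report["endpoints"]["cell_fraction_mean_relative_change"] = (
            changes["cohort_mean_relative"].round(4).to_dict()
        )

    if config.run_enrichment and gene_test is not None and "gene_sets" in inputs and gene_z:
        t0 = _stage("enrichment")
        expr_stats = make_gene_stats(gene_test["p_value"], np.sign(gene_test["log2_fc"]))
        enr_expr = directional_enrichment(
            expr_stats, inputs["gene_sets"],
            min_size=config.enrichment_min_size, max_size=config.enrichment_max_size,
        )
        enr_expr.to_csv(outdir / "enrichment_expression.tsv", sep="\t")
        # cohort-level methylation enrichment from the mean gene Z across participants
        zmat = pd.DataFrame({p: gz["z"] for p, gz in gene_z.items()})
        z_mean = zmat.mean(axis=1) * np.sqrt(zmat.notna().sum(axis=1))
        from scipy import stats as sp_stats

        meth_stats = make_gene_stats(
            pd.Series(2.0 * sp_stats.norm.sf(np.abs(z_mean)), index=z_mean.index),
            np.sign(z_mean),
        )
        enr_meth = directional_enrichment(
            meth_stats, inputs["gene_sets"],
            min_size=config.enrichment_min_size, max_size=config.enrichment_max_size,
        )
        enr_meth.to_csv(outdir / "enrichment_methylation.tsv", sep="\t")
        joint = joint_hypo_up(enr_meth, enr_expr, fdr_cut=config.fdr_cut)
        joint.to_csv(outdir / "joint_hypo_up.tsv", sep="\t")
        _done("enrichment", t0, n_sets_expr=int(len(enr_expr)), n_joint=int(len(joint)))
        report["endpoints"]["joint_hypo_up_sets"] = joint.index.tolist()

    if config.run_endpoints:
        t0 = _stage("endpoints")
        if "IFN_gamma" in sig_fc and gene_fc is not None and "CD274" in gene_fc.index:
            calls = call_molecular_responders(
                sig_fc["IFN_gamma"], gene_fc.loc["CD274"], fc_cut=config.responder_fc_cut
            )
            calls.to_csv(outdir / "responders.tsv", sep="\t")
            report["endpoints"]["responders"] = sorted(calls.index[calls["responder"]])
            report["endpoints"]["responder_table"] = calls.round(4).to_dict(orient="index")
        if prom_delta is not None and "clinical" in inputs:
            # BED marker: relative decrease in mean promoter beta per participant
            base = beta_for_deconv.values[design.baseline_samples]
            on = beta_for_deconv.values[design.on_treatment_samples]
            prom = beta_for_deconv.promoter_mask().to_numpy()
            mb = base.to_numpy()[prom].mean(axis=0)
            mo = on.to_numpy()[prom].mean(axis=0)
            decrease = pd.Series((mb - mo) / mb, index=design.participants)
            bed = assess_bed(
                decrease,
                inputs["clinical"]["dose"],
                decrease_cut=config.bed_decrease_cut,
                participant_frac=config.bed_participant_frac,
            )
            bed.to_csv(outdir / "bed.tsv", sep="\t")
            report["endpoints"]["bed"] = bed.to_dict(orient="index")
            report["endpoints"]["bed_marker"] = "relative decrease in mean promoter beta"
        if prom_delta is not None and gene_fc is not None and "gene_sets" in inputs and "TSG" in inputs["gene_sets"]:
            if "tumor_vs_normal" in inputs:
                hyper = tsg_hyper_dmps(inputs["tumor_vs_normal"], inputs["gene_sets"]["TSG"])
            else:
                hyper = sorted(set(inputs["gene_sets"]["TSG"]))
                report["warnings"].append(
                    "no tumor-vs-normal table supplied; treating full TSG set as hyper-DMP TSGs"
                )
            rev = tsg_reversal(
                hyper, prom_delta, gene_fc,
                meth_cut=config.reversal_meth_cut, fc_cut=config.reversal_fc_cut,
            )
            rev.per_participant.to_csv(outdir / "tsg_reversal.tsv", sep="\t")
            report["endpoints"]["tsg_reversal"] = rev.per_participant["n_reversed"].to_dict()
        if "clinical" in inputs:
            clin = inputs["clinical"]
            report["endpoints"]["nlr"] = nlr_cohort_summary(clin).round(3).to_dict(orient="index")
            km = km_curve(clin["survival_months"], clin["event"], rate_at=24.0)
            report["endpoints"]["km"] = {
                "median_months": km["median"],
                "rate_24mo": km.get("rate", {}).get("survival"),
            }
        _done("endpoints", t0)

    for name in ("beta_path", "annotation_path", "counts_path", "sample_sheet_path",
                 "clinical_path", "ihc_path", "gene_sets_path", "reference_path"):
        p = getattr(config, name)
        if p:
            report.setdefault("input_checksums", {})[name] = eio.sha256_of(p)

    eio.write_json(report, outdir / "report.json")
    return report
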