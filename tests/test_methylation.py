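"""Probe QC, β/M conversion, paired testing, DMRs and promoter statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epimmune.containers import BetaMatrix, PairedDesign
from epimmune.methylation import (
    beta_to_m,
    find_dmrs,
    gene_level_z,
    global_methylation_summary,
    m_to_beta,
    paired_dmp,
    promoter_delta,
    qc_filter_probes,
    standardize_promoter_deltas,
)

from conftest import make_beta_matrix, make_paired_design


class TestBetaMConversion:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0), (0.0, np.log2(1e-6 / (1 - 1e-6)))],
    )
    def test_known_values(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)

    def test_vectorized_round_trip(self):
        b = np.linspace(1e-6, 1 - 1e-6, 1001)
        assert np.max(np.abs(m_to_beta(beta_to_m(b)) - b)) < 1e-12


class TestProbeQC:
    def _matrix(self, n_samples=16):
        rng = np.random.default_rng(0)
        bm = make_beta_matrix(rng.uniform(0.1, 0.9, (6, n_samples)), with_qc=True)
        return bm

    def test_detection_failure_over_5pct_removed(self):
        bm = self._matrix(16)
        # probe 0 fails detection in 1 of 16 samples: 6.25% > 5% -> removed
        bm.annotation.loc["cg000000", "detection_p_s0"] = 0.5
        filtered, log = qc_filter_probes(bm)
        assert "cg000000" not in filtered.probe_ids
        assert log["detection_or_beads"] == 1

    def test_failure_at_exactly_5pct_retained(self):
        bm = self._matrix(20)
        # 1 of 20 = exactly 5%: the rule is strictly "over 5%"
        bm.annotation.loc["cg000001", "detection_p_s3"] = 0.5
        filtered, _ = qc_filter_probes(bm)
        assert "cg000001" in filtered.probe_ids

    def test_low_bead_count_counts_as_failure(self):
        bm = self._matrix(16)
        bm.annotation.loc["cg000002", ["beads_ok_s0", "beads_ok_s1"]] = False
        filtered, _ = qc_filter_probes(bm)
        assert "cg000002" not in filtered.probe_ids

    def test_sex_chromosome_probe_removed_even_if_clean(self):
        bm = self._matrix()
        bm.annotation.loc["cg000003", "chrom"] = "chrX"
        filtered, log = qc_filter_probes(bm)
        assert "cg000003" not in filtered.probe_ids
        assert log["sex_chromosome"] == 1

    def test_snp_and_multimap_flags_removed(self):
        bm = self._matrix()
        bm.annotation.loc["cg000004", "snp_flag"] = True
        bm.annotation.loc["cg000005", "multimap_flag"] = True
        filtered, log = qc_filter_probes(bm)
        assert set(filtered.probe_ids) & {"cg000004", "cg000005"} == set()
        assert log["snp"] == 1 and log["multimap"] == 1

    def test_removal_log_sums_to_removed_count(self):
        bm = self._matrix()
        bm.annotation.loc["cg000000", "detection_p_s0"] = 0.5
        bm.annotation.loc["cg000004", "snp_flag"] = True
        filtered, log = qc_filter_probes(bm)
        assert log.sum() == len(bm.probe_ids) - len(filtered.probe_ids)

    def test_missing_qc_columns_named_in_error(self):
        bm = make_beta_matrix(np.full((3, 4), 0.5))
        with pytest.raises(ValueError, match="detection_p"):
            qc_filter_probes(bm)


class TestPairedDMP:
    def _null_matrix(self, n_probes=400, n_pairs=8, seed=0, precision=50.0):
        rng = np.random.default_rng(seed)
        m = 0.05 + 0.9 * rng.beta(0.4, 0.4, n_probes)
        mm = np.clip(m, 0.01, 0.99)[:, None]
        vals = rng.beta(mm * precision, (1 - mm) * precision, (n_probes, 2 * n_pairs))
        return make_beta_matrix(vals), make_paired_design(n_pairs)

    def test_unmoderated_matches_scipy_paired_t(self):
        bm, design = self._null_matrix()
        res = paired_dmp(bm, design, moderated=False)
        m_on = beta_to_m(bm.values[design.on_treatment_samples].to_numpy())
        m_base = beta_to_m(bm.values[design.baseline_samples].to_numpy())
        ref = stats.ttest_rel(m_on, m_base, axis=1)
        assert np.allclose(res.table["p_value"], ref.pvalue, atol=1e-10)
        assert np.allclose(res.table["statistic"], ref.statistic, atol=1e-10)

    def test_planted_shift_detected_with_high_sensitivity(self):
        rng = np.random.default_rng(1)
        n_probes, n_pairs, prec = 2000, 8, 50.0
        m = np.full(n_probes, 0.6)
        base = rng.beta(m[:, None] * prec, (1 - m[:, None]) * prec, (n_probes, n_pairs))
        m_on = m.copy()
        m_on[:100] -= 0.30  # planted hypomethylation
        on = rng.beta(m_on[:, None] * prec, (1 - m_on[:, None]) * prec, (n_probes, n_pairs))
        vals = np.empty((n_probes, 2 * n_pairs))
        vals[:, ::2], vals[:, 1::2] = base, on
        bm = make_beta_matrix(vals)
        design = make_paired_design(n_pairs)
        res = paired_dmp(bm, design)
        sensitivity = (res.table["p_adjusted"].iloc[:100] < 0.05).mean()
        assert sensitivity >= 0.9
        assert res.table["delta_beta"].iloc[:100].mean() == pytest.approx(-0.30, abs=0.03)

    def test_delta_beta_reported_on_beta_scale(self):
        vals = np.array([[0.2, 0.5, 0.3, 0.6, 0.25, 0.55]])
        bm = make_beta_matrix(vals)
        design = make_paired_design(3)
        res = paired_dmp(bm, design, moderated=False)
        assert res.table["delta_beta"].iloc[0] == pytest.approx(0.3, abs=1e-12)

    def test_zero_variance_probe_flagged_with_p_one(self):
        vals = np.vstack([np.full(8, 0.5), np.tile([0.3, 0.6], 4)])
        bm = make_beta_matrix(vals)
        res = paired_dmp(bm, make_paired_design(4), moderated=False)
        assert bool(res.table["flagged"].iloc[0])
        assert res.table["p_value"].iloc[0] == 1.0
        assert bool(res.table["flagged"].iloc[1])  # constant nonzero differences

    def test_adjusted_p_dominates_raw_p(self):
        bm, design = self._null_matrix(seed=3)
        res = paired_dmp(bm, design)
        assert (res.table["p_adjusted"] >= res.table["p_value"] - 1e-15).all()
        assert res.table["p_adjusted"].between(0, 1).all()

    def test_requires_two_pairs(self):
        bm = make_beta_matrix(np.full((3, 2), 0.5))
        with pytest.raises(ValueError, match="2 pairs"):
            paired_dmp(bm, make_paired_design(1))


class TestFindDMRs:
    def _planted(self, n_probes=400, n_pairs=8, seed=3):
        rng = np.random.default_rng(seed)
        prec = 50.0
        m = np.full(n_probes, 0.6)
        base = rng.beta(m[:, None] * prec, (1 - m[:, None]) * prec, (n_probes, n_pairs))
        m_on = m.copy()
        m_on[100:105] -= 0.30
        on = rng.beta(m_on[:, None] * prec, (1 - m_on[:, None]) * prec, (n_probes, n_pairs))
        vals = np.empty((n_probes, 2 * n_pairs))
        vals[:, ::2], vals[:, 1::2] = base, on
        return make_beta_matrix(vals), make_paired_design(n_pairs)

    def test_planted_region_recovered_significant(self):
        bm, design = self._planted()
        res = find_dmrs(bm, design, seed=0)
        assert len(res.table) >= 1
        top = res.table.iloc[0]
        assert top["n_probes"] == 5
        assert top["p_adjusted"] < 0.05
        assert top["mean_delta_beta"] == pytest.approx(-0.30, abs=0.05)
        # exact null enumeration for 8 pairs: resolution 1/256
        assert res.n_permutations == 256
        assert top["p_value"] >= 1 / 256 - 1e-12
        assert (round(top["p_value"] * 256) - top["p_value"] * 256) == pytest.approx(0, abs=1e-9)

    def test_region_coordinates_are_1_based_closed(self):
        bm, design = self._planted()
        res = find_dmrs(bm, design, seed=0)
        top = res.table.iloc[0]
        ann = bm.annotation
        assert top["start"] == ann["pos"].iloc[100]
        assert top["end"] == ann["pos"].iloc[104]
        assert top["start"] <= top["end"]

    def test_single_extreme_probe_not_reported(self):
        vals = np.full((50, 16), 0.6)
        vals[25, 1::2] = 0.2  # one isolated probe, large shift
        bm = make_beta_matrix(vals)
        res = find_dmrs(bm, make_paired_design(8), min_probes=3, seed=0)
        assert (res.table["n_probes"] >= 3).all() if len(res.table) else True
        assert len(res.table) == 0

    def test_cluster_gap_breaks_regions(self):
        vals = np.full((10, 8), 0.6)
        vals[3:7, 1::2] = 0.3
        bm = make_beta_matrix(vals, spacing=200)
        # widen one gap beyond max_gap_bp so the run splits into 2+2
        bm.annotation.loc[bm.annotation.index[5:], "pos"] += 5_000
        res = find_dmrs(bm, make_paired_design(4), min_probes=3, seed=0)
        assert len(res.table) == 0  # neither half reaches 3 probes

    def test_unsorted_annotation_rejected(self):
        bm, design = self._planted(n_probes=20)
        bm.annotation["pos"] = bm.annotation["pos"].to_numpy()[::-1].copy()
        with pytest.raises(ValueError, match="sorted"):
            find_dmrs(bm, design, seed=0)

    def test_null_matrix_rarely_yields_significant_regions(self):
        rng = np.random.default_rng(9)
        prec = 50.0
        m = np.full(2000, 0.5)
        vals = rng.beta(m[:, None] * prec, (1 - m[:, None]) * prec, (2000, 16))
        bm = make_beta_matrix(vals)
        res = find_dmrs(bm, make_paired_design(8), seed=0)
        n_candidates = len(res.table)
        n_sig = int((res.table["p_adjusted"] < 0.05).sum()) if n_candidates else 0
        assert n_sig <= max(1, int(0.05 * n_candidates))


class TestPromoterStatistics:
    def test_promoter_delta_is_mean_over_promoter_probes(self):
        vals = np.array([[0.5, 0.3], [0.5, 0.1], [0.5, 0.5]])
        bm = make_beta_matrix(vals, region="TSS200", gene="GENE1")
        bm.annotation.loc["cg000001", "region"] = "5UTR"
        bm.annotation.loc["cg000002", "region"] = "Body"
        design = make_paired_design(1)
        out = promoter_delta(bm, design)
        assert out.loc["GENE1", "P0"] == pytest.approx((-0.2 - 0.4) / 2)

    def test_gene_without_promoter_probes_absent(self):
        bm = make_beta_matrix(np.full((2, 2), 0.5), region="Body", gene="GENE9")
        out = promoter_delta(bm, make_paired_design(1))
        assert "GENE9" not in out.index

    def test_identical_pairs_give_zero_deltas(self):
        rng = np.random.default_rng(2)
        half = rng.uniform(0.2, 0.8, (10, 1))
        vals = np.repeat(half, 2, axis=1)
        bm = make_beta_matrix(vals, region="TSS200", gene="G")
        out = promoter_delta(bm, make_paired_design(1))
        assert np.allclose(out.to_numpy(), 0.0)

    @pytest.mark.parametrize(
        "z,expected_z,expected_p",
        [
            ([2.0, 2.0, 2.0, 2.0], 4.0, None),
            ([0.0, 0.0], 0.0, 1.0),
            ([1.959964], 1.959964, 0.05),
        ],
    )
    def test_gene_level_z_stouffer(self, z, expected_z, expected_p):
        probe_z = pd.Series(z, index=[f"p{i}" for i in range(len(z))])
        genes = pd.Series("G1", index=probe_z.index)
        out = gene_level_z(probe_z, genes)
        assert out.loc["G1", "z"] == pytest.approx(expected_z, abs=1e-6)
        assert out.loc["G1", "n_cpg"] == len(z)
        if expected_p is not None:
            assert out.loc["G1", "p_value"] == pytest.approx(expected_p, abs=1e-6)

    def test_gene_level_z_null_is_standard_normal(self):
        rng = np.random.default_rng(5)
        sizes = rng.integers(1, 9, 10_000)
        genes = np.repeat([f"g{i}" for i in range(10_000)], sizes)
        z = pd.Series(rng.normal(size=len(genes)), index=[f"p{i}" for i in range(len(genes))])
        out = gene_level_z(z, pd.Series(genes, index=z.index))
        typeI = (out["p_value"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(out))
        assert abs(typeI - 0.05) < 2 * se
        assert stats.kstest(out["z"], "norm").pvalue > 0.01

    def test_standardize_promoter_deltas_centers_and_scales(self):
        rng = np.random.default_rng(6)
        tab = pd.DataFrame(rng.normal(0.1, 0.2, (500, 3)), columns=list("ABC"))
        z = standardize_promoter_deltas(tab)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)


class TestGlobalSummary:
    def _shifted(self, delta):
        vals = np.empty((100, 4))
        vals[:, 0] = vals[:, 2] = 0.6
        vals[:, 1] = vals[:, 3] = 0.6 + delta
        return make_beta_matrix(vals, region="TSS200", gene="G"), make_paired_design(2)

    def test_all_probes_shifted_past_cut(self):
        bm, design = self._shifted(-0.30)
        out = global_methylation_summary(bm, design)
        assert (out["frac_probes_decreased"] == 1.0).all()
        assert out["global_decrease"].all()

    def test_shift_below_cut_not_counted_but_flagged_decrease(self):
        bm, design = self._shifted(-0.20)
        out = global_methylation_summary(bm, design)
        assert (out["frac_probes_decreased"] == 0.0).all()  # strict > 0.25
        assert out["global_decrease"].all()

    def test_identical_pairs(self):
        bm, design = self._shifted(0.0)
        out = global_methylation_summary(bm, design)
        assert (out["frac_probes_decreased"] == 0.0).all()
        assert not out["global_decrease"].any()
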