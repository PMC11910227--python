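"""Endpoint rules, exact rank-sum test, H-score, NLR and survival summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from epimmune.biomarkers import (
    assess_bed,
    call_molecular_responders,
    h_score,
    km_curve,
    nlr,
    nlr_cohort_summary,
    tsg_hyper_dmps,
    tsg_reversal,
    wilcoxon_exact,
)


class TestResponderCall:
    @pytest.mark.parametrize(
        "ifng,cd274,expected",
        [
            (3.5, 2.8, True),   # both strictly above 2
            (2.0, 2.5, False),  # boundary on one -> strict rule fails
            (2.5, 1.9, False),  # conjunction
            (2.01, 2.01, True),
        ],
    )
    def test_conjunction_rule(self, ifng, cd274, expected):
        calls = call_molecular_responders(
            pd.Series({"P1": ifng}), pd.Series({"P1": cd274})
        )
        assert bool(calls.loc["P1", "responder"]) is expected

    def test_disjunction_option(self):
        calls = call_molecular_responders(
            pd.Series({"P1": 2.5}), pd.Series({"P1": 1.0}), require_both=False
        )
        assert bool(calls.loc["P1", "responder"])

    def test_missing_fold_change_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            call_molecular_responders(
                pd.Series({"P1": 3.0, "P2": np.nan}), pd.Series({"P1": 3.0, "P2": 3.0})
            )

    def test_brute_force_equivalence_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1_000):
            n = rng.integers(2, 10)
            ifng = pd.Series(rng.uniform(0, 5, n), index=[f"P{i}" for i in range(n)])
            cd274 = pd.Series(rng.uniform(0, 5, n), index=ifng.index)
            calls = call_molecular_responders(ifng, cd274)
            for p in ifng.index:
                assert calls.loc[p, "responder"] == ((ifng[p] > 2) and (cd274[p] > 2))


class TestBED:
    @pytest.mark.parametrize(
        "decreases,expected",
        [
            ([0.12, 0.15, 0.08, 0.11], True),   # 3/4 qualifying
            ([0.09, 0.09, 0.09, 0.20], False),  # 1/4
            ([0.10, 0.05], True),               # 1/2 = 50%, both thresholds inclusive
        ],
    )
    def test_rule_single_dose(self, decreases, expected):
        dec = pd.Series(decreases, index=[f"P{i}" for i in range(len(decreases))])
        dose = pd.Series("5day", index=dec.index)
        out = assess_bed(dec, dose)
        assert bool(out.loc["5day", "bed_met"]) is expected

    def test_doses_assessed_separately(self):
        dec = pd.Series([0.2, 0.2, 0.01, 0.01], index=list("abcd"))
        dose = pd.Series(["5day", "5day", "10day", "10day"], index=list("abcd"))
        out = assess_bed(dec, dose)
        assert bool(out.loc["5day", "bed_met"]) and not bool(out.loc["10day", "bed_met"])

    def test_brute_force_equivalence_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(1_000):
            n = rng.integers(2, 12)
            dec = pd.Series(rng.uniform(-0.2, 0.4, n), index=[f"P{i}" for i in range(n)])
            dose = pd.Series(rng.choice(["5day", "10day"], n), index=dec.index)
            out = assess_bed(dec, dose)
            for d in out.index:
                members = dec[dose == d]
                q = sum(1 for v in members if v >= 0.10)
                assert out.loc[d, "n_qualifying"] == q
                assert bool(out.loc[d, "bed_met"]) == (q / len(members) >= 0.5)


class TestTSG:
    def test_hyper_dmp_rule(self):
        tab = pd.DataFrame(
            {
                "gene": ["T1", "T2", "T3", "N1"],
                "delta_beta": [0.15, 0.08, -0.15, 0.30],
                "fdr": [0.01, 0.001, 0.01, 0.001],
            }
        )
        out = tsg_hyper_dmps(tab, ["T1", "T2", "T3"])
        assert out == ["T1"]  # hyper only, delta >= 0.10, FDR < 0.05, TSG only

    @pytest.mark.parametrize(
        "delta,fc,counted",
        [(-0.30, 2.5, 1), (-0.20, 3.0, 0), (-0.30, 2.0, 0), (-0.25, 2.5, 0)],
    )
    def test_reversal_strict_thresholds(self, delta, fc, counted):
        pd_tab = pd.DataFrame({"P1": [delta]}, index=["T1"])
        fc_tab = pd.DataFrame({"P1": [fc]}, index=["T1"])
        res = tsg_reversal(["T1"], pd_tab, fc_tab)
        assert res.per_participant.loc["P1", "n_reversed"] == counted

    def test_brute_force_equivalence_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(1_000):
            genes = [f"T{i}" for i in range(rng.integers(1, 15))]
            pd_tab = pd.DataFrame({"P1": rng.uniform(-0.5, 0.2, len(genes))}, index=genes)
            fc_tab = pd.DataFrame({"P1": rng.uniform(0.5, 4, len(genes))}, index=genes)
            res = tsg_reversal(genes, pd_tab, fc_tab)
            expected = sum(
                1 for g in genes if pd_tab.loc[g, "P1"] < -0.25 and fc_tab.loc[g, "P1"] > 2
            )
            assert res.per_participant.loc["P1", "n_reversed"] == expected

    def test_planted_reversals_recovered_in_synthetic_responders(self, small_cohort, small_design):
        from epimmune.containers import CountMatrix
        from epimmune.expression import paired_fold_change, rpkm
        from epimmune.methylation import promoter_delta

        pd_tab = promoter_delta(small_cohort.beta, small_design)
        fc = paired_fold_change(
            rpkm(CountMatrix(small_cohort.counts, small_cohort.gene_lengths)), small_design
        )
        res = tsg_reversal(small_cohort.truth["planted_reversed_tsgs"], pd_tab, fc)
        n_planted = len(small_cohort.truth["planted_reversed_tsgs"])
        for part in small_cohort.truth["responders"]:
            assert res.per_participant.loc[part, "n_reversed"] >= 0.75 * n_planted
        others = [p for p in res.per_participant.index if p not in small_cohort.truth["responders"]]
        assert res.per_participant.loc[others, "n_reversed"].max() == 0


class TestNLR:
    @pytest.mark.parametrize("n,l,expected", [(10, 2, 5.0), (8.5, 0.1, 85.0), (0, 1, 0.0)])
    def test_ratio(self, n, l, expected):
        assert nlr(n, l) == pytest.approx(expected)

    def test_zero_lymphocytes_missing(self):
        out = nlr(np.array([5.0, 5.0]), np.array([1.0, 0.0]))
        assert out[0] == 5.0 and np.isnan(out[1])

    def test_cohort_summary_available_case(self):
        clin = pd.DataFrame(
            {
                "neutrophils_baseline": [10.0, 8.0, 6.0],
                "lymphocytes_baseline": [1.0, 2.0, 1.0],
                "neutrophils_last": [5.0, 4.0, 6.0],
                "lymphocytes_last": [1.0, 2.0, 0.0],  # last record undefined
            }
        )
        out = nlr_cohort_summary(clin)
        assert out.loc["baseline", "n"] == 3
        assert out.loc["last_cycle", "n"] == 2
        assert out.loc["baseline", "mean"] == pytest.approx((10 + 4 + 6) / 3)


class TestHScore:
    @pytest.mark.parametrize(
        "pcts,expected",
        [
            ({0: 0, 1: 0, 2: 0, 3: 100}, 300.0),
            ({0: 100, 1: 0, 2: 0, 3: 0}, 0.0),
            ({0: 0, 1: 50, 2: 50, 3: 0}, 150.0),
        ],
    )
    def test_known_scores(self, pcts, expected):
        assert h_score(pcts) == expected

    def test_percentages_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum to 100"):
            h_score({0: 50, 1: 10, 2: 10, 3: 10})

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=4, max_size=4).filter(
            lambda w: sum(w) > 1e-6
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_linear_and_bounded(self, weights):
        pct = 100 * np.array(weights) / sum(weights)
        pct[0] = 100 - pct[1:].sum()
        score = h_score(dict(enumerate(pct)))
        assert 0 <= score <= 300
        assert score == pytest.approx(pct[1] + 2 * pct[2] + 3 * pct[3], abs=1e-9)

    def test_brute_force_equivalence_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(1_000):
            pct = 100 * rng.dirichlet(np.ones(4))
            pct[0] = 100 - pct[1:].sum()
            assert h_score(dict(enumerate(pct))) == pytest.approx(
                sum(i * pct[i] for i in range(4)), abs=1e-9
            )


class TestWilcoxonExact:
    def test_extreme_3v5_configuration(self):
        res = wilcoxon_exact([3.5, 3.4, 3.6], [0.8, 0.7, 0.9, 0.75, 0.85])
        assert res["exact"]
        assert res["p_value"] == pytest.approx(2 / 56)

    def test_symmetric_groups(self):
        assert wilcoxon_exact([1, 2], [1, 2])["p_value"] == pytest.approx(1.0)

    def test_single_observations(self):
        assert wilcoxon_exact([2], [1])["p_value"] == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = rng.normal(size=rng.integers(1, 6))
            b = rng.normal(size=rng.integers(1, 6))
            mine = wilcoxon_exact(a, b)["p_value"]
            ref = mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_matches_full_enumeration_oracle_with_ties(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(5)
        for _ in range(20):
            na, nb = int(rng.integers(2, 5)), int(rng.integers(2, 6))
            pool = rng.choice([0.0, 1.0, 2.0, 3.0], size=na + nb)  # heavy ties
            a, b = pool[:na], pool[na:]
            res = wilcoxon_exact(a, b)
            ranks = rankdata(pool)
            mean_w = na * ranks.sum() / (na + nb)
            obs = abs(ranks[:na].sum() - mean_w)
            hits = total = 0
            for comb in itertools.combinations(range(na + nb), na):
                total += 1
                if abs(ranks[list(comb)].sum() - mean_w) >= obs - 1e-9:
                    hits += 1
            assert res["p_value"] == pytest.approx(hits / total, abs=1e-12)

    def test_large_samples_fall_back_to_normal_approximation(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=20)
        res = wilcoxon_exact(a, b)
        assert not res["exact"]
        ref = mannwhitneyu(a, b, method="asymptotic", alternative="two-sided", use_continuity=False).pvalue
        assert res["p_value"] == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_exact([], [1.0])


class TestKaplanMeier:
    def test_step_function_and_median(self):
        out = km_curve([1.0, 2.0, 3.0], [True, True, True])
        s = out["survival"]["KM_estimate"]
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[2.0] == pytest.approx(1 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)
        assert out["median"] == 2.0

    def test_all_censored_median_missing(self):
        out = km_curve([5.0, 6.0, 7.0], [False, False, False])
        assert out["median"] is None

    def test_exponential_cohort_median_matches_closed_form(self):
        rng = np.random.default_rng(7)
        lam = 1.0 / 12.0
        times = rng.exponential(1 / lam, size=500)
        out = km_curve(times, np.ones(500, dtype=bool), rate_at=24.0)
        assert out["median"] == pytest.approx(np.log(2) / lam, rel=0.10)
        assert out["rate"]["ci"][0] <= out["rate"]["survival"] <= out["rate"]["ci"][1]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [True, True])
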