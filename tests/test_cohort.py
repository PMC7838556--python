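"""Exclusion ledger, descriptives, logistic ORs, ROC, T-stage subgroups."""

import numpy as np
import pandas as pd
import pytest

from ptsscore import (
    CohortSpec, apply_exclusions, derive_anyi, logistic_univariate, make_cohort,
    roc_auc, subgroup_by_tstage, table1_descriptives,
)
from ptsscore.synthetic import make_exclusion_records

from .oracles import chi_square_statistic, cross_product_or, trapezoid_auc

# 2x2 contingency of lymphatic invasion vs nodal metastasis used in the
# worked examples: (LI yes & LNM+, LI yes & LNM-, LI no & LNM+, LI no & LNM-)
LI_LNM = {"yes_pos": 42, "yes_neg": 11, "no_pos": 22, "no_neg": 79}


def li_lnm_frame():
    rows = []
    for key, n in LI_LNM.items():
        li, lnm = key.split("_")
        rows += [{"li": 1 if li == "yes" else 0, "lnm": 1 if lnm == "pos" else 0}] * n
    return pd.DataFrame(rows)


class TestExclusions:
    def test_published_counts_yield_164(self):
        records = make_exclusion_records(591, 153, 210, 64, seed=0)
        kept, ledger = apply_exclusions(records)
        assert ledger == {"rectal": 153, "inadequate_image": 210, "distant_metastasis": 64}
        assert len(kept) == 164

    def test_no_flags_passes_everything_through(self):
        records = pd.DataFrame({"patient_id": list("abc")})
        kept, ledger = apply_exclusions(records)
        assert len(kept) == 3 and all(v == 0 for v in ledger.values())

    def test_first_match_attribution(self):
        records = pd.DataFrame({
            "patient_id": ["x", "y"],
            "rectal": [True, False],
            "distant_metastasis": [True, False],
        })
        kept, ledger = apply_exclusions(records)
        assert ledger["rectal"] == 1 and ledger["distant_metastasis"] == 0
        assert list(kept["patient_id"]) == ["y"]

    def test_ledger_conservation(self):
        records = make_exclusion_records(200, 31, 17, 5, seed=3)
        kept, ledger = apply_exclusions(records)
        assert len(records) == len(kept) + sum(ledger.values())


class TestDeriveAnyi:
    @pytest.mark.parametrize("li,pi,vi,expected", [
        ("yes", np.nan, "no", "yes"),
        ("no", "no", "no", "no"),
        ("no", np.nan, "no", np.nan),
        (np.nan, np.nan, np.nan, np.nan),
        ("no", "no", "yes", "yes"),
    ])
    def test_truth_table(self, li, pi, vi, expected):
        result = derive_anyi(li, pi, vi)
        if pd.isna(expected):
            assert pd.isna(result)
        else:
            assert result == expected

    def test_vectorized_matches_scalar(self):
        coh = make_cohort(CohortSpec(n=500), seed=0)
        vec = derive_anyi(coh["li"], coh["pi"], coh["vi"])
        for i in range(0, 500, 37):
            scalar = derive_anyi(coh["li"][i], coh["pi"][i], coh["vi"][i])
            assert (pd.isna(vec[i]) and pd.isna(scalar)) or vec[i] == scalar


class TestTable1:
    def cohort_with_printed_li_counts(self):
        df = li_lnm_frame()
        return pd.DataFrame({
            "lnm": df["lnm"].astype(bool),
            "li": df["li"].map({1: "yes", 0: "no"}),
            "pts_score": np.linspace(0, 1, len(df)),
            "age": np.tile([60, 61, 70, 72], len(df) // 4 + 1)[: len(df)],
        })

    def test_group_shares_and_feature_percentages(self):
        coh = self.cohort_with_printed_li_counts()
        out = table1_descriptives(coh, continuous=("age",), categorical=("li",))
        n_neg, n_pos = out["n"]["lnm_negative"], out["n"]["lnm_positive"]
        assert (n_neg, n_pos) == (90, 64)
        li_yes = out["li"]["levels"]["yes"]
        assert li_yes["lnm_positive"]["count"] == 42
        assert li_yes["lnm_positive"]["pct"] == round(100 * 42 / 64, 1)

    def test_chi_square_matches_textbook_formula(self):
        from scipy import stats

        table = np.array([[11, 42], [79, 22]])
        stat, _, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(chi_square_statistic(table), rel=1e-12)
        coh = self.cohort_with_printed_li_counts()
        out = table1_descriptives(coh, continuous=(), categorical=("li",))
        p_ref = stats.chi2.sf(chi_square_statistic(table), 1)
        assert out["li"]["p_value"] == pytest.approx(p_ref, rel=1e-9)

    def test_na_rows_displayed_but_excluded_from_test(self):
        coh = self.cohort_with_printed_li_counts()
        coh.loc[coh.index[:10], "li"] = np.nan
        out = table1_descriptives(coh, continuous=(), categorical=("li",))
        assert "NA" in out["li"]["levels"]
        counts = out["li"]["levels"]
        total = sum(
            counts[level][g]["count"]
            for level in counts for g in ("lnm_negative", "lnm_positive")
        )
        assert total == len(coh)

    def test_zero_variance_continuous_warns_with_nan_p(self):
        coh = self.cohort_with_printed_li_counts()
        coh["age"] = 65.0
        with pytest.warns(UserWarning, match="zero variance"):
            out = table1_descriptives(coh, continuous=("age",), categorical=())
        assert np.isnan(out["age"]["p_value"])

    def test_requires_both_groups(self):
        coh = self.cohort_with_printed_li_counts()
        with pytest.raises(ValueError, match="nonempty"):
            table1_descriptives(coh[coh["lnm"]], continuous=(), categorical=("li",))


class TestLogistic:
    def test_binary_predictor_or_equals_cross_product_ratio(self):
        df = li_lnm_frame()
        res = logistic_univariate(df["li"], df["lnm"])
        expected = cross_product_or(LI_LNM["yes_pos"], LI_LNM["no_pos"],
                                    LI_LNM["yes_neg"], LI_LNM["no_neg"])
        assert res.odds_ratio == pytest.approx(expected, rel=5e-4)  # 4 s.f.
        assert res.ci_lower <= res.odds_ratio <= res.ci_upper
        assert res.p_value < 1e-6

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_univariate([1.0] * 20, [0, 1] * 10)

    def test_single_outcome_level_rejected(self):
        with pytest.raises(ValueError, match="both outcome levels"):
            logistic_univariate(np.arange(10.0), np.ones(10))

    def test_complete_separation_flagged_not_silent(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.warns(UserWarning, match="separation"):
            res = logistic_univariate(x, y)
        assert res.separation
        assert res.ci_upper == np.inf

    def test_na_pairs_dropped_listwise(self):
        x = np.array([0.0, 1.0, np.nan, 1.0, 0.0] * 8)
        y = np.array([0, 1, 1, 0, 1] * 8)
        res = logistic_univariate(x, y)
        assert res.n == 32

    def test_wald_ci_coverage_on_simulated_cohorts(self):
        spec = CohortSpec(n=2000, beta0=-1.5, beta1=3.0)
        covered = 0
        n_rep = 60  # quick check at loose bounds; the acceptance suite runs 200
        for rep in range(n_rep):
            coh = make_cohort(spec, seed=50_000 + rep)
            res = logistic_univariate(coh["pts_score"], coh["lnm"].astype(int))
            lo, hi = np.log(res.ci_lower), np.log(res.ci_upper)
            covered += lo <= 3.0 <= hi
        assert 0.85 <= covered / n_rep <= 1.0


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_independent_labels_give_half(self):
        rng = np.random.default_rng(7)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.03)
        assert res.ci_lower <= res.auc <= res.ci_upper

    def test_rank_sum_equals_trapezoid_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            scores = np.round(rng.normal(size=n), 1)  # ties included
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            ours = roc_auc(scores, labels).auc
            assert ours == pytest.approx(trapezoid_auc(scores, labels), abs=1e-10)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.3
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_label_flip_and_monotone_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.random(200)
        labels = rng.random(200) < 0.5
        a = roc_auc(scores, labels).auc
        assert roc_auc(scores, ~labels).auc == pytest.approx(1.0 - a, abs=1e-12)
        assert roc_auc(np.exp(3 * scores), labels).auc == pytest.approx(a, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestSubgroups:
    def test_all_late_stage_leaves_early_stratum_na(self):
        coh = make_cohort(CohortSpec(n=120, t_stage_probs=(0, 0, 0, 0.8, 0.2)), seed=1)
        report = subgroup_by_tstage(coh)
        assert report["T0-T2"]["n"] == 0
        assert report["T0-T2"]["li"]["logistic"] is None
        assert report["T3-T4"]["n"] == 120

    def test_strata_partition_cohort(self):
        coh = make_cohort(CohortSpec(n=300), seed=2)
        report = subgroup_by_tstage(coh)
        assert report["T0-T2"]["n"] + report["T3-T4"]["n"] == 300

    def test_effect_only_in_late_stratum_detected(self):
        rng = np.random.default_rng(11)
        n = 2000
        pts = rng.beta(1.5, 2.5, n)
        late = rng.random(n) < 0.5
        t_stage = np.where(late, "T3", "T2")
        from scipy.special import expit

        p = np.where(late, expit(-2.0 + 4.0 * pts), 0.25)
        li = np.where(rng.random(n) < p, "yes", "no")
        coh = pd.DataFrame({
            "t_stage": t_stage, "li": li, "pi": "no", "vi": "no",
            "pts_score": pts,
        })
        report = subgroup_by_tstage(coh, outcomes=("li",))
        late_fit = report["T3-T4"]["li"]["logistic"]
        early_fit = report["T0-T2"]["li"]["logistic"]
        assert late_fit["ci_lower"] > 1.0 and late_fit["p_value"] < 0.001
        assert early_fit["p_value"] > 0.01  # no effect where none was planted
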