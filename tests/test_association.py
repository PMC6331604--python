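from math import comb

import numpy as np
import pandas as pd
import pytest

from apscore import association as assoc
from apscore.association import (
    AssociationError,
    anova_oneway,
    combine_predictors,
    compare_cnv,
    compare_mutation_freq,
    contingency_test,
    correlate_genes_with_score,
    immune_ssgsea_association,
    label_outcomes,
    paired_t,
    pearson_corr,
    roc_auc_outcome,
)
from apscore.data_io import CohortClinical, ExpressionMatrix, GeneSet, MutationTable
from apscore.scoring import ap_score
from apscore.survival import dichotomize_by_median
from apscore.synthetic import SyntheticConfig, generate_cohort


def fisher_oracle_2x2(a, b, c, d):
    """Two-sided Fisher by hypergeometric enumeration: sum of table
    probabilities <= that of the observed table."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestANOVA:
    def test_hand_example(self):
        from scipy.stats import f as fdist

        res = anova_oneway([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(16.0)
        assert res.p == pytest.approx(float(fdist.sf(16.0, 2, 3)))

    def test_identical_means(self):
        res = anova_oneway([[1, 2], [1, 2], [2, 1]])
        assert res.statistic == pytest.approx(0.0)

    def test_two_groups_equals_pooled_t_squared(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        res = anova_oneway([a, b])
        t, _ = ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2)

    def test_degenerate_all_equal(self):
        res = anova_oneway([[2, 2], [2, 2]])
        assert res.statistic == 0.0 and res.p == 1.0


class TestContingency:
    def test_fisher_hand_example(self):
        res = contingency_test([[2, 0], [0, 2]])
        assert res.test == "fisher"
        assert res.p == pytest.approx(1 / 3)

    def test_balanced_chi2(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        tab = np.array([[8, 3], [2, 9]])
        assert contingency_test(tab).p == pytest.approx(contingency_test(tab.T).p)

    def test_fisher_vs_enumeration_all_small_tables(self):
        # every 2x2 with total n <= 12 and nonzero margins
        count = 0
        for a in range(13):
            for b in range(13 - a):
                for c in range(13 - a - b):
                    for d in range(13 - a - b - c):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        res = contingency_test([[a, b], [c, d]], method="fisher")
                        assert res.p == pytest.approx(
                            fisher_oracle_2x2(a, b, c, d), abs=1e-9
                        ), (a, b, c, d)
                        count += 1
        assert count > 400

    def test_zero_margin_error(self):
        with pytest.raises(AssociationError):
            contingency_test([[0, 0], [1, 2]])

    def test_non_integer_rejected(self):
        with pytest.raises(AssociationError):
            contingency_test([[1.5, 2], [3, 4]])


class TestPearsonPaired:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_r(self):
        assert pearson_corr([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(0.5)

    def test_constant_error(self):
        with pytest.raises(AssociationError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_paired_t_hand(self):
        res = paired_t([2, 2, 2, 4], [1, 1, 1, 1])
        assert res.statistic == pytest.approx(3.0)
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(float(2 * tdist.sf(3.0, 3)))

    def test_paired_t_zero_variance(self):
        with pytest.raises(AssociationError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_paired_t_swap_negates(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)


def make_clinical(times, events):
    n = len(times)
    rows = []
    for i, (t, e) in enumerate(zip(times, events)):
        rows.append(
            {
                "sample_id": f"s{i}",
                "tissue_group": "GBM",
                "os_days": float(t),
                "event": int(e),
                "age": 50,
                "gender": "M",
                "grade": "IV",
                "idh": "wildtype",
                "mgmt": "methylated",
                "subtype": "CL",
                "chemo": "yes",
                "radio": "yes",
            }
        )
    return CohortClinical(pd.DataFrame(rows))


class TestROC:
    def test_labelling_rule(self):
        # mean OS over deceased = (100+300)/2 = 200
        clin = make_clinical([100, 300, 150, 250], [1, 1, 0, 0])
        labels, mean_os, n_excl = label_outcomes(clin.table)
        assert mean_os == 200
        assert labels["s0"] == 1  # died early
        assert labels["s1"] == 0  # survived past mean OS (even though died)
        assert np.isnan(labels["s2"])  # censored short: indeterminate
        assert labels["s3"] == 0
        assert n_excl == 1

    def test_perfect_auc(self):
        clin = make_clinical([100, 120, 300, 350], [1, 1, 0, 0])
        scores = pd.Series([0.9, 0.8, 0.7, 0.6], index=[f"s{i}" for i in range(4)])
        assert roc_auc_outcome(scores, clin).auc == pytest.approx(1.0)

    def test_quarter_auc(self):
        clin = make_clinical([100, 300, 120, 350], [1, 1, 1, 1])
        # labels: s0 +, s1 -, s2 +, s3 - ; scores 1,2,3,4 -> 1 of 4 pairs concordant
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        assert roc_auc_outcome(scores, clin).auc == pytest.approx(0.25)

    def test_negation_complement(self):
        rng = np.random.default_rng(2)
        n = 40
        t = rng.integers(50, 400, n)
        e = rng.integers(0, 2, n)
        e[:4] = 1
        clin = make_clinical(t, e)
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        a = roc_auc_outcome(scores, clin).auc
        b = roc_auc_outcome(-scores, clin).auc
        assert a + b == pytest.approx(1.0)

    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            t = rng.integers(10, 500, n)
            e = rng.integers(0, 2, n)
            clin = make_clinical(t, e)
            scores = pd.Series(
                np.round(rng.normal(size=n), 1), index=[f"s{i}" for i in range(n)]
            )
            try:
                res = roc_auc_outcome(scores, clin)
            except AssociationError:
                continue
            labels, _, _ = label_outcomes(clin.table)
            keep = labels.dropna()
            pos = scores[keep[keep == 1].index].to_numpy()
            neg = scores[keep[keep == 0].index].to_numpy()
            total = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert res.auc == pytest.approx(total / (len(pos) * len(neg)), abs=1e-12)

    def test_one_class_empty_error(self):
        # mean OS = 100; no death strictly before it -> zero positives
        clin = make_clinical([100, 100], [1, 1])
        scores = pd.Series([1.0, 2.0], index=["s0", "s1"])
        with pytest.raises(AssociationError, match="degenerate"):
            roc_auc_outcome(scores, clin)


class TestCombinePredictors:
    def test_constant_second_factor_preserves_auc(self):
        rng = np.random.default_rng(4)
        n = 200
        a = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-a))).astype(float)
        lp, _ = combine_predictors(y, a, np.zeros(n) + 1.0)
        # linear predictor is monotone in a -> same ranking
        assert np.corrcoef(np.argsort(np.argsort(lp)), np.argsort(np.argsort(a)))[0, 1] > 0.999

    def test_null_auc_half(self):
        rng = np.random.default_rng(5)
        n = 500
        y = rng.integers(0, 2, n).astype(float)
        lp, sep = combine_predictors(y, rng.normal(size=n), rng.normal(size=n))
        pos, neg = lp[y == 1], lp[y == 0]
        auc = np.mean([(pos[:, None] > neg).mean() + 0.5 * (pos[:, None] == neg).mean()])
        assert abs(auc - 0.5) < 0.08 and not sep

    def test_in_sample_combined_beats_singles(self, default_cohort, truth_scores):
        c = default_cohort
        tum = c.clinical.tumour_samples()
        clin = c.clinical.table.set_index("sample_id").loc[tum]
        labels, _, _ = label_outcomes(clin.reset_index())
        keep = labels.dropna()
        ap = truth_scores.as_series().loc[keep.index].to_numpy()
        idh = (clin.loc[keep.index, "idh"] == "wildtype").to_numpy(float)
        y = keep.to_numpy()

        def auc_of(score):
            pos, neg = score[y == 1], score[y == 0]
            return (
                (pos[:, None] > neg).mean() + 0.5 * (pos[:, None] == neg).mean()
            )

        lp, _ = combine_predictors(y, ap, idh)
        assert auc_of(lp) >= max(auc_of(ap), auc_of(idh)) - 0.01


@pytest.fixture(scope="module")
def labelled():
    c = generate_cohort(SyntheticConfig(n_lgg=260, n_gbm=140, seed=3))
    scores = ap_score(c.expression, c.truth).as_series()
    tum = c.latent.index
    labels = pd.Series(dichotomize_by_median(scores.loc[tum].to_numpy()), index=tum)
    return c, labels


class TestGenomicComparisons:
    def test_mutation_directions(self, labelled):
        c, labels = labelled
        res = compare_mutation_freq(c.mutations, labels).set_index("gene")
        for g in ("IDH1", "TP53", "ATRX"):
            assert res.loc[g, "enriched_in"] == "low" and res.loc[g, "q"] < 0.05
        for g in ("PTEN", "EGFR"):
            assert res.loc[g, "enriched_in"] == "high" and res.loc[g, "q"] < 0.05

    def test_mutation_everywhere_is_null(self):
        samples = [f"s{i}" for i in range(10)]
        mt = MutationTable(
            pd.DataFrame({"sample_id": samples, "gene": "X", "mutated": True})
        )
        labels = pd.Series(["high"] * 5 + ["low"] * 5, index=samples)
        res = compare_mutation_freq(mt, labels)
        assert res.loc[0, "p"] == 1.0

    def test_mutation_label_permutation_null(self):
        rng = np.random.default_rng(6)
        c, labels = generate_cohort(SyntheticConfig(n_lgg=60, n_gbm=40, seed=9)), None
        ps = []
        for _ in range(10):
            perm = pd.Series(
                rng.permutation(np.repeat(["high", "low"], 50)), index=c.latent.index
            )
            res = compare_mutation_freq(c.mutations, perm)
            ps.extend(res["p"].tolist())
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_cnv_directions(self, labelled):
        c, labels = labelled
        res = compare_cnv(c.cnv, labels).set_index("gene")
        assert res.loc["EGFR", "mean_high"] > res.loc["EGFR", "mean_low"]
        assert res.loc["CDKN2A", "mean_high"] < res.loc["CDKN2A", "mean_low"]
        assert res.loc["EGFR", "q"] < 0.05 and res.loc["CDKN2A", "q"] < 0.05

    def test_cnv_label_swap(self, labelled):
        c, labels = labelled
        swapped = labels.map({"high": "low", "low": "high"})
        a = compare_cnv(c.cnv, labels).set_index("gene")
        b = compare_cnv(c.cnv, swapped).set_index("gene")
        np.testing.assert_allclose(a["mean_high"], b["mean_low"])
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_cnv_identical_groups_null(self):
        from apscore.data_io import CNVMatrix

        samples = [f"s{i}" for i in range(8)]
        vals = np.tile(np.array([[1.0, 2, 3, 4]]), (1, 2))
        cnv = CNVMatrix(["G"], samples, vals)
        labels = pd.Series(["high"] * 4 + ["low"] * 4, index=samples)
        res = compare_cnv(cnv, labels)
        assert res.loc[0, "p"] == pytest.approx(1.0)
        assert res.loc[0, "mean_high"] == res.loc[0, "mean_low"]


class TestCorrelateAndImmune:
    def test_planted_pos_gene_in_positive_set(self, default_cohort, truth_scores):
        c = default_cohort
        ap = truth_scores.as_series().loc[c.latent.index]
        expr = c.expression.subset_samples(list(c.latent.index))
        pos, neg, rmap = correlate_genes_with_score(expr, ap)
        assert len(pos & c.truth.pos.genes) >= 10
        assert len(neg & c.truth.neg.genes) >= 4

    def test_injected_score_r_one(self, default_cohort, truth_scores):
        c = default_cohort
        ap = truth_scores.as_series().loc[c.latent.index]
        m = ExpressionMatrix(
            ["pseudo"], list(c.latent.index), ap.to_numpy()[None, :]
        )
        _, _, rmap = correlate_genes_with_score(m, ap)
        assert rmap["pseudo"] == pytest.approx(1.0)

    def test_threshold_one_empty(self, default_cohort, truth_scores):
        c = default_cohort
        ap = truth_scores.as_series().loc[c.latent.index]
        expr = c.expression.subset_samples(list(c.latent.index))
        pos, neg, _ = correlate_genes_with_score(expr, ap, r_threshold=1.0)
        assert pos == set() and neg == set()

    def test_immune_report_shape_and_pos_ap_row(self, default_cohort, truth_scores):
        c = default_cohort
        ap = truth_scores.as_series()
        rng = np.random.default_rng(7)
        random_set = GeneSet(
            "RANDOM", frozenset(rng.choice(c.expression.gene_ids, 15, replace=False))
        )
        sets = [GeneSet("POSSELF", c.truth.pos.genes), random_set]
        rep = immune_ssgsea_association(c.expression, sets, ap, c.clinical)
        assert list(rep.columns) == ["set", "r", "r_p", "logrank_p"]
        assert len(rep) == 2
        r_pos = rep.set_index("set").loc["POSSELF", "r"]
        assert r_pos > 0.8
        assert abs(rep.set_index("set").loc["RANDOM", "r"]) < 0.6

    def test_immune_no_overlap_na_row(self, small_cohort):
        from apscore.scoring import ap_score as apf

        ap = apf(small_cohort.expression, small_cohort.truth).as_series()
        rep = immune_ssgsea_association(
            small_cohort.expression,
            [GeneSet("MISSING", frozenset({"NOT_A_GENE"}))],
            ap,
            small_cohort.clinical,
        )
        assert np.isnan(rep.loc[0, "r"]) and np.isnan(rep.loc[0, "logrank_p"])
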