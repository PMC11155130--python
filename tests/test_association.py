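"""Stage 3: categorical tests, prevalence, phi co-occurrence, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from wsdecipher.io_formats import ABSENT, PRESENT, UNRECORDED, CohortTable
from wsdecipher.association_analysis import (
    FISHER_EXACT,
    PEARSON_CHI2,
    distribution_summaries,
    fisher_exact,
    group_association_test,
    inheritance_association,
    pearson_chi2,
    phi_correlation,
    phi_matrix,
    prevalence,
    select_test,
    sex_difference_tests,
)
from wsdecipher.synthetic_data import exact_cohort


def cohort_from_cells(pairs, genes=None, sex=None):
    """Tiny cohort with two phenotype columns from explicit status pairs."""
    n = len(pairs)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "gene": genes if genes is not None else ["PAX3"] * n,
            "sex": sex if sex is not None else [UNRECORDED] * n,
            "ph_a": [p[0] for p in pairs],
            "ph_b": [p[1] for p in pairs],
        }
    )
    return CohortTable(
        data=df, phenotypes=["ph_a", "ph_b"], gene_vocabulary=frozenset(df["gene"])
    )


def fisher_oracle_2x2(a, b, c, d):
    """Exact-integer enumeration of all 2x2 tables with the observed margins."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    weights = {
        k: math.comb(c1, k) * math.comb(n - c1, r1 - k)
        for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
    }
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / math.comb(n, r1)


class TestPearsonChi2:
    def test_independent_table(self):
        s, df, p = pearson_chi2([[10, 10], [10, 10]])
        assert s == 0 and df == 1 and p == 1

    def test_perfect_association_statistic_equals_n(self):
        s, _, p = pearson_chi2([[20, 0], [0, 20]])
        assert s == pytest.approx(40) and p < 1e-9

    def test_random_2x3_matches_direct_formula(self):
        rng = np.random.default_rng(15)
        obs = rng.integers(1, 30, size=(2, 3)).astype(float)
        s, df, _ = pearson_chi2(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert s == pytest.approx(((obs - expected) ** 2 / expected).sum())
        assert df == 2
        # independent route: scipy's implementation without correction
        from scipy.stats import chi2_contingency

        ref = chi2_contingency(obs, correction=False)
        assert s == pytest.approx(ref.statistic) and ref.pvalue == pytest.approx(
            pearson_chi2(obs)[2]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 5]])


class TestFisherExact:
    def test_classic_table_against_enumeration(self):
        # frozen from the exact-integer enumeration oracle below
        assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(
            fisher_oracle_2x2(1, 9, 11, 3), abs=1e-12
        )
        assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(0.00275945618522, abs=1e-12)

    def test_symmetric_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_random_2x2_tables_match_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle_2x2(a, b, c, d), abs=1e-12
            )

    def test_random_2x3_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            obs = rng.integers(0, 8, size=(2, 3))
            if (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
                continue
            # brute force over all margin-consistent tables with exact integers
            r1 = int(obs[0].sum())
            cols = obs.sum(0)
            n = int(obs.sum())
            denom = math.comb(n, r1)
            weights = []
            w_obs = None
            for n11 in range(int(cols[0]) + 1):
                for n12 in range(int(cols[1]) + 1):
                    n13 = r1 - n11 - n12
                    if n13 < 0 or n13 > cols[2]:
                        continue
                    w = (
                        math.comb(int(cols[0]), n11)
                        * math.comb(int(cols[1]), n12)
                        * math.comb(int(cols[2]), n13)
                    )
                    weights.append(w)
                    if (n11, n12) == (int(obs[0, 0]), int(obs[0, 1])):
                        w_obs = w
            expect = sum(w for w in weights if w <= w_obs) / denom
            assert fisher_exact(obs) == pytest.approx(expect, abs=1e-12)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError, match="pearson_chi2"):
            fisher_exact([[3000, 10], [10, 10]])


class TestTestSelection:
    def test_small_expected_count_triggers_exact_test(self):
        # expected count for the smallest cell is 3.2 (< 5)
        obs = np.array([[2, 10, 10], [6, 20, 32]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert expected.min() < 5
        assert select_test(obs) == FISHER_EXACT

    def test_large_expected_counts_use_chi2(self):
        assert select_test(np.array([[20, 30], [25, 25]])) == PEARSON_CHI2


class TestPrevalence:
    def cohort(self):
        pairs = [(PRESENT, ABSENT)] * 345 + [(ABSENT, ABSENT)] * 63 + [
            (UNRECORDED, ABSENT)
        ] * 35
        return cohort_from_cells(pairs)

    def test_missing_aware_denominator(self):
        cell = prevalence(self.cohort(), "ph_a")
        assert (cell.n_present, cell.n_recorded) == (345, 408)
        assert round(100 * cell.proportion, 2) == 84.56
        assert cell.as_fraction_string() == "345/408 (84.56%)"

    def test_all_unrecorded_is_undefined(self):
        pairs = [(UNRECORDED, ABSENT)] * 5
        cell = prevalence(cohort_from_cells(pairs), "ph_a")
        assert cell.n_recorded == 0 and cell.proportion is None
        assert cell.as_fraction_string() == "NA"

    def test_stratum_prevalence(self):
        pairs = [(PRESENT, ABSENT)] * 18 + [(ABSENT, ABSENT)] * 32 + [(PRESENT, ABSENT)] * 7
        genes = ["SOX10"] * 50 + ["PAX3"] * 7
        cell = prevalence(cohort_from_cells(pairs, genes=genes), "ph_a", gene="SOX10")
        assert (cell.n_present, cell.n_recorded) == (18, 50)
        assert round(100 * cell.proportion, 2) == 36.00

    def test_unknown_phenotype_errors(self):
        with pytest.raises(KeyError):
            prevalence(self.cohort(), "nope")


class TestGroupAssociation:
    def test_stratum_without_records_dropped(self):
        pairs = [(PRESENT, ABSENT)] * 20 + [(ABSENT, ABSENT)] * 20 + [
            (UNRECORDED, ABSENT)
        ] * 5
        genes = ["PAX3"] * 20 + ["MITF"] * 20 + ["SOX10"] * 5
        res = group_association_test(cohort_from_cells(pairs, genes=genes), "ph_a")
        assert res.strata == ("PAX3", "MITF")

    def test_fewer_than_two_usable_strata_errors(self):
        pairs = [(PRESENT, ABSENT)] * 10
        with pytest.raises(ValueError):
            group_association_test(cohort_from_cells(pairs), "ph_a")

    def test_pairwise_tests_cover_all_pairs(self):
        rng = np.random.default_rng(18)
        genes = [str(g) for g in rng.choice(["PAX3", "MITF", "SOX10"], size=120)]
        pairs = [
            (PRESENT if rng.random() < 0.5 else ABSENT, ABSENT) for _ in range(120)
        ]
        res = group_association_test(cohort_from_cells(pairs, genes=genes), "ph_a")
        assert len(res.pairwise) == 3
        assert all(0 < p <= 1 for *_unused, p in res.pairwise)


class TestPhi:
    @staticmethod
    def cells_to_pairs(a, b, c, d):
        return (
            [(PRESENT, PRESENT)] * a + [(PRESENT, ABSENT)] * b
            + [(ABSENT, PRESENT)] * c + [(ABSENT, ABSENT)] * d
        )

    def test_perfect_concordance(self):
        res = phi_correlation(cohort_from_cells(self.cells_to_pairs(10, 0, 0, 10)), "ph_a", "ph_b")
        assert res.phi == pytest.approx(1.0)

    def test_proportional_rows_give_zero(self):
        res = phi_correlation(cohort_from_cells(self.cells_to_pairs(9, 3, 6, 2)), "ph_a", "ph_b")
        assert res.phi == pytest.approx(0.0)

    def test_chi2_equals_n_phi_squared(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
            res = phi_correlation(
                cohort_from_cells(self.cells_to_pairs(a, b, c, d)), "ph_a", "ph_b"
            )
            stat, _, _ = pearson_chi2([[a, b], [c, d]])
            assert stat == pytest.approx((a + b + c + d) * res.phi**2)

    def test_zero_margin_undefined(self):
        res = phi_correlation(cohort_from_cells(self.cells_to_pairs(5, 5, 0, 0)), "ph_a", "ph_b")
        assert res.phi is None and res.p is None

    def test_sign_flips_under_single_label_swap(self):
        a, b, c, d = 12, 3, 4, 9
        res = phi_correlation(cohort_from_cells(self.cells_to_pairs(a, b, c, d)), "ph_a", "ph_b")
        # swapping present/absent on one phenotype permutes the table columns
        flipped = phi_correlation(
            cohort_from_cells(self.cells_to_pairs(b, a, d, c)), "ph_a", "ph_b"
        )
        double = phi_correlation(
            cohort_from_cells(self.cells_to_pairs(d, c, b, a)), "ph_a", "ph_b"
        )
        assert flipped.phi == pytest.approx(-res.phi)
        assert double.phi == pytest.approx(res.phi)

    def test_unrecorded_rows_excluded(self):
        pairs = self.cells_to_pairs(5, 5, 5, 5) + [(UNRECORDED, PRESENT)] * 7
        res = phi_correlation(cohort_from_cells(pairs), "ph_a", "ph_b")
        assert res.a + res.b + res.c + res.d == 20

    def test_matrix_symmetric_with_unit_diagonal(self):
        pairs = self.cells_to_pairs(12, 3, 4, 9)
        mat, mask, results = phi_matrix(cohort_from_cells(pairs), ["ph_a", "ph_b"])
        assert mat.loc["ph_a", "ph_a"] == 1.0
        assert mat.loc["ph_a", "ph_b"] == mat.loc["ph_b", "ph_a"]
        assert len(results) == 1
        assert mask.values.dtype == bool


class TestSexAndDistributions:
    def test_identical_sex_tables_p_one(self):
        pairs = [(PRESENT, ABSENT)] * 10 + [(ABSENT, ABSENT)] * 10
        sex = (["male"] * 5 + ["female"] * 5) * 2
        df = sex_difference_tests(cohort_from_cells(pairs, sex=sex), ["ph_a"])
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_missing_sex_group_errors(self):
        pairs = [(PRESENT, ABSENT)] * 4
        with pytest.raises(ValueError):
            sex_difference_tests(cohort_from_cells(pairs, sex=["male"] * 4), ["ph_a"])

    def test_gene_shares_from_exact_counts(self):
        cohort = exact_cohort(
            {("PAX3", "WS1"): 138, ("MITF", "WS2"): 161, ("SOX10", "WS2"): 124,
             ("EDNRB", "WS4"): 13, ("EDN3", "WS4"): 4, ("SNAI2", "WS2"): 2,
             ("KITLG", "WS2"): 1}
        )
        dist = distribution_summaries(cohort)["gene_by_subtype"].set_index("gene")
        assert round(dist.loc["PAX3", "pct_total"], 2) == 31.15
        assert round(dist.loc["MITF", "pct_total"], 2) == 36.34
        assert round(dist.loc["SOX10", "pct_total"], 2) == 27.99

    def test_empty_cohort_gives_empty_tables(self):
        empty = CohortTable(
            data=pd.DataFrame(columns=["patient_id", "gene", "subtype"]),
            phenotypes=[],
            gene_vocabulary=frozenset(),
        )
        dist = distribution_summaries(empty)
        assert len(dist["gene_by_subtype"]) == 0

    def test_inheritance_association_uses_recorded_only(self):
        cohort = exact_cohort(
            {("PAX3", "WS1"): 40, ("SOX10", "WS2"): 40},
            inheritance_counts={"familial": 30, "de novo": 40},
        )
        res = inheritance_association(cohort, genes=("PAX3", "SOX10"))
        assert sum(sum(row) for row in res.table) == 70
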