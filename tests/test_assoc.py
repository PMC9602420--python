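"""HWE screening and the four-model association battery."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import polyscore as ps
from polyscore.assoc import (
    DegenerateTableError, EXPECTED_CELL_MIN, expected_cells, model_tests,
)
from polyscore.panel import GenotypeCounts


def fisher_two_sided_oracle(table):
    """Brute-force two-sided Fisher p: enumerate the hypergeometric support.

    Sums P(table) over all tables with the observed margins whose probability
    does not exceed that of the observed table.
    """
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    return float(sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9)))


class TestHWE:
    def test_exact_proportions_give_zero(self):
        r = ps.hwe_chi2((25, 50, 25))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_near_equilibrium_counts(self):
        # q = 39/252; expected counts (90.02, 32.97, 3.02)
        r = ps.hwe_chi2(GenotypeCounts(90, 33, 3))
        assert r.statistic < 1e-3
        assert r.p > 0.97

    def test_all_homozygote_extreme(self):
        # q = 0.5 -> expected (25, 50, 25); chi2 = 25 + 50 + 25 = 100
        r = ps.hwe_chi2((50, 0, 50))
        assert r.statistic == pytest.approx(100.0)
        assert r.p < 1e-20

    def test_monomorphic_flagged(self):
        r = ps.hwe_chi2((40, 0, 0))
        assert (r.statistic, r.p, r.monomorphic) == (0.0, 1.0, True)

    def test_matches_direct_arithmetic(self, rng):
        """Statistic equals the hand-computed Pearson sum for random counts."""
        for _ in range(20):
            c = rng.integers(1, 80, size=3)
            n = int(c.sum())
            q = (c[1] + 2 * c[2]) / (2 * n)
            if q in (0.0, 1.0):
                continue
            e = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q]) * n
            expect = float(((c - e) ** 2 / e).sum())
            assert ps.hwe_chi2(tuple(c)).statistic == pytest.approx(expect)


class TestModelTables:
    CASE = GenotypeCounts(65, 60, 12)
    CONTROL = GenotypeCounts(90, 33, 3)

    def test_allele_table(self):
        t = ps.build_model_tables(self.CASE, self.CONTROL)["allele"]
        # minor-allele counts: 60 + 24 = 84 of 274; 33 + 6 = 39 of 252
        np.testing.assert_array_equal(t, [[84, 190], [39, 213]])

    def test_dominant_table(self):
        t = ps.build_model_tables(self.CASE, self.CONTROL)["dominant"]
        np.testing.assert_array_equal(t, [[65, 72], [90, 36]])

    def test_recessive_table(self):
        t = ps.build_model_tables(self.CASE, self.CONTROL)["recessive"]
        np.testing.assert_array_equal(t, [[125, 12], [123, 3]])

    def test_codominant_collapse_handled_downstream(self):
        mono = GenotypeCounts(10, 0, 0)
        tests = model_tests(mono, mono)
        assert all(t.method == "degenerate" and t.p == 1.0 for t in tests.values())


class TestPearsonChi2:
    def test_strongest_snp_allele_model(self):
        """The headline allele-model p-value: chi2 = 16.89, p = 4.0e-5."""
        t = ps.pearson_chi2([[84, 190], [39, 213]])
        assert t.statistic == pytest.approx(16.885, abs=5e-3)
        assert t.p == pytest.approx(3.97e-5, rel=0.01)

    def test_no_association_gives_unit_p(self):
        t = ps.pearson_chi2([[10, 10], [10, 10]])
        assert (t.statistic, t.p) == (0.0, 1.0)

    def test_second_snp_allele_model(self):
        # allele counts from published frequencies 55.8%/42.9% of 274/252
        t = ps.pearson_chi2([[153, 121], [108, 144]])
        assert t.statistic == pytest.approx(8.85, abs=0.01)
        assert round(t.p, 3) == 0.003

    def test_empty_column_dropped_and_df_adjusted(self):
        t = ps.pearson_chi2([[10, 5, 0], [8, 9, 0]])
        assert t.df == 1

    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateTableError):
            ps.pearson_chi2([[5, 0], [9, 0]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_invariant_to_row_and_column_permutation(self, cells):
        a, b, c, d = cells
        base = ps.pearson_chi2([[a, b], [c, d]]).statistic
        for t in ([[c, d], [a, b]], [[b, a], [d, c]], [[d, c], [b, a]]):
            assert ps.pearson_chi2(t).statistic == pytest.approx(base, rel=1e-12)

    def test_allele_statistic_monotone_in_frequency_gap(self):
        """For fixed margins, widening the case-control gap never lowers chi2."""
        r1, c1, n = 100, 80, 200
        e = r1 * c1 / n  # independence expectation for cell a
        stats_seq = [
            ps.pearson_chi2([[a, r1 - a], [c1 - a, n - r1 - c1 + a]]).statistic
            for a in range(int(np.ceil(e)), min(r1, c1) + 1)
        ]
        assert all(s2 >= s1 - 1e-9 for s1, s2 in zip(stats_seq, stats_seq[1:]))


class TestFisherExact:
    def test_diagonal_three_by_three(self):
        # margins (3,3|3,3): P(obs)=0.05, only the mirror table qualifies
        assert ps.fisher_exact([[3, 0], [0, 3]]).p == pytest.approx(0.1)

    def test_transpose_symmetry(self):
        p1 = ps.fisher_exact([[0, 5], [5, 0]]).p
        p2 = ps.fisher_exact([[0, 5], [5, 0]][::-1]).p
        assert p1 == pytest.approx(p2)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            ps.fisher_exact([[1, 2, 3], [4, 5, 6]])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    def test_equals_hypergeometric_enumeration(self, cells):
        """Fisher p equals brute-force enumeration for all tables with N <= 60."""
        table = [[cells[0], cells[1]], [cells[2], cells[3]]]
        if sum(cells) == 0 or min(cells[0] + cells[1], cells[2] + cells[3]) == 0:
            return
        if min(cells[0] + cells[2], cells[1] + cells[3]) == 0:
            return
        assert ps.fisher_exact(table).p == pytest.approx(
            fisher_two_sided_oracle(table), rel=1e-6
        )

    def test_converges_to_chi2_as_tables_scale(self):
        """The exact and asymptotic tests agree in the large-count limit.

        For fixed cell proportions, scaling a 2x2 table by 50 brings the two
        p-values within 0.01 of each other; at small counts (2x) the exact
        test's discreteness leaves differences an order of magnitude larger.
        """
        rng = np.random.default_rng(2024)
        small_diffs, large_diffs = [], []
        for _ in range(30):
            base = rng.integers(3, 12, size=(2, 2))
            for k, sink in ((2, small_diffs), (50, large_diffs)):
                t = base * k
                sink.append(abs(ps.fisher_exact(t).p - ps.pearson_chi2(t).p))
        assert max(large_diffs) < 0.01
        assert max(large_diffs) < max(small_diffs)


class TestBattery:
    def test_bonferroni_threshold_for_full_candidate_family(self):
        thr = ps.bonferroni_threshold(0.05, 70, 4)
        assert thr == pytest.approx(0.00018, abs=5e-6)

    def test_fisher_fallback_on_sparse_recessive_table(self, table2_counts):
        # recessive 2/2 column for this SNP: 0 cases + 2 controls
        tests = model_tests(table2_counts["rs13107325"]["case"],
                            table2_counts["rs13107325"]["control"])
        assert tests["recessive"].method == "fisher_exact"

    def test_expected_cell_rule(self):
        t = np.array([[50, 2], [60, 1]])
        assert (expected_cells(t) < EXPECTED_CELL_MIN).any()

    def test_strongest_snp_full_battery(self, table2_counts):
        """rs699785: nominal in all four models; published per-model p-values
        (allele 0.00004, codominant 0.0002, dominant 0.0001, recessive 0.026)
        are reproduced at printed precision; survives the 70-SNP x 4-model
        Bonferroni threshold in exactly two models (allele and dominant)."""
        r = ps.association_from_counts(
            "rs699785",
            table2_counts["rs699785"]["case"],
            table2_counts["rs699785"]["control"],
            favorable_is_allele2=True,
            bonferroni_p=ps.bonferroni_threshold(0.05, 70, 4),
        )
        assert not r.hwe_excluded
        assert r.nominal
        assert all(t.p < 0.05 for t in r.tests.values())
        assert round(r.tests["allele"].p, 5) == 0.00004
        assert round(r.tests["codominant"].p, 4) == 0.0002
        assert round(r.tests["dominant"].p, 4) == 0.0001
        assert round(r.tests["recessive"].p, 3) == 0.026
        assert r.survives_bonferroni
        assert sorted(r.bonferroni_models) == ["allele", "dominant"]

    def test_no_snp_fails_hwe_in_reconstructed_cohort(self, panel, table2_counts):
        for snp in panel:
            r = ps.association_from_counts(
                snp.rsid,
                table2_counts[snp.rsid]["case"],
                table2_counts[snp.rsid]["control"],
                snp.favorable_is_allele2,
            )
            assert not r.hwe_excluded, snp.rsid

    def test_hwe_violating_snp_excluded_with_empty_tests(self):
        r = ps.association_from_counts(
            "rsX", GenotypeCounts(50, 0, 50), GenotypeCounts(40, 45, 15), True
        )
        assert r.hwe_excluded and r.tests == {}

    def test_identical_groups_yield_no_nominal_snps(self, panel):
        counts = GenotypeCounts(60, 50, 17)
        for snp in panel:
            r = ps.association_from_counts(snp.rsid, counts, counts,
                                           snp.favorable_is_allele2)
            assert not r.nominal

    def test_run_association_over_matrix(self, panel, study_cohort):
        results = ps.run_association(study_cohort, panel, bonferroni_snps=70)
        assert len(results) == 15
        assert {r.rsid for r in results} == set(panel.rsids)
        for r in results:
            assert abs(
                r.freq_diff - (r.favorable_freq_case - r.favorable_freq_control)
            ) < 1e-12

    def test_empty_panel_or_group_rejected(self, panel, study_cohort):
        solo = ps.GenotypeMatrix(
            sample_ids=["s1"], rsids=list(panel.rsids),
            doses=np.ones((1, 15)), labels=np.array(["case"], dtype=object),
        )
        with pytest.raises(ValueError, match="control"):
            ps.run_association(solo, panel)


class TestFrequencyDifferences:
    # published per-group favorable-allele percentages and their printed
    # difference column; three rows of the printed differences carry
    # last-digit arithmetic slips (the correct subtractions are 5.9, 5.4
    # and 5.4), so the expected value here is the correct subtraction of
    # the two printed percentages.
    PRINTED_DIFF = {
        "rs11264302": 0.129, "rs11548200": 0.059, "rs699785": 0.152,
        "rs55680124": 0.054, "rs2920503": 0.085, "rs13107325": 0.054,
        "rs205262": 0.062, "rs4134943": 0.059, "rs10452738": 0.072,
        "rs2439823": 0.131, "rs12883788": 0.085, "rs8011870": 0.073,
        "rs11881338": 0.137, "rs1667369": 0.100, "rs143384": 0.122,
    }

    def test_diff_column_reproduced_to_three_decimals(self, panel, table2_counts):
        for snp in panel:
            r = ps.association_from_counts(
                snp.rsid,
                table2_counts[snp.rsid]["case"],
                table2_counts[snp.rsid]["control"],
                snp.favorable_is_allele2,
            )
            assert r.freq_diff_printed == pytest.approx(
                self.PRINTED_DIFF[snp.rsid], abs=1e-9
            ), snp.rsid


class TestTypeIError:
    def test_null_rejection_rate_per_model(self):
        """Simulating equal-distribution cohorts at the study sizes keeps the
        nominal rejection rate of each model at 0.05 +/- 0.02 (1000 reps)."""
        rng = np.random.default_rng(777)
        triple = np.array([0.49, 0.42, 0.09])  # HWE at q = 0.3
        reps = 1000
        rejections = {m: 0 for m in ps.assoc.MODELS} if hasattr(ps, "assoc") else {}
        rejections = {m: 0 for m in ("allele", "codominant", "dominant", "recessive")}
        for _ in range(reps):
            c = rng.multinomial(137, triple)
            k = rng.multinomial(126, triple)
            tests = model_tests(GenotypeCounts(*c), GenotypeCounts(*k))
            for m, t in tests.items():
                rejections[m] += t.p < 0.05
        for m, n_rej in rejections.items():
            assert 0.03 <= n_rej / reps <= 0.07, (m, n_rej / reps)
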