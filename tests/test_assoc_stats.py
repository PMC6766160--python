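import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import fisher_two_sided_enum
from varprio.assoc_stats import (
    AssociationResult,
    ContingencyTable2x2,
    allele_freq_table,
    chi_square_2x2,
    fisher_exact_2x2,
    pooled_t_test,
    qc_filter,
    rank_results,
    recessive_table,
    sem,
    t_test_by_genotype_class,
)
from varprio.variant_io import Cohort, GenotypeCall, Sample

G = GenotypeCall


def build_cohort(genotype_counts, missing=0, variant_id="v1"):
    """Cohort with (n_hom_ref, n_het, n_hom_alt) genotypes plus missings,
    phenotypes alternating so tables stay generic."""
    calls = (
        [G.HOM_REF] * genotype_counts[0]
        + [G.HET] * genotype_counts[1]
        + [G.HOM_ALT] * genotype_counts[2]
        + [G.MISSING] * missing
    )
    samples = [
        Sample(id=f"s{i}", phenotype="case" if i % 2 else "control")
        for i in range(len(calls))
    ]
    genotypes = {variant_id: {s.id: g for s, g in zip(samples, calls)}}
    return Cohort(samples=samples, genotypes=genotypes)


class TestQcFilter:
    def test_rare_allele_fails_maf(self):
        # 106 hom-ref + 4 het carriers: allele frequency 4/220
        (qc,) = qc_filter(build_cohort((106, 4, 0)))
        assert qc.maf == pytest.approx(4 / 220)
        assert qc.fail_reasons == ("low_maf",)

    def test_monomorphic_variant_fails_cardinality(self):
        (qc,) = qc_filter(build_cohort((0, 0, 50)))
        assert "insufficient_cardinality" in qc.fail_reasons
        assert "low_maf" in qc.fail_reasons  # maf 0 as well

    def test_call_rate_counts_missing(self):
        (qc,) = qc_filter(build_cohort((40, 40, 14), missing=24))
        assert qc.call_rate == pytest.approx((118 - 24) / 118)
        assert "low_call_rate" in qc.fail_reasons

    def test_thresholds_are_strict_inequalities(self):
        # call rate exactly 0.90 and maf exactly 0.05 both pass
        (qc,) = qc_filter(build_cohort((72, 18, 0), missing=10))
        assert qc.call_rate == pytest.approx(0.90)
        assert qc.maf == pytest.approx(0.10)
        assert qc.passed
        (qc,) = qc_filter(build_cohort((90, 10, 0)))
        assert qc.maf == pytest.approx(0.05)
        assert "low_maf" not in qc.fail_reasons

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        counts=st.tuples(
            st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
        ).filter(lambda c: sum(c) >= 2),
        missing=st.integers(0, 20),
    )
    def test_maf_bounded_and_matches_direct_tally(self, counts, missing):
        (qc,) = qc_filter(build_cohort(counts, missing=missing))
        n_called = sum(counts)
        af = (counts[1] + 2 * counts[2]) / (2 * n_called)
        assert 0.0 <= qc.maf <= 0.5
        assert qc.maf == pytest.approx(min(af, 1 - af))
        assert qc.call_rate == pytest.approx(n_called / (n_called + missing))

    def test_lowering_maf_threshold_is_monotone(self):
        cohorts = build_cohort((80, 12, 8))
        strict = [q.passed for q in qc_filter(cohorts, maf_min=0.20)]
        loose = [q.passed for q in qc_filter(cohorts, maf_min=0.01)]
        assert all(s <= l for s, l in zip(strict, loose))


def cohort_from_recessive_counts(case_nonrisk, case_hom, ctrl_nonrisk, ctrl_hom):
    """Phenotyped genotype maps reproducing a recessive 2x2 table; the
    non-risk class is split between hom-ref and het."""
    genotypes, phenotypes = {}, {}
    for phen, nonrisk, hom in [
        ("case", case_nonrisk, case_hom),
        ("control", ctrl_nonrisk, ctrl_hom),
    ]:
        i = 0
        for k in range(nonrisk):
            sid = f"{phen}{i}"; i += 1
            genotypes[sid] = G.HOM_REF if k % 2 else G.HET
            phenotypes[sid] = phen
        for _ in range(hom):
            sid = f"{phen}{i}"; i += 1
            genotypes[sid] = G.HOM_ALT
            phenotypes[sid] = phen
    return genotypes, phenotypes


class TestRecessiveTable:
    def test_reproduces_cohort_counts(self):
        genotypes, phenotypes = cohort_from_recessive_counts(7, 49, 48, 14)
        table = recessive_table(genotypes, phenotypes)
        assert table.rows == ((7, 49), (48, 14))

    def test_missing_samples_excluded(self):
        genotypes, phenotypes = cohort_from_recessive_counts(2, 2, 2, 2)
        genotypes["case0"] = G.MISSING
        table = recessive_table(genotypes, phenotypes)
        assert table.total == 7

    def test_carriers_only_gives_zero_risk_column(self):
        genotypes, phenotypes = cohort_from_recessive_counts(5, 0, 5, 0)
        table = recessive_table(genotypes, phenotypes)
        assert table.b == table.d == 0

    def test_reference_orientation_flips_columns(self):
        genotypes, phenotypes = cohort_from_recessive_counts(4, 6, 8, 2)
        flipped = recessive_table(genotypes, phenotypes, risk_allele_is_alt=False)
        # hom-ref is now the risk class; hets stay in the carrier column
        n_case_hom_ref = sum(
            1 for s, g in genotypes.items()
            if phenotypes[s] == "case" and g is G.HOM_REF
        )
        assert flipped.b == n_case_hom_ref

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            recessive_table({"a": G.MISSING}, {"a": "case"})

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        gts=st.lists(
            st.sampled_from((G.HOM_REF, G.HET, G.HOM_ALT, G.MISSING)),
            min_size=2, max_size=40,
        ).filter(lambda g: any(x is not G.MISSING for x in g)),
        phens=st.data(),
    )
    def test_matches_brute_force_tally(self, gts, phens):
        phenotypes = {
            f"s{i}": phens.draw(st.sampled_from(("case", "control")))
            for i in range(len(gts))
        }
        genotypes = {f"s{i}": g for i, g in enumerate(gts)}
        table = recessive_table(genotypes, phenotypes)
        brute = {
            (p, hom): sum(
                1 for s in genotypes
                if phenotypes[s] == p
                and genotypes[s] is not G.MISSING
                and (genotypes[s] is G.HOM_ALT) == hom
            )
            for p in ("case", "control") for hom in (False, True)
        }
        assert table.rows == (
            (brute[("case", False)], brute[("case", True)]),
            (brute[("control", False)], brute[("control", True)]),
        )


class TestChiSquare:
    def test_identical_rows_give_null_statistic(self):
        chi2, p = chi_square_2x2(ContingencyTable2x2(10, 20, 10, 20))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_invariant_under_transpose_and_swaps(self):
        t = ContingencyTable2x2(7, 49, 48, 14)
        chi2, p = chi_square_2x2(t)
        transposed = ContingencyTable2x2(7, 48, 49, 14)
        rows_swapped = ContingencyTable2x2(48, 14, 7, 49)
        assert chi_square_2x2(transposed) == pytest.approx((chi2, p))
        assert chi_square_2x2(rows_swapped) == pytest.approx((chi2, p))

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))

    def test_agrees_with_fisher_for_large_expected_counts(self):
        t = ContingencyTable2x2(30, 50, 55, 25)
        _, p_chi = chi_square_2x2(t)
        p_fisher = fisher_exact_2x2(t)
        assert 0.1 < p_chi / p_fisher < 10.0


class TestFisherExact:
    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 7)) == 1.0
        assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        a=st.integers(0, 50), b=st.integers(0, 50),
        c=st.integers(0, 50), d=st.integers(0, 50),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_enum(a, b, c, d), rel=1e-6)


class TestPooledTTest:
    def test_equal_means_give_zero_statistic(self):
        t, df, p = pooled_t_test(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 20

    def test_raw_ages_match_summary_route(self):
        rng = np.random.default_rng(42)
        ages, genotypes = {}, {}
        for i in range(30):
            sid = f"s{i}"
            hom = i % 3 == 0
            ages[sid] = float(rng.normal(10 if hom else 13, 2))
            genotypes[sid] = G.HOM_ALT if hom else (G.HET if i % 2 else G.HOM_REF)
        t1, df1, p1 = t_test_by_genotype_class(ages, genotypes)
        other = [a for s, a in ages.items() if genotypes[s] is not G.HOM_ALT]
        hom = [a for s, a in ages.items() if genotypes[s] is G.HOM_ALT]
        t2, df2, p2 = pooled_t_test(
            float(np.mean(other)), float(np.std(other, ddof=1)), len(other),
            float(np.mean(hom)), float(np.std(hom, ddof=1)), len(hom),
        )
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))

    def test_degenerate_group_size_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestAlleleFreqTable:
    def test_genotype_counts_to_allele_counts(self):
        table = allele_freq_table((106, 4, 0), (96, 3, 0))
        assert table.rows == ((216, 4), (195, 3))

    def test_zero_group_gives_zero_row(self):
        table = allele_freq_table((0, 0, 0), (10, 5, 1))
        assert table.rows[0] == (0, 0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        counts=st.tuples(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
    )
    def test_allele_totals_conserved(self, counts):
        if sum(counts) == 0:
            return
        table = allele_freq_table(counts, (1, 1, 1))
        assert table.a + table.b == 2 * sum(counts)


class TestSem:
    def test_single_observation_returns_sd(self):
        assert sem(3.7, 1) == pytest.approx(3.7)

    def test_scales_with_sqrt_n(self):
        assert sem(2.0, 4) == pytest.approx(1.0)


class TestRankResults:
    @staticmethod
    def result(vid, p, pos=0):
        return AssociationResult(
            variant_id=vid,
            table=ContingencyTable2x2(1, 1, 1, 1),
            chi2=0.0, p=p, chrom="12", pos=pos,
        )

    def test_smallest_p_ranks_first(self):
        ranked = rank_results([
            self.result("a", 1.68e-12), self.result("b", 3.39e-17),
            self.result("c", 4.81e-13), self.result("d", 3.95e-14),
        ])
        assert [r.variant_id for r in ranked] == ["b", "d", "c", "a"]
        assert ranked[0].rank == 1
        assert ranked[0].neg_log10_p == pytest.approx(-math.log10(3.39e-17))

    def test_ties_broken_by_position(self):
        ranked = rank_results([
            self.result("late", 0.5, pos=200), self.result("early", 0.5, pos=100),
        ])
        assert [r.variant_id for r in ranked] == ["early", "late"]

    def test_single_entry_gets_rank_one(self):
        (r,) = rank_results([self.result("only", 0.3)])
        assert r.rank == 1

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(ps=st.lists(st.floats(1e-20, 1.0), min_size=1, max_size=30))
    def test_order_matches_sort_oracle(self, ps):
        ranked = rank_results(
            [self.result(f"v{i}", p, pos=i) for i, p in enumerate(ps)]
        )
        assert [r.p for r in ranked] == sorted(ps)
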