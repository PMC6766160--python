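"""Genotyping QC and case/control association statistics.

Covers the statistics run on the large genotyped cohort: per-variant
quality control (call rate, minor allele frequency, genotype-class
cardinality), the recessive-model 2x2 contingency table and uncorrected
Pearson chi-squared test, two-sided Fisher's exact tests, a pooled
two-sample t-test on summary statistics, standard error of the mean,
allele-frequency tables, and ranking of association results.

Conventions: the chi-squared test is Pearson's without continuity
correction (1 df); Fisher's two-sided p sums the probabilities of all
tables with the observed margins that are no more probable than the
observed one (probability-mass method). Both are deliberate: they match
the conventions of standard SNP association suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .variant_io import Cohort, GenotypeCall

__all__ = [
    "ContingencyTable2x2",
    "QCRecord",
    "AssociationResult",
    "qc_filter",
    "recessive_table",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "allele_freq_table",
    "pooled_t_test",
    "t_test_by_genotype_class",
    "sem",
    "rank_results",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are phenotype/group, columns genotype/allele."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def rows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))

    def as_array(self) -> np.ndarray:
        return np.array(self.rows, dtype=float)


@dataclass(frozen=True)
class QCRecord:
    """Per-variant quality-control outcome."""

    variant_id: str
    call_rate: float
    maf: float
    n_genotype_classes: int
    fail_reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


@dataclass
class AssociationResult:
    """Recessive-model association outcome for one variant."""

    variant_id: str
    table: ContingencyTable2x2
    chi2: float
    p: float
    risk_allele: str = "alt"
    df: int = 1
    rank: int | None = None
    chrom: str = ""
    pos: int = 0

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p)


# ---------------------------------------------------------------------------
# QC


def _genotype_values(gmap: Mapping[str, GenotypeCall], sample_ids: Sequence[str]):
    return [gmap.get(s, GenotypeCall.MISSING) for s in sample_ids]


def qc_filter(
    cohort: Cohort,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
) -> list[QCRecord]:
    """Apply per-variant genotyping QC over a cohort.

    Call rate is called/total samples; MAF is computed from called
    genotypes only (minor-allele count over 2 x called). Failure
    thresholds are strict inequalities — a variant at exactly the
    threshold passes. ``insufficient_cardinality`` flags variants with
    fewer than two distinct called genotype classes, which cannot form
    an association table.
    """
    out = []
    ids = cohort.sample_ids
    n_total = len(ids)
    for vid in sorted(cohort.genotypes):
        calls = [g for g in _genotype_values(cohort.genotypes[vid], ids) if g.is_called]
        n_called = len(calls)
        call_rate = n_called / n_total if n_total else 0.0
        if n_called:
            n_alt = sum(
                2 if g is GenotypeCall.HOM_ALT else (1 if g is GenotypeCall.HET else 0)
                for g in calls
            )
            af = n_alt / (2 * n_called)
            maf = min(af, 1.0 - af)
        else:
            maf = 0.0
        n_classes = len(set(calls))
        reasons = []
        if call_rate < call_rate_min:
            reasons.append("low_call_rate")
        if maf < maf_min:
            reasons.append("low_maf")
        if n_classes < 2:
            reasons.append("insufficient_cardinality")
        out.append(
            QCRecord(
                variant_id=vid,
                call_rate=call_rate,
                maf=maf,
                n_genotype_classes=n_classes,
                fail_reasons=tuple(reasons),
            )
        )
    return out


# ---------------------------------------------------------------------------
# contingency tables


def recessive_table(
    variant_genotypes: Mapping[str, GenotypeCall],
    phenotypes: Mapping[str, str],
    risk_allele_is_alt: bool = True,
) -> ContingencyTable2x2:
    """Build the recessive-model 2x2 table for one variant.

    Rows are affected/unaffected; columns are carrier-or-reference
    (HOM_REF or HET of the risk allele) versus homozygous-risk. Samples
    with missing genotypes are excluded.
    """
    hom_risk = GenotypeCall.HOM_ALT if risk_allele_is_alt else GenotypeCall.HOM_REF
    cells = {("case", False): 0, ("case", True): 0,
             ("control", False): 0, ("control", True): 0}
    n_used = 0
    for sid, phen in phenotypes.items():
        g = variant_genotypes.get(sid, GenotypeCall.MISSING)
        if not g.is_called:
            continue
        cells[(phen, g is hom_risk)] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no called genotypes to tabulate")
    return ContingencyTable2x2(
        a=cells[("case", False)],
        b=cells[("case", True)],
        c=cells[("control", False)],
        d=cells[("control", True)],
    )


def allele_freq_table(
    genotype_counts_a: tuple[int, int, int],
    genotype_counts_b: tuple[int, int, int],
) -> ContingencyTable2x2:
    """Convert genotype counts (hom-ref, het, hom-alt) per group into an
    allele-count 2x2 table (rows = groups, columns = ref/alt alleles)."""

    def alleles(counts):
        hr, het, ha = counts
        if min(hr, het, ha) < 0:
            raise ValueError("genotype counts must be nonnegative")
        return 2 * hr + het, 2 * ha + het

    a, b = alleles(genotype_counts_a)
    c, d = alleles(genotype_counts_b)
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# tests


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction.

    Raises on a degenerate table (any zero row or column margin), where
    the statistic is undefined.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (with a small relative tolerance for floating-point ties).
    A table with any zero margin admits only one configuration, so p=1.
    """
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t-test from summary stats.

    Returns ``(t, df, two-sided p)`` with ``df = n1 + n2 - 2``. A Welch
    variant is available through scipy directly; the pooled form is the
    default here because it is the classical unpaired t-test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def t_test_by_genotype_class(
    ages: Mapping[str, float],
    genotypes: Mapping[str, GenotypeCall],
    hom_risk: GenotypeCall = GenotypeCall.HOM_ALT,
) -> tuple[float, int, float]:
    """Pooled t-test of age between homozygous-risk and other samples.

    Computes the per-class summary statistics from raw ages (samples
    missing either an age or a called genotype are dropped), then
    delegates to :func:`pooled_t_test` with the non-risk class first.
    """
    grp_other, grp_hom = [], []
    for sid, age in ages.items():
        g = genotypes.get(sid, GenotypeCall.MISSING)
        if age is None or not g.is_called:
            continue
        (grp_hom if g is hom_risk else grp_other).append(float(age))
    if len(grp_other) < 2 or len(grp_hom) < 2:
        raise ValueError("each genotype class needs at least two aged samples")
    return pooled_t_test(
        float(np.mean(grp_other)), float(np.std(grp_other, ddof=1)), len(grp_other),
        float(np.mean(grp_hom)), float(np.std(grp_hom, ddof=1)), len(grp_hom),
    )


def sem(sd: float, n: int) -> float:
    """Standard error of the mean, sd / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return sd / math.sqrt(n)


def rank_results(results: Iterable[AssociationResult]) -> list[AssociationResult]:
    """Order association results by ascending p, ties by (chrom, pos).

    Ranks are written back (1-based) and the sorted list returned.
    """
    ordered = sorted(results, key=lambda r: (r.p, r.chrom, r.pos))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered
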