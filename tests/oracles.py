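"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration and counting
— and shares no code with the package implementation it checks.
"""

from math import comb

from varprio.variant_io import GenotypeCall

HOM_REF, HET, HOM_ALT, MISSING = (
    GenotypeCall.HOM_REF,
    GenotypeCall.HET,
    GenotypeCall.HOM_ALT,
    GenotypeCall.MISSING,
)


def filter1_truth(case_gts, control_gts, strict=True):
    """Perfect concordance: all cases hom-alt, no control hom-alt."""
    if strict and MISSING in case_gts + control_gts:
        return False
    called_cases = [g for g in case_gts if g is not MISSING]
    return (
        all(g is HOM_ALT for g in called_cases)
        and sum(g is HOM_ALT for g in called_cases) >= 1
        and sum(g is HOM_ALT for g in control_gts) == 0
    )


def filter2_truth(case_gts, control_gts, strict=True):
    """All cases hom-alt, at most one control hom-alt."""
    if strict and MISSING in case_gts + control_gts:
        return False
    called_cases = [g for g in case_gts if g is not MISSING]
    return (
        all(g is HOM_ALT for g in called_cases)
        and sum(g is HOM_ALT for g in called_cases) >= 1
        and sum(g is HOM_ALT for g in control_gts) <= 1
    )


def filter3_truth(case_gts, control_gts, strict=True):
    """At least one case hom-alt, at least one control with a ref allele."""
    if strict and MISSING in case_gts + control_gts:
        return False
    return sum(g is HOM_ALT for g in case_gts) >= 1 and (
        sum(g in (HOM_REF, HET) for g in control_gts) >= 1
    )


FILTER_TRUTHS = {
    "filter1": filter1_truth,
    "filter2": filter2_truth,
    "filter3": filter3_truth,
}


def concordance_tally(case_gts, control_gts):
    """Direct per-class tally of genotype states."""
    return {
        "n_case_hom_alt": sum(g is HOM_ALT for g in case_gts),
        "n_case_not_hom_alt": sum(g in (HOM_REF, HET) for g in case_gts),
        "n_case_missing": sum(g is MISSING for g in case_gts),
        "n_control_hom_alt": sum(g is HOM_ALT for g in control_gts),
        "n_control_with_ref": sum(g in (HOM_REF, HET) for g in control_gts),
        "n_control_missing": sum(g is MISSING for g in control_gts),
    }


def fisher_two_sided_enum(a, b, c, d, tie_tol=1e-7):
    """Two-sided Fisher p by full enumeration over the fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + tie_tol))
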