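"""Concordance filtering and variant prioritization.

Implements the three case/control genotype-concordance filters used to
screen a small sequenced discovery panel under a recessive model, the
annotation-impact prioritization cascade that narrows the filtered sets
to variants worth genotyping in a large cohort, and an automated
artifact screen (multiallelic sites, excess depth, ambiguous mapping)
standing in for manual alignment inspection.

Filter semantics, for a panel of affected cases and unaffected controls:

* ``filter1`` — perfect concordance: every case homozygous for the
  alternate allele, no control homozygous-alternate.
* ``filter2`` — tolerates incomplete penetrance: every case
  homozygous-alternate, at most one control homozygous-alternate.
* ``filter3`` — tolerates phenocopies too: at least one case
  homozygous-alternate and at least one control carrying a reference
  allele (heterozygous controls qualify).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .variant_io import Cohort, GenotypeCall, RegionInterval, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "ConcordanceCounts",
    "FilterSpec",
    "CascadeConfig",
    "FILTER_PRESETS",
    "classify_concordance",
    "apply_filter",
    "prioritization_cascade",
    "artifact_screen",
]


@dataclass(frozen=True)
class ConcordanceCounts:
    """Tally of panel genotypes at one variant, split by phenotype."""

    n_case_hom_alt: int
    n_case_not_hom_alt: int  # called cases that are HET or HOM_REF
    n_case_missing: int
    n_control_hom_alt: int
    n_control_with_ref: int  # called controls that are HET or HOM_REF
    n_control_missing: int

    @property
    def n_cases(self) -> int:
        return self.n_case_hom_alt + self.n_case_not_hom_alt + self.n_case_missing

    @property
    def n_controls(self) -> int:
        return (
            self.n_control_hom_alt + self.n_control_with_ref + self.n_control_missing
        )


@dataclass(frozen=True)
class FilterSpec:
    """Parameterization of one concordance filter.

    Exactly one of ``require_all_cases_hom_alt`` / ``min_cases_hom_alt``
    governs the case condition: when the flag is true the count is
    ignored. ``missing_policy`` controls what an uncalled panel genotype
    does: under ``strict`` a MISSING sample in a constrained phenotype
    class disqualifies the variant; under ``permissive`` conditions are
    evaluated over called samples only.
    """

    name: str
    require_all_cases_hom_alt: bool = True
    min_cases_hom_alt: int = 1
    max_controls_hom_alt: int | None = 0
    min_controls_with_ref: int = 0
    missing_policy: str = "strict"

    def __post_init__(self):
        if self.missing_policy not in ("strict", "permissive"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.min_cases_hom_alt < 1:
            raise ValueError("min_cases_hom_alt must be >= 1")

    def _cases_constrained(self) -> bool:
        return True  # every preset constrains the case class

    def _controls_constrained(self) -> bool:
        return self.max_controls_hom_alt is not None or self.min_controls_with_ref > 0

    def passes(self, counts: ConcordanceCounts) -> bool:
        """Evaluate the filter on a concordance tally."""
        if self.missing_policy == "strict":
            if self._cases_constrained() and counts.n_case_missing > 0:
                return False
            if self._controls_constrained() and counts.n_control_missing > 0:
                return False
        if self.require_all_cases_hom_alt:
            if counts.n_case_not_hom_alt > 0 or counts.n_case_hom_alt < 1:
                return False
        elif counts.n_case_hom_alt < self.min_cases_hom_alt:
            return False
        if (
            self.max_controls_hom_alt is not None
            and counts.n_control_hom_alt > self.max_controls_hom_alt
        ):
            return False
        if counts.n_control_with_ref < self.min_controls_with_ref:
            return False
        return True


def _preset(name: str, **kw) -> FilterSpec:
    return FilterSpec(name=name, **kw)


FILTER_PRESETS: dict[str, FilterSpec] = {
    "filter1": _preset("filter1", require_all_cases_hom_alt=True, max_controls_hom_alt=0),
    "filter2": _preset("filter2", require_all_cases_hom_alt=True, max_controls_hom_alt=1),
    "filter3": _preset(
        "filter3",
        require_all_cases_hom_alt=False,
        min_cases_hom_alt=1,
        max_controls_hom_alt=None,
        min_controls_with_ref=1,
    ),
}


def classify_concordance(variant: VariantRecord, panel: Cohort) -> ConcordanceCounts:
    """Tally a variant's panel genotypes by phenotype class.

    Missing genotype entries count as MISSING. A panel without at least
    one case and one control cannot express any concordance pattern and
    raises ``ValueError``.
    """
    cases, controls = panel.cases, panel.controls
    if not cases or not controls:
        raise ValueError("panel must contain at least one case and one control")

    def tally(samples):
        hom_alt = not_hom_alt = missing = 0
        for s in samples:
            g = variant.genotypes.get(s.id, GenotypeCall.MISSING)
            if g is GenotypeCall.MISSING:
                missing += 1
            elif g is GenotypeCall.HOM_ALT:
                hom_alt += 1
            else:
                not_hom_alt += 1
        return hom_alt, not_hom_alt, missing

    ca, cn, cm = tally(cases)
    ka, kn, km = tally(controls)
    return ConcordanceCounts(
        n_case_hom_alt=ca,
        n_case_not_hom_alt=cn,
        n_case_missing=cm,
        n_control_hom_alt=ka,
        n_control_with_ref=kn,
        n_control_missing=km,
    )


def apply_filter(
    variants: Iterable[VariantRecord], panel: Cohort, spec: FilterSpec | str
) -> list[VariantRecord]:
    """Keep the variants whose panel concordance pattern satisfies ``spec``.

    ``spec`` may be a preset name (``filter1``/``filter2``/``filter3``)
    or a custom :class:`FilterSpec`. Sample order in the panel is
    irrelevant: only per-class tallies are evaluated.
    """
    if isinstance(spec, str):
        spec = FILTER_PRESETS[spec]
    return [v for v in variants if spec.passes(classify_concordance(v, panel))]


# ---------------------------------------------------------------------------
# prioritization cascade


@dataclass(frozen=True)
class CascadeConfig:
    """Options narrowing the filtered sets to follow-up candidates.

    ``strict_region`` is the core associated interval (without the
    flanks used for the initial region filter); modifier-class variants
    from filter 2 are only kept when dual-caller and inside it.
    """

    strict_region: RegionInterval
    nonsynonymous_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE", "LOW"})
    exclude_synonymous: bool = True
    require_dual_caller_for_modifiers: bool = True
    dual_caller_for_filter3: bool = True
    filter3_impacts: frozenset[str] = frozenset({"MODERATE", "LOW"})


def _is_synonymous(v: VariantRecord) -> bool:
    return "synonymous_variant" in v.consequence


def _dual_caller(v: VariantRecord) -> bool:
    return len(v.callers) >= 2


def prioritization_cascade(
    f1: Sequence[VariantRecord],
    f2: Sequence[VariantRecord],
    f3: Sequence[VariantRecord],
    config: CascadeConfig,
) -> list[tuple[VariantRecord, str]]:
    """Combine the three filtered sets into a tagged candidate list.

    * every filter-1 variant is kept (tag ``filter1``);
    * from filter 2: functional-impact non-synonymous variants (tag
      ``filter2-functional``) regardless of caller provenance, plus
      modifier-class variants that are dual-caller and inside the strict
      region (tag ``filter2-modifier``);
    * from filter 3, excluding anything already tagged: dual-caller
      moderate/low non-synonymous variants (tag ``filter3-functional``).

    A variant reached by several routes keeps the highest-priority tag
    (filter1 > filter2 > filter3); each output record carries exactly
    one tag.
    """
    tagged: dict[tuple, tuple[VariantRecord, str]] = {}

    def claim(v: VariantRecord, tag: str):
        tagged.setdefault(v.key, (v, tag))

    for v in f1:
        claim(v, "filter1")
    for v in f2:
        if v.impact in config.nonsynonymous_impacts and not (
            config.exclude_synonymous and _is_synonymous(v)
        ):
            claim(v, "filter2-functional")
        elif v.impact == "MODIFIER":
            if (
                not config.require_dual_caller_for_modifiers or _dual_caller(v)
            ) and (v.chrom, v.pos) in config.strict_region:
                claim(v, "filter2-modifier")
    for v in f3:
        if v.key in tagged:
            continue
        if (
            v.impact in config.filter3_impacts
            and not (config.exclude_synonymous and _is_synonymous(v))
            and (not config.dual_caller_for_filter3 or _dual_caller(v))
        ):
            claim(v, "filter3-functional")
    return sorted(tagged.values(), key=lambda vt: (vt[0].chrom, vt[0].pos, vt[0].alt))


# ---------------------------------------------------------------------------
# artifact screen


def artifact_screen(
    variant: VariantRecord,
    local_median_depth: float,
    max_alleles: int = 2,
    depth_ratio_max: float = 3.0,
    mq0_max: float = 0.2,
) -> tuple[bool, list[str]]:
    """Screen a candidate for alignment-artifact signatures.

    Replaces manual genome-browser inspection with three rules: a site
    with more than ``max_alleles`` observed alleles (``multiallelic``),
    read depth more than ``depth_ratio_max`` times the local median
    (``excess_depth``, repetitive-region signature), or more than
    ``mq0_max`` of reads with mapping quality zero
    (``ambiguous_mapping``, multi-mapping signature). Returns
    ``(passes, flags)``; a clean variant passes with an empty flag list.
    """
    if local_median_depth <= 0:
        raise ValueError("local_median_depth must be positive")
    flags = []
    if variant.n_observed_alleles > max_alleles:
        flags.append("multiallelic")
    if variant.site_depth / local_median_depth > depth_ratio_max:
        flags.append("excess_depth")
    if variant.mq0_fraction > mq0_max:
        flags.append("ambiguous_mapping")
    return (not flags, flags)
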