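"""Variant and cohort I/O.

Reads multi-sample VCFs produced by two independent variant callers,
normalizes records to biallelic form, parses SnpEff-style ``ANN``
annotations down to a single most-severe entry, merges the two callsets
while tracking caller provenance, and reads/writes the tab-separated
cohort and result tables used by the rest of the pipeline.

Coordinates are 1-based and intervals are closed on both ends, matching
VCF ``POS`` and the ``chrom:start-end`` notation used in genetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "RegionInterval",
    "Sample",
    "Cohort",
    "VcfParseError",
    "read_callset",
    "parse_annotation",
    "merge_callsets",
    "region_filter",
    "read_cohort",
    "write_cohort",
    "write_results",
]

# SnpEff impact classes ordered from most to least severe.
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {name: i for i, name in enumerate(IMPACT_ORDER)}

MISSING_GT_TOKENS = {".", "", None}


class VcfParseError(ValueError):
    """Raised for malformed VCF input, carrying file/line context."""


class GenotypeCall(Enum):
    """Diploid genotype class of one sample at one biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @classmethod
    def from_allele_pair(cls, a, b) -> "GenotypeCall":
        """Classify an (unordered, possibly phased) diploid allele pair.

        Alleles are allele indices relative to a biallelic site: 0 =
        reference, 1 = alternate. Any no-call token (None or '.') makes
        the whole genotype MISSING.
        """
        if a in MISSING_GT_TOKENS or b in MISSING_GT_TOKENS:
            return cls.MISSING
        a, b = int(a), int(b)
        n_alt = (a != 0) + (b != 0)
        return (cls.HOM_REF, cls.HET, cls.HOM_ALT)[n_alt]

    @property
    def carries_reference(self) -> bool:
        """True for genotypes that include at least one reference allele."""
        return self in (GenotypeCall.HOM_REF, GenotypeCall.HET)

    @property
    def is_called(self) -> bool:
        return self is not GenotypeCall.MISSING

    def to_vcf(self) -> str:
        return {
            GenotypeCall.HOM_REF: "0/0",
            GenotypeCall.HET: "0/1",
            GenotypeCall.HOM_ALT: "1/1",
            GenotypeCall.MISSING: "./.",
        }[self]

    @classmethod
    def from_vcf(cls, token: str) -> "GenotypeCall":
        token = token.strip()
        if token in MISSING_GT_TOKENS:
            return cls.MISSING
        sep = "|" if "|" in token else "/"
        parts = token.split(sep)
        if len(parts) != 2:
            raise ValueError(f"not a diploid GT token: {token!r}")
        return cls.from_allele_pair(
            None if parts[0] == "." else parts[0],
            None if parts[1] == "." else parts[1],
        )


@dataclass(frozen=True)
class RegionInterval:
    """Closed 1-based genomic interval ``chrom:start-end``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def __contains__(self, item) -> bool:
        chrom, pos = item
        return chrom == self.chrom and self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class VariantRecord:
    """One biallelic variant with genotypes, provenance and annotation.

    ``site_depth``, ``mq0_fraction`` and ``n_observed_alleles`` feed the
    artifact screen; ``n_observed_alleles`` is recorded before any
    multiallelic splitting so a split record still remembers that more
    than two alleles segregated at its locus.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    callers: frozenset[str] = frozenset()
    impact: str = "MODIFIER"
    consequence: str = "unannotated"
    gene: str = ""
    site_depth: float = 0.0
    mq0_fraction: float = 0.0
    n_observed_alleles: int = 2

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.impact not in _IMPACT_RANK:
            raise ValueError(f"unknown impact class {self.impact!r}")
        if not 0.0 <= self.mq0_fraction <= 1.0:
            raise ValueError(f"mq0_fraction out of [0,1]: {self.mq0_fraction}")
        if self.n_observed_alleles < 1:
            raise ValueError("n_observed_alleles must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized identity used to match records across callers."""
        pos, ref, alt = trim_shared_bases(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def trim_shared_bases(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim bases shared by ref and alt at both ends (minimal form).

    Trailing bases are removed first, then leading ones (advancing
    ``pos``); at least one base is kept on each allele unless the allele
    is an insertion/deletion remainder, in which case the last shared
    leading base is retained VCF-style.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# annotation parsing


def _severity(impact: str) -> int:
    return _IMPACT_RANK.get(impact.upper(), len(IMPACT_ORDER))


def parse_annotation(ann_field) -> tuple[str, str, str]:
    """Reduce a SnpEff ``ANN`` INFO field to ``(impact, consequence, gene)``.

    ``ANN`` holds comma-separated alternatives, each a pipe-delimited
    entry ``Allele|Annotation|Putative_impact|Gene_Name|...`` (a VCF
    reader may deliver them pre-split as a tuple). The entry with the
    most severe impact wins; ties go to the first occurrence. An empty
    or absent field yields ``("MODIFIER", "unannotated", "")``.
    """
    if isinstance(ann_field, (tuple, list)):
        ann_field = ",".join(str(e) for e in ann_field)
    if not ann_field or ann_field == ".":
        return ("MODIFIER", "unannotated", "")
    best: tuple[int, str, str, str] | None = None
    for entry in str(ann_field).split(","):
        parts = entry.split("|")
        if len(parts) < 3:
            continue
        consequence = parts[1].strip()
        impact = parts[2].strip().upper()
        gene = parts[3].strip() if len(parts) > 3 else ""
        if impact not in _IMPACT_RANK:
            continue
        rank = _severity(impact)
        if best is None or rank < best[0]:
            best = (rank, impact, consequence, gene)
    if best is None:
        return ("MODIFIER", "unannotated", "")
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# VCF reading


def _info_float(info: Mapping, key: str, default: float = 0.0) -> float:
    # some readers raise (rather than default) for keys absent from the header
    if key not in info:
        return default
    val = info.get(key, default)
    if isinstance(val, (tuple, list)):
        val = val[0]
    try:
        return float(val)
    except (TypeError, ValueError):
        return default


def read_callset(path: str | Path, caller_label: str) -> list[VariantRecord]:
    """Read a multi-sample VCF into biallelic :class:`VariantRecord` s.

    Multiallelic records are split into one record per alternate allele
    (sharing ``pos``); for a split record a sample genotype is classified
    against that alternate only, with any other alternate allele counting
    as reference. The pre-split allele count is kept in
    ``n_observed_alleles``. The single most severe ``ANN`` entry is
    retained. ``callers`` is ``{caller_label}`` on every record.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfParseError(f"{path}: no sample columns in VCF header")
        line_no = len(str(vcf.header).rstrip("\n").split("\n"))
        for rec in vcf:
            line_no += 1
            try:
                records.extend(_split_record(rec, samples, caller_label))
            except VcfParseError:
                raise
            except Exception as exc:  # malformed record content
                raise VcfParseError(
                    f"{path} line {line_no} ({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return records


def _split_record(rec, samples: Sequence[str], caller_label: str) -> list[VariantRecord]:
    alts = [a for a in (rec.alts or ()) if a not in (None, ".", "*")]
    if not alts:
        return []
    n_alleles = 1 + len(alts)
    impact, consequence, gene = parse_annotation(
        rec.info.get("ANN") if "ANN" in rec.info else None
    )
    depth = _info_float(rec.info, "DP")
    mq0f = _info_float(rec.info, "MQ0F")
    if mq0f == 0.0 and "MQ0" in rec.info and depth > 0:
        mq0f = min(1.0, _info_float(rec.info, "MQ0") / depth)
    out = []
    for alt_index, alt in enumerate(alts, start=1):
        genotypes: dict[str, GenotypeCall] = {}
        for s in samples:
            gt = rec.samples[s].get("GT", (None, None))
            if gt is None or len(gt) != 2:
                log.warning(
                    "non-diploid GT for sample %s at %s:%s; set to MISSING",
                    s, rec.chrom, rec.pos,
                )
                genotypes[s] = GenotypeCall.MISSING
                continue
            if any(a is None for a in gt):
                genotypes[s] = GenotypeCall.MISSING
            else:
                # against this alt allele; other alts count as reference
                genotypes[s] = GenotypeCall.from_allele_pair(
                    int(gt[0] == alt_index), int(gt[1] == alt_index)
                )
        out.append(
            VariantRecord(
                chrom=str(rec.chrom),
                pos=int(rec.pos),
                ref=str(rec.ref),
                alt=str(alt),
                genotypes=genotypes,
                callers=frozenset({caller_label}),
                impact=impact,
                consequence=consequence,
                gene=gene,
                site_depth=depth,
                mq0_fraction=mq0f,
                n_observed_alleles=n_alleles,
            )
        )
    return out


# ---------------------------------------------------------------------------
# callset merging


def merge_callsets(
    set_a: Iterable[VariantRecord], set_b: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Union two caller callsets, matching on the normalized variant key.

    Matched records carry both caller labels and keep the genotypes (and
    site metrics) of ``set_a``; a genotype disagreement in more than half
    the shared samples is logged but does not block the merge — the
    discovery filters tolerate caller noise, and association testing runs
    on independently assayed genotypes. Output is sorted by (chrom, pos).
    """
    by_key: dict[tuple, VariantRecord] = {}
    for rec in set_a:
        by_key[rec.key] = rec
    for rec in set_b:
        prev = by_key.get(rec.key)
        if prev is None:
            by_key[rec.key] = rec
            continue
        shared = set(prev.genotypes) & set(rec.genotypes)
        if shared:
            n_disagree = sum(
                prev.genotypes[s] is not rec.genotypes[s] for s in shared
            )
            if n_disagree > 0.5 * len(shared):
                log.warning(
                    "caller genotype disagreement at %s in %d/%d samples; "
                    "keeping first callset's genotypes",
                    prev.variant_id, n_disagree, len(shared),
                )
        by_key[rec.key] = replace(prev, callers=prev.callers | rec.callers)
    return sorted(by_key.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


def region_filter(
    variants: Iterable[VariantRecord], region: RegionInterval
) -> list[VariantRecord]:
    """Keep variants inside the closed interval (both endpoints included)."""
    return [v for v in variants if (v.chrom, v.pos) in region]


# ---------------------------------------------------------------------------
# cohort tables


PHENOTYPES = ("case", "control")
SEXES = ("male", "female", "unknown")
CASTRATION = ("gelding", "stallion", "mare", "unknown")
_CASTRATION_SEX = {"gelding": "male", "stallion": "male", "mare": "female"}

COHORT_COLUMNS = ["sample_id", "phenotype", "sex", "castration", "age_years", "breed"]
GT_PREFIX = "gt:"


@dataclass(frozen=True)
class Sample:
    id: str
    phenotype: str
    sex: str = "unknown"
    castration: str = "unknown"
    age_years: float | None = None
    breed: str = ""

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"sample {self.id}: phenotype must be case/control")
        implied = _CASTRATION_SEX.get(self.castration)
        if implied is not None and self.sex not in ("unknown", implied):
            raise ValueError(
                f"sample {self.id}: castration {self.castration!r} "
                f"inconsistent with sex {self.sex!r}"
            )
        if implied is not None and self.sex == "unknown":
            object.__setattr__(self, "sex", implied)
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"sample {self.id}: negative age")


@dataclass
class Cohort:
    """Phenotyped samples plus their assayed genotypes.

    ``genotypes`` maps variant-id -> {sample-id -> GenotypeCall}; a
    sample absent from a variant's map is treated as MISSING there.
    """

    samples: list[Sample]
    genotypes: dict[str, dict[str, GenotypeCall]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in cohort")

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def cases(self) -> list[Sample]:
        return [s for s in self.samples if s.phenotype == "case"]

    @property
    def controls(self) -> list[Sample]:
        return [s for s in self.samples if s.phenotype == "control"]

    def genotype(self, sample_id: str, variant_id: str) -> GenotypeCall:
        return self.genotypes.get(variant_id, {}).get(sample_id, GenotypeCall.MISSING)

    def subset(self, sample_ids: Sequence[str]) -> "Cohort":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.id in keep]
        genotypes = {
            vid: {s: g for s, g in gmap.items() if s in keep}
            for vid, gmap in self.genotypes.items()
        }
        return Cohort(samples=samples, genotypes=genotypes)


def read_cohort(path: str | Path) -> Cohort:
    """Read a tab-separated cohort table.

    Required columns: ``sample_id`` and ``phenotype``. ``sex``,
    ``castration``, ``age_years`` and ``breed`` default to unknown when
    absent or blank; columns prefixed ``gt:`` are per-variant genotypes
    in VCF GT notation (empty cell = missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: cohort table lacks required column {col!r}")
    samples = []
    for _, row in df.iterrows():
        phenotype = row["phenotype"].strip().lower()
        if phenotype not in PHENOTYPES:
            raise ValueError(
                f"{path}: sample {row['sample_id']!r} has phenotype "
                f"{row['phenotype']!r}; expected case or control"
            )
        age_text = row.get("age_years", "").strip()
        samples.append(
            Sample(
                id=row["sample_id"].strip(),
                phenotype=phenotype,
                sex=(row.get("sex", "").strip().lower() or "unknown"),
                castration=(row.get("castration", "").strip().lower() or "unknown"),
                age_years=float(age_text) if age_text else None,
                breed=row.get("breed", "").strip(),
            )
        )
    genotypes: dict[str, dict[str, GenotypeCall]] = {}
    gt_cols = [c for c in df.columns if c.startswith(GT_PREFIX)]
    for col in gt_cols:
        vid = col[len(GT_PREFIX):]
        genotypes[vid] = {
            row["sample_id"].strip(): GenotypeCall.from_vcf(row[col] or "./.")
            for _, row in df.iterrows()
        }
    return Cohort(samples=samples, genotypes=genotypes)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort table that :func:`read_cohort` round-trips."""
    rows = []
    vids = sorted(cohort.genotypes)
    for s in cohort.samples:
        row = {
            "sample_id": s.id,
            "phenotype": s.phenotype,
            "sex": s.sex,
            "castration": s.castration,
            "age_years": "" if s.age_years is None else f"{s.age_years:g}",
            "breed": s.breed,
        }
        for vid in vids:
            row[GT_PREFIX + vid] = cohort.genotype(s.id, vid).to_vcf()
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS + [GT_PREFIX + v for v in vids]).to_csv(
        path, sep="\t", index=False
    )


def write_results(results: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write a result table as TSV with a header row."""
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    df.to_csv(path, sep="\t", index=False)
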