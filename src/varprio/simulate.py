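"""Synthetic case/control cohort and callset generator.

Generates, deterministically under a fixed seed, every input the
prioritization and association pipeline consumes:

* a genotyped case/control cohort (default 56 cases, 62 controls) with
  an incompletely penetrant recessive risk variant planted inside a
  linkage-disequilibrium block, neutral variants at Hardy-Weinberg
  proportions across a ~3 Mb region, ages, sex and castration status
  with the case-enrichment structure the analysis probes;
* a small discovery panel (default 4 cases + 2 controls) chosen either
  at random or "informative" — deliberately including discordant
  individuals (phenocopy cases and an unaffected homozygous-risk
  control) so that only the most permissive concordance filter can
  recover the risk variant;
* two partially overlapping multi-sample VCF callsets for the panel,
  with SnpEff-style ANN annotations, caller-unique false positives, and
  planted alignment artifacts (excess depth, mapping-quality-zero
  reads, multiallelic sites) for the artifact screen to catch.

The genotype model is allele-frequency based: each variant's genotypes
are Binomial(2, p) draws (Hardy-Weinberg), with variants inside the LD
block copying the risk variant's genotype with a probability that
decays exponentially with distance. Phenotype follows a recessive
penetrance model: homozygous-risk individuals are affected with
probability ``penetrance_hom``; everyone else with probability
``phenocopy_rate``. Individuals are drawn until the case and control
pools fill, mimicking case/control ascertainment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .variant_io import Cohort, GenotypeCall, RegionInterval, Sample, VariantRecord

__all__ = [
    "PlantedVariant",
    "SimulationConfig",
    "SimulationTruth",
    "CallsetEmission",
    "simulate_cohort",
    "select_panel",
    "emit_callsets",
    "panel_variant_records",
]

_DOSAGE_TO_CALL = {
    0: GenotypeCall.HOM_REF,
    1: GenotypeCall.HET,
    2: GenotypeCall.HOM_ALT,
}

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PlantedVariant:
    """The recessive risk variant the simulation plants.

    The alternate allele is the risk allele; ``penetrance_hom`` is the
    probability a homozygous-risk individual is affected, and
    ``phenocopy_rate`` the probability anyone else is.
    """

    position: int = 11_500_000
    ref: str = "C"
    alt: str = "T"
    risk_allele_freq: float = 0.5
    penetrance_hom: float = 0.85
    phenocopy_rate: float = 0.10


@dataclass(frozen=True)
class SimulationConfig:
    """All latent parameters of one synthetic study.

    Defaults mirror the study design this package targets: a ~2.5 Mb
    scan region containing a 483 kb strictly associated core, 56 cases
    and 62 controls genotyped at 57 variants, a 4-case/2-control
    sequencing panel, ~80% caller overlap, and a MODIFIER-heavy
    annotation mix.
    """

    seed: int = 0
    region: RegionInterval = RegionInterval("12", 10_284_011, 12_767_256)
    strict_region: RegionInterval = RegionInterval("12", 11_284_011, 11_767_256)
    planted: PlantedVariant = PlantedVariant()
    n_neutral_variants: int = 56
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length: int = 100_000  # bp; copy probability decays over this scale
    n_cases: int = 56
    n_controls: int = 62
    panel_cases: int = 4
    panel_controls: int = 2
    missing_rate: float = 0.02
    caller_overlap: float = 0.8
    caller_unique_fp_rate: float = 0.05
    n_artifact_variants: int = 3
    artifact_depth_multiplier: float = 5.0
    artifact_mq0_fraction: float = 0.5
    mean_depth: float = 20.0
    annotation_mix: tuple[tuple[str, float], ...] = (
        ("HIGH", 0.01),
        ("MODERATE", 0.04),
        ("LOW", 0.05),
        ("MODIFIER", 0.90),
    )
    # age model (years): mean/sd per class; controls floored at the
    # study's minimum control age, everything truncated at zero
    age_case_hom_risk: tuple[float, float] = (10.13, 5.37)
    age_case_other: tuple[float, float] = (13.14, 6.39)
    age_control: tuple[float, float] = (19.0, 4.0)
    control_min_age: float = 13.0
    # sex/castration model
    p_male: float = 0.45
    p_gelding_male_case: float = 0.96
    p_gelding_male_control: float = 0.71
    breed: str = "Haflinger"
    # guarantee the discovery-panel genotype classes exist in the cohort
    # (the study population is known to contain discordant individuals)
    ensure_panel_classes: bool = True
    max_draw_factor: int = 500

    def __post_init__(self):
        p = self.planted
        for name, prob in [
            ("risk_allele_freq", p.risk_allele_freq),
            ("penetrance_hom", p.penetrance_hom),
            ("phenocopy_rate", p.phenocopy_rate),
            ("missing_rate", self.missing_rate),
            ("caller_overlap", self.caller_overlap),
            ("caller_unique_fp_rate", self.caller_unique_fp_rate),
        ]:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{name} must be a probability, got {prob}")
        if (self.region.chrom, p.position) not in self.region:
            raise ValueError(f"planted position {p.position} outside region")


@dataclass(frozen=True)
class VariantDef:
    """Latent definition of one simulated variant."""

    chrom: str
    position: int
    ref: str
    alt: str
    alt_freq: float
    ld_copy_prob: float = 0.0
    is_planted: bool = False

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.position}:{self.ref}>{self.alt}"


@dataclass
class SimulationTruth:
    """Every latent quantity behind one simulated cohort."""

    config: SimulationConfig
    variants: list[VariantDef]
    planted_id: str
    # dosage matrices: rows = samples (cohort order), cols = variants
    true_dosage: np.ndarray
    sample_ids: list[str]
    # draw bookkeeping, before case/control ascertainment truncation
    n_drawn_hom_risk: int = 0
    n_drawn_hom_risk_affected: int = 0
    n_drawn_other: int = 0
    n_drawn_other_affected: int = 0

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def dosage_of(self, sample_id: str, variant_id: str) -> int:
        i = self.sample_ids.index(sample_id)
        j = self.variant_ids.index(variant_id)
        return int(self.true_dosage[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.position for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "alt_freq": [v.alt_freq for v in self.variants],
                "ld_copy_prob": [v.ld_copy_prob for v in self.variants],
                "is_planted": [v.is_planted for v in self.variants],
            }
        )


def _draw_variant_defs(config: SimulationConfig, rng: np.random.Generator) -> list[VariantDef]:
    region, planted = config.region, config.planted
    positions: set[int] = {planted.position}
    while len(positions) < config.n_neutral_variants + 1:
        positions.add(int(rng.integers(region.start, region.end + 1)))
    positions.discard(planted.position)
    defs = [
        VariantDef(
            chrom=region.chrom,
            position=planted.position,
            ref=planted.ref,
            alt=planted.alt,
            alt_freq=planted.risk_allele_freq,
            is_planted=True,
        )
    ]
    lo, hi = config.maf_range
    for pos in sorted(positions):
        ref, alt = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
        dist = abs(pos - planted.position)
        copy_prob = (
            math.exp(-4.0 * dist / config.ld_block_length)
            if dist <= config.ld_block_length
            else 0.0
        )
        defs.append(
            VariantDef(
                chrom=region.chrom,
                position=pos,
                ref=NUCLEOTIDES[ref],
                alt=NUCLEOTIDES[alt],
                alt_freq=float(rng.uniform(lo, hi)),
                ld_copy_prob=copy_prob,
            )
        )
    return sorted(defs, key=lambda v: v.position)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Generate one phenotyped, genotyped cohort plus its truth record.

    Individuals are drawn one at a time (risk genotype from
    Hardy-Weinberg, phenotype from the penetrance model) and kept while
    their phenotype pool has room, until ``n_cases`` cases and
    ``n_controls`` controls are banked; a config under which a pool
    cannot fill within ``max_draw_factor`` times the cohort size raises
    ``ValueError``. With ``ensure_panel_classes`` the sampler keeps
    drawing (bounded) until the four discovery-panel genotype classes —
    homozygous-risk case, non-homozygous case, homozygous-reference
    control, homozygous-risk control — all exist, swapping surplus
    members out.
    """
    rng = np.random.default_rng(config.seed)
    planted = config.planted
    q = planted.risk_allele_freq
    n_target = config.n_cases + config.n_controls
    budget = config.max_draw_factor * max(n_target, 1)

    cases: list[int] = []  # planted dosages
    controls: list[int] = []
    tallies = dict(hom=0, hom_aff=0, other=0, other_aff=0)

    def draw_one() -> tuple[int, bool]:
        dosage = int(rng.binomial(2, q))
        p_aff = planted.penetrance_hom if dosage == 2 else planted.phenocopy_rate
        affected = bool(rng.random() < p_aff)
        if dosage == 2:
            tallies["hom"] += 1
            tallies["hom_aff"] += affected
        else:
            tallies["other"] += 1
            tallies["other_aff"] += affected
        return dosage, affected

    n_drawn = 0
    while (len(cases) < config.n_cases or len(controls) < config.n_controls):
        if n_drawn >= budget:
            raise ValueError(
                f"could not assemble {config.n_cases} cases and "
                f"{config.n_controls} controls within {budget} draws; "
                "config is infeasible"
            )
        n_drawn += 1
        dosage, affected = draw_one()
        pool = cases if affected else controls
        target = config.n_cases if affected else config.n_controls
        if len(pool) < target:
            pool.append(dosage)

    if config.ensure_panel_classes:
        swap_rng = rng

        def ensure(pool: list[int], want_affected: bool, predicate, label: str):
            if any(predicate(d) for d in pool):
                return
            for _ in range(budget):
                dosage, affected = draw_one()
                if affected == want_affected and predicate(dosage):
                    # swap out a random surplus member
                    candidates = [i for i, d in enumerate(pool) if not predicate(d)]
                    pool[candidates[int(swap_rng.integers(len(candidates)))]] = dosage
                    return
            raise ValueError(f"panel class unavailable after bounded redraws: {label}")

        ensure(controls, False, lambda d: d == 0, "homozygous-reference control")
        ensure(controls, False, lambda d: d == 2, "homozygous-risk control")

        # the 2+2 informative case panel needs two of each case class
        def top_up(pool, want_affected, predicate, need, label):
            guard = 0
            while sum(predicate(d) for d in pool) < need:
                if guard >= budget:
                    raise ValueError(f"panel class unavailable: {label}")
                guard += 1
                dosage, affected = draw_one()
                if affected == want_affected and predicate(dosage):
                    candidates = [i for i, d in enumerate(pool) if not predicate(d)]
                    pool[candidates[int(rng.integers(len(candidates)))]] = dosage

        half = config.panel_cases // 2
        top_up(cases, True, lambda d: d == 2, half, "homozygous-risk cases")
        top_up(cases, True, lambda d: d != 2, config.panel_cases - half,
               "phenocopy cases")

    planted_dosage = np.array(cases + controls, dtype=np.int8)
    phenotype = np.array(["case"] * len(cases) + ["control"] * len(controls))
    n = len(planted_dosage)
    order = rng.permutation(n)  # interleave cases/controls in sample ids
    planted_dosage, phenotype = planted_dosage[order], phenotype[order]

    variant_defs = _draw_variant_defs(config, rng)
    n_var = len(variant_defs)
    dosage = np.empty((n, n_var), dtype=np.int8)
    for j, vdef in enumerate(variant_defs):
        if vdef.is_planted:
            dosage[:, j] = planted_dosage
            continue
        col = rng.binomial(2, vdef.alt_freq, size=n).astype(np.int8)
        if vdef.ld_copy_prob > 0:
            copied = rng.random(n) < vdef.ld_copy_prob
            col[copied] = planted_dosage[copied]
        dosage[:, j] = col

    sample_ids = [f"HF{i + 1:03d}" for i in range(n)]
    samples = []
    for i, sid in enumerate(sample_ids):
        is_case = phenotype[i] == "case"
        if is_case:
            mu, sd = (
                config.age_case_hom_risk
                if planted_dosage[i] == 2
                else config.age_case_other
            )
            age = max(0.0, float(rng.normal(mu, sd)))
        else:
            mu, sd = config.age_control
            age = max(config.control_min_age, float(rng.normal(mu, sd)))
        male = bool(rng.random() < config.p_male)
        if male:
            p_geld = (
                config.p_gelding_male_case if is_case else config.p_gelding_male_control
            )
            castration = "gelding" if rng.random() < p_geld else "stallion"
        else:
            castration = "mare"
        samples.append(
            Sample(
                id=sid,
                phenotype="case" if is_case else "control",
                sex="male" if male else "female",
                castration=castration,
                age_years=round(age, 1),
                breed=config.breed,
            )
        )

    missing = rng.random((n, n_var)) < config.missing_rate
    genotypes: dict[str, dict[str, GenotypeCall]] = {}
    for j, vdef in enumerate(variant_defs):
        genotypes[vdef.variant_id] = {
            sid: (
                GenotypeCall.MISSING
                if missing[i, j]
                else _DOSAGE_TO_CALL[int(dosage[i, j])]
            )
            for i, sid in enumerate(sample_ids)
        }

    cohort = Cohort(samples=samples, genotypes=genotypes)
    truth = SimulationTruth(
        config=config,
        variants=variant_defs,
        planted_id=next(v.variant_id for v in variant_defs if v.is_planted),
        true_dosage=dosage,
        sample_ids=sample_ids,
        n_drawn_hom_risk=tallies["hom"],
        n_drawn_hom_risk_affected=tallies["hom_aff"],
        n_drawn_other=tallies["other"],
        n_drawn_other_affected=tallies["other_aff"],
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# panel selection


def select_panel(
    cohort: Cohort,
    truth: SimulationTruth,
    scenario: str = "informative",
    seed: int | None = None,
) -> Cohort:
    """Choose the discovery panel (default 4 cases + 2 controls).

    ``informative`` mirrors a maximally informative study design: two
    homozygous-risk cases, two phenocopy (non-homozygous) cases, one
    homozygous-reference control and one homozygous-risk unaffected
    control — the pattern that defeats strict concordance filtering.
    ``random`` samples uniformly. Selection uses the latent (true)
    risk-variant dosages, as a study would after assaying its panel.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    planted_col = truth.variant_ids.index(truth.planted_id)
    dosage_by_id = {
        sid: int(truth.true_dosage[i, planted_col])
        for i, sid in enumerate(truth.sample_ids)
    }
    cases = [s.id for s in cohort.cases]
    controls = [s.id for s in cohort.controls]
    if scenario == "random":
        chosen = list(rng.choice(cases, size=config.panel_cases, replace=False))
        chosen += list(rng.choice(controls, size=config.panel_controls, replace=False))
        return cohort.subset(chosen)
    if scenario != "informative":
        raise ValueError(f"unknown panel scenario {scenario!r}")

    def pick(ids: Sequence[str], want, k: int, label: str) -> list[str]:
        eligible = [sid for sid in ids if want(dosage_by_id[sid])]
        if len(eligible) < k:
            raise ValueError(
                f"cannot assemble informative panel: need {k} {label}, "
                f"cohort has {len(eligible)}"
            )
        return list(rng.choice(eligible, size=k, replace=False))

    half = config.panel_cases // 2
    chosen = pick(cases, lambda d: d == 2, half, "homozygous-risk case(s)")
    chosen += pick(cases, lambda d: d != 2, config.panel_cases - half,
                   "phenocopy case(s)")
    chosen += pick(controls, lambda d: d == 2, 1, "homozygous-risk control(s)")
    chosen += pick(
        [c for c in controls if c not in chosen],
        lambda d: d == 0,
        config.panel_controls - 1,
        "homozygous-reference control(s)",
    )
    return cohort.subset(chosen)


# ---------------------------------------------------------------------------
# callset emission


_CONSEQUENCE_BY_IMPACT = {
    "HIGH": ("stop_gained",),
    "MODERATE": ("missense_variant",),
    "LOW": ("splice_region_variant", "synonymous_variant"),
    "MODIFIER": ("intron_variant", "intergenic_variant"),
}


@dataclass
class CallsetEmission:
    """Bookkeeping for one pair of emitted caller VCFs."""

    path_a: Path
    path_b: Path
    callers_by_id: dict[str, frozenset[str]]
    artifact_ids: list[str]
    false_positive_ids: dict[str, list[str]]
    annotations: dict[str, tuple[str, str, str]]  # id -> (impact, consequence, gene)

    @property
    def dual_fraction(self) -> float:
        true_ids = [
            vid
            for vid, callers in self.callers_by_id.items()
            if vid not in self.false_positive_ids["caller_a"]
            and vid not in self.false_positive_ids["caller_b"]
        ]
        n_dual = sum(len(self.callers_by_id[v]) == 2 for v in true_ids)
        return n_dual / len(true_ids)


def _vcf_header(samples: Sequence[str], region: RegionInterval) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={region.chrom},length={region.end + 1_000_000}>")
    header.add_line(
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site read depth">'
    )
    header.add_line(
        '##INFO=<ID=MQ0F,Number=1,Type=Float,'
        'Description="Fraction of reads with mapping quality zero">'
    )
    header.add_line(
        '##INFO=<ID=ANN,Number=.,Type=String,'
        'Description="Functional annotations: Allele|Annotation|Impact|Gene">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    return header


def _ann_string(alt: str, consequence: str, impact: str, gene: str) -> str:
    return f"{alt}|{consequence}|{impact}|{gene}"


def emit_callsets(
    cohort: Cohort,
    panel: Cohort,
    config: SimulationConfig,
    truth: SimulationTruth,
    out_dir: str | Path,
    seed: int | None = None,
) -> CallsetEmission:
    """Write the two caller VCFs for the discovery panel.

    Caller A reports every true variant; each also appears in caller B
    with probability ``caller_overlap`` (the planted risk variant is a
    clean call both callers agree on). Each caller additionally gains
    unique false-positive records, and ``n_artifact_variants`` planted
    artifact sites receive inflated depth, a high mapping-quality-zero
    fraction and (for the first) a third allele — with perfectly
    concordant panel genotypes, so they reach the candidate list and
    must be caught by the artifact screen. Panel genotypes are the
    latent truth (sequencing-grade, no missingness).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    panel_ids = panel.sample_ids
    if not set(panel_ids) <= set(cohort.sample_ids):
        raise ValueError("panel is not a subset of the cohort")
    row_of = {sid: truth.sample_ids.index(sid) for sid in panel_ids}
    case_ids = {s.id for s in panel.cases}

    impacts, weights = zip(*config.annotation_mix)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    used_positions = {v.position for v in truth.variants}

    def fresh_position() -> int:
        while True:
            pos = int(rng.integers(config.region.start, config.region.end + 1))
            if pos not in used_positions:
                used_positions.add(pos)
                return pos

    def draw_annotation(vdef_alt: str, forced: tuple[str, str, str] | None = None):
        if forced:
            return forced
        impact = str(impacts[int(rng.choice(len(impacts), p=weights))])
        consequence = str(
            _CONSEQUENCE_BY_IMPACT[impact][
                int(rng.integers(len(_CONSEQUENCE_BY_IMPACT[impact])))
            ]
        )
        gene = f"GENE{int(rng.integers(1, 300)):03d}" if consequence != "intergenic_variant" else ""
        return impact, consequence, gene

    # per-record rows: (pos, ref, alts, genotypes-by-sample(allele tuples),
    #                   depth, mq0f, ann, vid)
    rows = []
    callers_by_id: dict[str, frozenset[str]] = {}
    annotations: dict[str, tuple[str, str, str]] = {}
    in_b: dict[str, bool] = {}

    for j, vdef in enumerate(truth.variants):
        ann = draw_annotation(
            vdef.alt,
            ("MODERATE", "missense_variant", "DDB2") if vdef.is_planted else None,
        )
        depth = max(1.0, float(rng.normal(config.mean_depth, config.mean_depth / 6)))
        gts = {}
        for sid in panel_ids:
            d = int(truth.true_dosage[row_of[sid], j])
            gts[sid] = (0, 1) if d == 1 else ((1, 1) if d == 2 else (0, 0))
        vid = vdef.variant_id
        dual = True if vdef.is_planted else bool(rng.random() < config.caller_overlap)
        in_b[vid] = dual
        callers_by_id[vid] = frozenset(
            {"caller_a", "caller_b"} if dual else {"caller_a"}
        )
        annotations[vid] = ann
        rows.append((vdef.position, vdef.ref, (vdef.alt,), gts, depth, 0.0, ann, vid))

    # planted artifact sites: concordant genotypes, pathological metrics
    artifact_ids = []
    for k in range(config.n_artifact_variants):
        pos = fresh_position()
        ref, alt = (NUCLEOTIDES[i] for i in rng.choice(4, size=2, replace=False))
        # first artifact is multiallelic (two ALT alleles)
        alts = (alt,) if k else tuple(sorted(set(NUCLEOTIDES) - {ref}))[:2]
        gts = {
            sid: ((1, 1) if sid in case_ids else (0, 0)) for sid in panel_ids
        }
        depth = config.mean_depth * config.artifact_depth_multiplier
        ann = draw_annotation(alts[0])
        vid = f"{config.region.chrom}:{pos}:{ref}>{alts[0]}"
        artifact_ids.append(vid)
        callers_by_id[vid] = frozenset({"caller_a", "caller_b"})
        annotations[vid] = ann
        rows.append(
            (pos, ref, alts, gts, depth, config.artifact_mq0_fraction, ann, vid)
        )
        in_b[vid] = True

    # caller-unique false positives
    false_positive_ids = {"caller_a": [], "caller_b": []}
    n_fp = rng.binomial(len(truth.variants), config.caller_unique_fp_rate, size=2)
    fp_rows = {"caller_a": [], "caller_b": []}
    for caller, n in zip(("caller_a", "caller_b"), n_fp):
        for _ in range(int(n)):
            pos = fresh_position()
            ref, alt = (NUCLEOTIDES[i] for i in rng.choice(4, size=2, replace=False))
            carrier = panel_ids[int(rng.integers(len(panel_ids)))]
            gts = {
                sid: ((0, 1) if sid == carrier else (0, 0)) for sid in panel_ids
            }
            depth = max(1.0, float(rng.normal(config.mean_depth, config.mean_depth / 6)))
            ann = draw_annotation(alt)
            vid = f"{config.region.chrom}:{pos}:{ref}>{alt}"
            false_positive_ids[caller].append(vid)
            callers_by_id[vid] = frozenset({caller})
            annotations[vid] = ann
            fp_rows[caller].append((pos, ref, (alt,), gts, depth, 0.0, ann, vid))

    def write_vcf(path: Path, caller: str):
        keep = [
            r
            for r in rows
            if caller == "caller_a" or in_b[r[7]]
        ] + fp_rows[caller]
        keep.sort(key=lambda r: r[0])
        header = _vcf_header(panel_ids, config.region)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for pos, ref, alts, gts, depth, mq0f, ann, _vid in keep:
                rec = vcf.new_record(
                    contig=config.region.chrom,
                    start=pos - 1,
                    alleles=(ref,) + alts,
                )
                rec.info["DP"] = int(round(depth))
                rec.info["MQ0F"] = float(mq0f)
                rec.info["ANN"] = (_ann_string(alts[0], ann[1], ann[0], ann[2]),)
                for sid in panel_ids:
                    rec.samples[sid]["GT"] = gts[sid]
                    rec.samples[sid].phased = False
                vcf.write(rec)

    path_a = out_dir / "caller_a.vcf"
    path_b = out_dir / "caller_b.vcf"
    write_vcf(path_a, "caller_a")
    write_vcf(path_b, "caller_b")
    return CallsetEmission(
        path_a=path_a,
        path_b=path_b,
        callers_by_id=callers_by_id,
        artifact_ids=artifact_ids,
        false_positive_ids=false_positive_ids,
        annotations=annotations,
    )


def panel_variant_records(
    truth: SimulationTruth, panel: Cohort, dual_caller: bool = True
) -> list[VariantRecord]:
    """Build in-memory VariantRecords for the panel from the truth matrix.

    A fast path for property tests and replicated end-to-end runs that
    do not need VCF round-tripping: genotypes are the latent truth for
    the panel samples, provenance defaults to both callers, and the
    planted variant carries its forced moderate missense annotation.
    """
    records = []
    callers = frozenset({"caller_a", "caller_b"} if dual_caller else {"caller_a"})
    row_of = {sid: truth.sample_ids.index(sid) for sid in panel.sample_ids}
    for j, vdef in enumerate(truth.variants):
        genotypes = {
            sid: _DOSAGE_TO_CALL[int(truth.true_dosage[i, j])]
            for sid, i in row_of.items()
        }
        records.append(
            VariantRecord(
                chrom=vdef.chrom,
                pos=vdef.position,
                ref=vdef.ref,
                alt=vdef.alt,
                genotypes=genotypes,
                callers=callers,
                impact="MODERATE" if vdef.is_planted else "MODIFIER",
                consequence="missense_variant" if vdef.is_planted else "intron_variant",
                gene="DDB2" if vdef.is_planted else "",
                site_depth=20.0,
            )
        )
    return records
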