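"""End-to-end pipeline orchestration.

Wires the library stages together in the order a study would run them:

``run_prioritize``
    region filter (extended interval) -> callset merge with provenance
    -> three concordance filters on the discovery panel ->
    impact/provenance prioritization cascade -> artifact screen,
    with every exclusion recorded in an audit log.

``run_associate``
    genotyping QC -> recessive-model 2x2 tables -> uncorrected Pearson
    chi-squared -> ranking, with an optional Manhattan-style plot.

Configuration is a plain mapping (typically loaded from YAML); see
:class:`RunConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import assoc_stats, prioritize, variant_io
from .variant_io import Cohort, GenotypeCall, RegionInterval

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_prioritize", "run_associate", "plot_association",
           "provenance_impact_counts"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with study-scale defaults."""

    callset_a: Path | None = None
    callset_b: Path | None = None
    cohort_path: Path | None = None
    panel_path: Path | None = None
    out_dir: Path = Path("varprio_out")
    extended_region: RegionInterval = RegionInterval("12", 10_284_011, 12_767_256)
    strict_region: RegionInterval = RegionInterval("12", 11_284_011, 11_767_256)
    missing_policy: str = "strict"
    max_alleles: int = 2
    depth_ratio_max: float = 3.0
    mq0_max: float = 0.2
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        kw = {}
        paths = data.get("paths", {})
        for key, attr in [
            ("callset_a", "callset_a"),
            ("callset_b", "callset_b"),
            ("cohort", "cohort_path"),
            ("panel", "panel_path"),
            ("out_dir", "out_dir"),
        ]:
            if key in paths:
                kw[attr] = Path(paths[key])
        regions = data.get("regions", {})
        for key, attr in [("extended", "extended_region"), ("strict", "strict_region")]:
            if key in regions:
                r = regions[key]
                kw[attr] = RegionInterval(str(r["chrom"]), int(r["start"]), int(r["end"]))
        filters = data.get("filters", {})
        if "missing_policy" in filters:
            kw["missing_policy"] = filters["missing_policy"]
        screen = data.get("artifact_screen", {})
        for key in ("max_alleles", "depth_ratio_max", "mq0_max"):
            if key in screen:
                kw[key] = screen[key]
        qc = data.get("qc", {})
        for key in ("call_rate_min", "maf_min"):
            if key in qc:
                kw[key] = qc[key]
        if "seed" in data:
            kw["seed"] = int(data["seed"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def _filter_specs(missing_policy: str) -> dict[str, prioritize.FilterSpec]:
    from dataclasses import replace

    return {
        name: replace(spec, missing_policy=missing_policy)
        for name, spec in prioritize.FILTER_PRESETS.items()
    }


def provenance_impact_counts(variants) -> pd.DataFrame:
    """Count variants by impact class and caller provenance.

    The layout used for reporting filter outcomes: one row per impact
    class, columns for caller-unique and dual-caller records.
    """
    rows = []
    for impact in variant_io.IMPACT_ORDER:
        subset = [v for v in variants if v.impact == impact]
        rows.append(
            {
                "impact": impact,
                "unique_to_caller_a": sum(v.callers == {"caller_a"} for v in subset),
                "unique_to_caller_b": sum(v.callers == {"caller_b"} for v in subset),
                "both_callers": sum(len(v.callers) >= 2 for v in subset),
            }
        )
    return pd.DataFrame(rows)


def run_prioritize(
    config: RunConfig,
    panel: Cohort | None = None,
    variants=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full prioritization stage.

    Either pass pre-merged ``variants`` (a list of VariantRecord) and a
    ``panel`` cohort directly, or set ``callset_a``/``callset_b``/
    ``panel_path`` in the config. Returns ``(candidates, audit)``
    DataFrames; the audit table holds one row per variant seen, with
    its fate and reason.
    """
    if panel is None:
        if config.panel_path is None:
            raise ValueError("no panel cohort provided")
        panel = variant_io.read_cohort(config.panel_path)
    if variants is None:
        if config.callset_a is None or config.callset_b is None:
            raise ValueError("no callsets provided")
        set_a = variant_io.read_callset(config.callset_a, "caller_a")
        set_b = variant_io.read_callset(config.callset_b, "caller_b")
        variants = variant_io.merge_callsets(set_a, set_b)

    audit_rows = []
    in_region = variant_io.region_filter(variants, config.extended_region)
    dropped = {v.key for v in variants} - {v.key for v in in_region}
    for v in variants:
        if v.key in dropped:
            audit_rows.append(
                {"variant_id": v.variant_id, "stage": "region_filter",
                 "outcome": "excluded", "detail": "outside extended region"}
            )

    specs = _filter_specs(config.missing_policy)
    filtered = {
        name: prioritize.apply_filter(in_region, panel, spec)
        for name, spec in specs.items()
    }
    for name, kept in filtered.items():
        log.info("%s kept %d of %d variants", name, len(kept), len(in_region))
        log.info("\n%s", provenance_impact_counts(kept).to_string(index=False))

    cascade_config = prioritize.CascadeConfig(strict_region=config.strict_region)
    tagged = prioritize.prioritization_cascade(
        filtered["filter1"], filtered["filter2"], filtered["filter3"], cascade_config
    )
    tagged_keys = {v.key for v, _ in tagged}
    for v in in_region:
        if v.key not in tagged_keys:
            audit_rows.append(
                {"variant_id": v.variant_id, "stage": "cascade",
                 "outcome": "excluded", "detail": "no prioritization route"}
            )

    depths = [v.site_depth for v in in_region if v.site_depth > 0]
    local_median_depth = float(np.median(depths)) if depths else 1.0

    candidate_rows = []
    for v, tag in tagged:
        passed, flags = prioritize.artifact_screen(
            v,
            local_median_depth=local_median_depth,
            max_alleles=config.max_alleles,
            depth_ratio_max=config.depth_ratio_max,
            mq0_max=config.mq0_max,
        )
        stage = "artifact_screen"
        if passed:
            audit_rows.append(
                {"variant_id": v.variant_id, "stage": stage,
                 "outcome": "kept", "detail": tag}
            )
            candidate_rows.append(
                {
                    "variant_id": v.variant_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "impact": v.impact,
                    "consequence": v.consequence,
                    "callers": "+".join(sorted(v.callers)),
                    "tag": tag,
                }
            )
        else:
            audit_rows.append(
                {"variant_id": v.variant_id, "stage": stage,
                 "outcome": "excluded", "detail": ",".join(flags)}
            )
    candidates = pd.DataFrame(
        candidate_rows,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "gene", "impact",
                 "consequence", "callers", "tag"],
    )
    audit = pd.DataFrame(
        audit_rows, columns=["variant_id", "stage", "outcome", "detail"]
    )
    return candidates, audit


def run_associate(
    config: RunConfig, cohort: Cohort | None = None
) -> tuple[pd.DataFrame, list[assoc_stats.AssociationResult]]:
    """Run QC and recessive-model association on a genotyped cohort.

    Returns a result DataFrame (one row per variant, QC failures
    included with empty statistics) and the ranked AssociationResult
    list for variants that were testable. The risk-allele orientation
    defaults to the allele whose homozygote class is enriched in cases.
    """
    if cohort is None:
        if config.cohort_path is None:
            raise ValueError("no cohort provided")
        cohort = variant_io.read_cohort(config.cohort_path)
    phenotypes = {s.id: s.phenotype for s in cohort.samples}
    qc_records = assoc_stats.qc_filter(
        cohort, call_rate_min=config.call_rate_min, maf_min=config.maf_min
    )
    results = []
    rows = {}
    for qc in qc_records:
        row = {
            "variant_id": qc.variant_id,
            "call_rate": qc.call_rate,
            "maf": qc.maf,
            "qc_pass": qc.passed,
            "qc_fail_reasons": ",".join(qc.fail_reasons),
        }
        rows[qc.variant_id] = row
        if not qc.passed:
            continue
        gmap = cohort.genotypes[qc.variant_id]
        orientation = _risk_orientation(gmap, phenotypes)
        try:
            table = assoc_stats.recessive_table(
                gmap, phenotypes, risk_allele_is_alt=orientation
            )
            chi2, p = assoc_stats.chi_square_2x2(table)
        except ValueError as exc:
            # expected for low-MAF variants with no homozygous-risk class
            row["qc_pass"] = False
            row["qc_fail_reasons"] = "untestable_recessive_contrast"
            log.info("variant %s untestable: %s", qc.variant_id, exc)
            continue
        chrom, pos = _parse_variant_id(qc.variant_id)
        results.append(
            assoc_stats.AssociationResult(
                variant_id=qc.variant_id,
                table=table,
                chi2=chi2,
                p=p,
                risk_allele="alt" if orientation else "ref",
                chrom=chrom,
                pos=pos,
            )
        )
    if not results:
        log.warning("no variants survived QC; association table is empty")
    ranked = assoc_stats.rank_results(results)
    for r in ranked:
        rows[r.variant_id].update(
            {
                "n_case_nonrisk": r.table.a,
                "n_case_hom_risk": r.table.b,
                "n_control_nonrisk": r.table.c,
                "n_control_hom_risk": r.table.d,
                "risk_allele": r.risk_allele,
                "chi2": r.chi2,
                "p": r.p,
                "neg_log10_p": r.neg_log10_p,
                "rank": r.rank,
            }
        )
    df = pd.DataFrame(list(rows.values()))
    if "rank" in df.columns:
        df = df.sort_values(
            ["rank"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return df, ranked


def _parse_variant_id(variant_id: str) -> tuple[str, int]:
    parts = variant_id.split(":")
    try:
        return parts[0], int(parts[1])
    except (IndexError, ValueError):
        return variant_id, 0


def _risk_orientation(
    gmap: Mapping[str, GenotypeCall], phenotypes: Mapping[str, str]
) -> bool:
    """True when the alternate allele's homozygote class is the one
    enriched in cases (the default recessive risk orientation). Both
    orientations are compared by case-vs-control homozygote-fraction
    excess; ties go to the alternate allele."""

    def hom_frac(phenotype: str, hom: GenotypeCall) -> float:
        called = [
            g
            for s, g in gmap.items()
            if phenotypes.get(s) == phenotype and g.is_called
        ]
        if not called:
            return 0.0
        return sum(g is hom for g in called) / len(called)

    excess_alt = hom_frac("case", GenotypeCall.HOM_ALT) - hom_frac(
        "control", GenotypeCall.HOM_ALT
    )
    excess_ref = hom_frac("case", GenotypeCall.HOM_REF) - hom_frac(
        "control", GenotypeCall.HOM_REF
    )
    return excess_alt >= excess_ref


def plot_association(
    results, path: str | Path, strict_region: RegionInterval | None = None
) -> None:
    """Manhattan-style plot: -log10 p by genomic position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    xs = [r.pos for r in results]
    ys = [r.neg_log10_p for r in results]
    ax.scatter(xs, ys, s=18, c="tab:blue")
    if results:
        top = min(results, key=lambda r: r.p)
        ax.annotate(
            top.variant_id, (top.pos, top.neg_log10_p),
            textcoords="offset points", xytext=(5, -3), fontsize=8,
        )
    if strict_region is not None:
        ax.axvspan(strict_region.start, strict_region.end, color="0.9", zorder=0)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
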