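"""Orchestration of the analysis branches and study-style reports.

Three analyses share one filter cascade (quality -> gene/region exclusion
-> rarity/control) and diverge at the sharing step:

* population analysis — the 20%-carrier + one-homozygote rule per
  population, with the HLA region excluded;
* family analysis — the two-homozygote rule per family, HLA retained
  (annotation is reporting-only here: intronic hits are reported);
* genome validation & discovery — genotype counts for exome-identified
  variants in the genome data, plus the 7-of-8-carrier discovery rule with
  a hard exonic/nonsynonymous filter.

Reports are plain TSV tables mirroring the column layout of the study's
result tables, plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotation import damaging_source_count, functional_filter
from .comphet import CompoundHetCall
from .model import (
    AnnotationTable,
    FilterConfig,
    SampleSet,
    VariantKey,
    VariantRecord,
    format_key,
)
from .qc import FilterDecision, filter_variants, write_decision_log
from .sharing import (
    SharingResult,
    count_genotypes,
    family_filter,
    population_filter,
    wgs_discovery_filter,
)

logger = logging.getLogger(__name__)

_REPORT_COLUMNS = [
    "scope", "gene", "chrom", "pos", "alt", "ref",
    "AA", "AR", "RR", "missing", "carrier_fraction",
    "location", "function", "freq_1000g", "n_damaging",
]


@dataclass
class AnalysisReport:
    """Result bundle of one analysis run."""

    name: str
    config: dict
    stage_counts: list[tuple[str, int]]
    rows: pd.DataFrame
    decisions: dict[VariantKey, FilterDecision]
    extra: dict = field(default_factory=dict)

    @property
    def passing_keys(self) -> list[VariantKey]:
        if self.rows.empty:
            return []
        keys = list(
            zip(self.rows["chrom"], self.rows["pos"], self.rows["ref"], self.rows["alt"])
        )
        return list(dict.fromkeys(keys))

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.rows.to_csv(os.path.join(out_dir, f"{self.name}_results.tsv"),
                         sep="\t", index=False)
        write_decision_log(os.path.join(out_dir, f"{self.name}_drops.tsv"),
                           self.decisions)
        manifest = {
            "analysis": self.name,
            "config": self.config,
            "stage_counts": [[s, n] for s, n in self.stage_counts],
            "n_result_rows": int(len(self.rows)),
        }
        with open(os.path.join(out_dir, f"{self.name}_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _annotation_columns(key: VariantKey, annotations: AnnotationTable) -> dict:
    ann = annotations.get(key)
    return {
        "gene": ann.gene if ann else None,
        "location": ann.location if ann else None,
        "function": ann.function if ann else None,
        "freq_1000g": ann.freq_1000g if ann else None,
        "n_damaging": damaging_source_count(ann),
    }


def _result_row(key: VariantKey, result: SharingResult,
                annotations: AnnotationTable) -> dict:
    chrom, pos, ref, alt = key
    c = result.counts
    return {
        "scope": result.scope,
        "chrom": chrom, "pos": pos, "alt": alt, "ref": ref,
        "AA": c.n_hom_alt, "AR": c.n_het, "RR": c.n_hom_ref,
        "missing": c.n_missing,
        "carrier_fraction": round(result.carrier_fraction, 6),
        **_annotation_columns(key, annotations),
    }


def _finish_rows(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return df.sort_values(
        ["scope", "chrom", "pos", "alt"], kind="mergesort"
    ).reset_index(drop=True)


def run_family_analysis(
    variants: Sequence[VariantRecord],
    roster: SampleSet,
    annotations: AnnotationTable,
    config: Optional[FilterConfig] = None,
    exclude_hla: bool = False,
) -> AnalysisReport:
    """Family-specific scan: QC -> rarity -> two-homozygote family rule.

    Only families with at least two sequenced affected members enter the
    scan; annotation columns are attached for reporting but intronic or
    intergenic hits are not filtered out.
    """
    config = config or FilterConfig()
    eligible = [
        f for f in roster.family_ids()
        if len(roster.family_members(f, affected_only=True)) >= 2
    ]
    if not eligible:
        raise ValueError("no family with >= 2 sequenced affected members")

    decisions = filter_variants(variants, annotations, roster, config,
                                exclude_hla=exclude_hla)
    kept = [v for v in variants if decisions[v.key].kept]
    rows = []
    for v in kept:
        counts_by_family = {
            fam: count_genotypes(v, roster.family_members(fam), roster)
            for fam in eligible
        }
        for res in family_filter(counts_by_family, config, key=v.key):
            if res.passed:
                rows.append(_result_row(v.key, res, annotations))
    df = _finish_rows(rows)
    return AnalysisReport(
        name="family_analysis",
        config=config.to_dict(),
        stage_counts=[
            ("input", len(variants)),
            ("after_qc_rarity", len(kept)),
            ("passing_rows", len(df)),
        ],
        rows=df,
        decisions=decisions,
    )


def run_population_analysis(
    variants: Sequence[VariantRecord],
    roster: SampleSet,
    annotations: AnnotationTable,
    config: Optional[FilterConfig] = None,
    exclude_hla: bool = True,
) -> AnalysisReport:
    """Population-specific scan with the 20%-carrier + homozygote rule."""
    config = config or FilterConfig()
    decisions = filter_variants(variants, annotations, roster, config,
                                exclude_hla=exclude_hla)
    kept = [v for v in variants if decisions[v.key].kept]
    rows = []
    for pop in roster.populations():
        cases = roster.affected_ids(pop)
        if not cases:
            logger.warning("population %s has no cases; skipped", pop)
            continue
        for v in kept:
            counts = count_genotypes(v, cases, roster)
            res = population_filter(counts, len(cases), config,
                                    scope=pop, key=v.key)
            if res.passed:
                rows.append(_result_row(v.key, res, annotations))
    df = _finish_rows(rows)
    return AnalysisReport(
        name="population_analysis",
        config=config.to_dict(),
        stage_counts=[
            ("input", len(variants)),
            ("after_qc_rarity", len(kept)),
            ("passing_rows", len(df)),
        ],
        rows=df,
        decisions=decisions,
    )


def run_wgs_validation_and_discovery(
    wes_hits: Sequence[VariantKey],
    wgs_variants: Sequence[VariantRecord],
    roster: SampleSet,
    annotations: AnnotationTable,
    config: Optional[FilterConfig] = None,
    target_family: Optional[str] = None,
    comphet_calls: Optional[Sequence[CompoundHetCall]] = None,
) -> AnalysisReport:
    """Genome-data validation of exome hits plus within-family discovery.

    Validation reports genotype counts for each exome-identified variant
    over all sequenced affected members of the target family and,
    separately, over the members absent from the exome analysis (dataset
    tag not ``both``).  Discovery applies the QC/rarity cascade, the
    one-homozygote + carrier-quota rule and a hard exonic/nonsynonymous
    filter, and reports only variants not already identified in the exome
    scan.  Validated compound-heterozygote gene calls may be passed in to
    form the combined family result set.
    """
    config = config or FilterConfig()
    if target_family is None:
        families = roster.family_ids()
        if len(families) != 1:
            raise ValueError("target_family required with a multi-family roster")
        target_family = families[0]
    members = roster.family_members(target_family, affected_only=True)
    if not members:
        raise ValueError(f"family {target_family} absent from the genome roster")
    non_overlap = [
        sid for sid in members if roster.get(sid).dataset != "both"
    ]
    by_key = {v.key: v for v in wgs_variants}
    wes_hit_set = set(wes_hits)

    validation_rows = []
    for key in wes_hits:
        v = by_key.get(key)
        if v is None:
            logger.warning("exome hit %s absent from genome data", format_key(key))
            continue
        counts_all = count_genotypes(v, members, roster)
        res = wgs_discovery_filter(counts_all, len(members), config,
                                   scope=target_family, key=key)
        row = _result_row(key, res, annotations)
        row["analysis"] = "validation"
        row["validated"] = res.passed
        counts_new = count_genotypes(v, non_overlap, roster)
        row["AA_nonoverlap"] = counts_new.n_hom_alt
        row["AR_nonoverlap"] = counts_new.n_het
        row["RR_nonoverlap"] = counts_new.n_hom_ref
        validation_rows.append(row)

    decisions = filter_variants(wgs_variants, annotations, roster, config,
                                exclude_hla=False)
    discovery_rows = []
    for v in wgs_variants:
        if v.key in wes_hit_set or not decisions[v.key].kept:
            continue
        if not functional_filter(annotations.get(v.key)):
            continue
        counts = count_genotypes(v, members, roster)
        res = wgs_discovery_filter(counts, len(members), config,
                                   scope=target_family, key=v.key)
        if res.passed:
            row = _result_row(v.key, res, annotations)
            row["analysis"] = "discovery"
            row["validated"] = True
            discovery_rows.append(row)

    columns = _REPORT_COLUMNS + ["analysis", "validated",
                                 "AA_nonoverlap", "AR_nonoverlap", "RR_nonoverlap"]
    df = pd.DataFrame(validation_rows + discovery_rows, columns=columns)

    combined = [(r["chrom"], r["pos"], r["ref"], r["alt"])
                for r in validation_rows if r["validated"]]
    combined += [(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in discovery_rows]
    comphet_validated_keys: list[VariantKey] = []
    if comphet_calls:
        for call in comphet_calls:
            if call.gene_qualifies:
                comphet_validated_keys += [
                    k for k in call.variant_keys if k not in comphet_validated_keys
                ]
    combined += [k for k in comphet_validated_keys if k not in combined]

    return AnalysisReport(
        name="wgs_validation_discovery",
        config=config.to_dict(),
        stage_counts=[
            ("input", len(wgs_variants)),
            ("validation_variants", len(validation_rows)),
            ("discovery_variants", len(discovery_rows)),
            ("combined_variants", len(combined)),
        ],
        rows=df,
        decisions=decisions,
        extra={
            "combined_variant_keys": combined,
            "comphet_validated_keys": comphet_validated_keys,
            "target_family": target_family,
        },
    )
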