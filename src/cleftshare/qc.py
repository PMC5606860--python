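"""Variant-level drop rules: quality metrics, exclusion lists, rarity.

Each rule is a pure predicate on one variant; a variant is kept iff no rule
fires, so the set of kept variants does not depend on the order in which
the three operations are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .model import (
    CARRIER_STATES,
    AnnotationRecord,
    AnnotationTable,
    FilterConfig,
    SampleSet,
    VariantKey,
    VariantRecord,
    format_key,
)

logger = logging.getLogger(__name__)


class DropReason(str, Enum):
    MQ_LOW = "MQ_LOW"
    DEPTH_LOW = "DEPTH_LOW"
    DEPTH_HIGH = "DEPTH_HIGH"
    CALL_RATE_LOW = "CALL_RATE_LOW"
    REPLICATE_DISCORDANT = "REPLICATE_DISCORDANT"
    MONOMORPHIC = "MONOMORPHIC"
    VQSR_AND_ML_FAIL = "VQSR_AND_ML_FAIL"
    FREQUENT_HITTER = "FREQUENT_HITTER"
    HLA_REGION = "HLA_REGION"
    COMMON_1000G = "COMMON_1000G"
    DBSNP_COMMON = "DBSNP_COMMON"
    CONTROL_CARRIER = "CONTROL_CARRIER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class FilterDecision:
    """Keep/drop verdict for one variant with machine-readable reasons."""

    key: VariantKey
    reasons: list[DropReason] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not self.reasons

    def merge(self, other: "FilterDecision") -> "FilterDecision":
        if other.key != self.key:
            raise ValueError("cannot merge decisions for different variants")
        merged = list(self.reasons)
        merged += [r for r in other.reasons if r not in merged]
        return FilterDecision(self.key, merged)


class MissingQCFieldError(ValueError):
    """A QC metric required in strict mode is absent from the variant."""


def _require(variant: VariantRecord, name: str, config: FilterConfig):
    value = getattr(variant, name)
    if value is None:
        if config.strict_qc:
            raise MissingQCFieldError(
                f"variant {format_key(variant.key)} has no {name}; "
                "set strict_qc=False to pass absent metrics through"
            )
        logger.warning(
            "variant %s has no %s; rule skipped", format_key(variant.key), name
        )
    return value


def apply_quality_filter(
    variant: VariantRecord,
    config: FilterConfig,
    roster: Optional[SampleSet] = None,
) -> FilterDecision:
    """Apply the per-variant quality drop rules.

    A variant is dropped if any single metric fails: mapping quality below
    30, site depth outside [8, 20000], non-Y call rate below 98%, genotype
    discordance in more than one declared duplicate pair, a monomorphic
    genotype vector, or failing *both* the variant-recalibration filter and
    the low-quality classifier (probability strictly above 0.70).  The
    call-rate rule is skipped for Y-chromosome variants.
    """
    reasons: list[DropReason] = []

    mq = _require(variant, "mapping_quality", config)
    if mq is not None and mq < config.min_mapping_quality:
        reasons.append(DropReason.MQ_LOW)

    depth = _require(variant, "depth", config)
    if depth is not None:
        if depth < config.min_depth:
            reasons.append(DropReason.DEPTH_LOW)
        elif depth > config.max_depth:
            reasons.append(DropReason.DEPTH_HIGH)

    if variant.chrom.upper() != "Y":
        call_rate = _require(variant, "call_rate", config)
        if call_rate is not None and call_rate < config.min_call_rate:
            reasons.append(DropReason.CALL_RATE_LOW)

    rep = variant.replicate_discordant_pairs
    if rep is None and roster is not None:
        from .io import count_discordant_pairs

        rep = count_discordant_pairs(variant, roster)
    if rep is not None and rep > config.max_replicate_discordant_pairs:
        reasons.append(DropReason.REPLICATE_DISCORDANT)

    if variant.is_monomorphic():
        reasons.append(DropReason.MONOMORPHIC)

    # Joint rule: drop only when the variant fails recalibration AND the
    # classifier probability strictly exceeds the threshold.
    if variant.vqsr_pass is False:
        lowq = _require(variant, "low_quality_prob", config)
        if lowq is not None and lowq > config.low_quality_prob_threshold:
            reasons.append(DropReason.VQSR_AND_ML_FAIL)

    return FilterDecision(variant.key, reasons)


def apply_exclusion_lists(
    variant: VariantRecord,
    annotation: Optional[AnnotationRecord],
    config: FilterConfig,
    exclude_hla: bool = True,
) -> FilterDecision:
    """Drop variants in frequent-hitter genes or (optionally) the HLA region.

    An unannotated variant passes the gene exclusion.  HLA exclusion is a
    per-analysis toggle: population-level scans exclude the region, the
    family-level scan does not.
    """
    reasons: list[DropReason] = []
    gene = annotation.gene if annotation is not None else None
    if gene is not None and gene in config.frequent_hitter_genes:
        reasons.append(DropReason.FREQUENT_HITTER)
    if exclude_hla and config.in_hla_region(variant.chrom, variant.pos):
        reasons.append(DropReason.HLA_REGION)
    return FilterDecision(variant.key, reasons)


def apply_rarity_filter(
    variant: VariantRecord,
    annotation: Optional[AnnotationRecord],
    control_genotypes: Sequence[str],
    config: FilterConfig,
) -> FilterDecision:
    """Drop common variants and variants carried by a control sample.

    Common means reference-panel frequency strictly above ``max_maf`` (5%)
    or membership in the common-variant set of dbSNP.  A frequency absent
    from every database is treated as zero: novel alleles are rare.
    """
    reasons: list[DropReason] = []
    freq = annotation.freq_1000g if annotation is not None else None
    if freq is not None and freq > config.max_maf:
        reasons.append(DropReason.COMMON_1000G)
    if annotation is not None and annotation.dbsnp_common:
        reasons.append(DropReason.DBSNP_COMMON)
    if any(g in CARRIER_STATES for g in control_genotypes):
        reasons.append(DropReason.CONTROL_CARRIER)
    return FilterDecision(variant.key, reasons)


def control_genotypes_of(variant: VariantRecord, roster: SampleSet) -> list[str]:
    return [
        variant.genotypes[roster.index_of(s.sample_id)] for s in roster.controls
    ]


def filter_variants(
    variants: Iterable[VariantRecord],
    annotations: AnnotationTable,
    roster: SampleSet,
    config: FilterConfig,
    exclude_hla: bool = True,
) -> dict[VariantKey, FilterDecision]:
    """Run the full QC + exclusion + rarity cascade over a variant set.

    Returns one merged :class:`FilterDecision` per variant; the kept set is
    the conjunction of the three pure predicates and therefore independent
    of evaluation order.
    """
    decisions: dict[VariantKey, FilterDecision] = {}
    for v in variants:
        ann = annotations.get(v.key)
        d = apply_quality_filter(v, config, roster)
        d = d.merge(apply_exclusion_lists(v, ann, config, exclude_hla=exclude_hla))
        d = d.merge(
            apply_rarity_filter(v, ann, control_genotypes_of(v, roster), config)
        )
        decisions[v.key] = d
    return decisions


def write_decision_log(path, decisions: dict[VariantKey, FilterDecision]) -> None:
    """Write the keep/drop log as TSV (key, kept, semicolon-joined reasons)."""
    with open(path, "w") as fh:
        fh.write("variant\tkept\treasons\n")
        for key in sorted(decisions):
            d = decisions[key]
            reasons = ";".join(r.value for r in d.reasons)
            fh.write(f"{format_key(key)}\t{d.kept}\t{reasons}\n")
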