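"""Functional post-filters and the regulatory-region variant scan.

Pathogenicity is summarised as the number of predictor sources (out of
nine) calling a variant damaging; the predictors themselves are consumed
as annotation columns, never recomputed.  The regulatory scan tallies rare
het / homozygous-alternate calls inside pre-built enhancer and promoter
intervals; screening of candidate regions (enhancer confidence score above
5, promoters within 200 kb of the transcription start site) happens when
the region BED is constructed, not inside the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import RegionSet
from .model import (
    HET,
    HOM_ALT,
    AnnotationRecord,
    SampleSet,
    VariantKey,
    VariantRecord,
)

logger = logging.getLogger(__name__)


def functional_filter(annotation: Optional[AnnotationRecord]) -> bool:
    """True iff the variant is exonic and nonsynonymous."""
    if annotation is None:
        return False
    return (
        (annotation.location or "").lower() == "exonic"
        and (annotation.function or "").lower() == "nonsynonymous"
    )


def damaging_source_count(annotation: Optional[AnnotationRecord]) -> int:
    """Number of predictor sources (0-9) calling the variant damaging."""
    if annotation is None:
        return 0
    return annotation.n_damaging


@dataclass
class RegulatoryScanResult:
    """Per-sample tallies of rare variant calls inside regulatory regions."""

    variant_regions: dict[VariantKey, list[str]]  # key -> region names hit
    het_counts: dict[str, int]
    hom_alt_counts: dict[str, int]
    max_het_samples: list[str] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variant_regions)


def regulatory_region_scan(
    variants: Sequence[VariantRecord],
    regions: RegionSet,
    samples: Sequence[str],
    roster: SampleSet,
) -> RegulatoryScanResult:
    """Tally het and hom-alt calls at rare variants inside regulatory regions.

    ``variants`` should already be rarity-filtered.  A variant inside
    several overlapping regions is counted once per sample.  The samples
    with the maximum heterozygous count are reported as a set (ties kept).
    """
    if not regions:
        logger.warning("regulatory scan called with an empty region set")
        return RegulatoryScanResult({}, {s: 0 for s in samples}, {s: 0 for s in samples})

    variant_regions: dict[VariantKey, list[str]] = {}
    het_counts = {s: 0 for s in samples}
    hom_counts = {s: 0 for s in samples}
    for v in variants:
        names = regions.regions_at(v.chrom, v.pos)
        if not names:
            continue
        variant_regions[v.key] = names
        for sid in samples:
            g = v.genotypes[roster.index_of(sid)]
            if g == HET:
                het_counts[sid] += 1
            elif g == HOM_ALT:
                hom_counts[sid] += 1
    max_het = max(het_counts.values(), default=0)
    max_samples = sorted(s for s, c in het_counts.items() if c == max_het and max_het > 0)
    return RegulatoryScanResult(variant_regions, het_counts, hom_counts, max_samples)


def write_regulatory_report(
    path,
    result: RegulatoryScanResult,
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    roster: SampleSet,
) -> None:
    """Write the scan as TSV: rows = in-region variants, columns = samples."""
    from .model import format_key

    by_key = {v.key: v for v in variants}
    with open(path, "w") as fh:
        fh.write("variant\tregions\t" + "\t".join(samples) + "\n")
        for key in sorted(result.variant_regions):
            v = by_key[key]
            regions = ";".join(result.variant_regions[key])
            calls = "\t".join(
                v.genotypes[roster.index_of(s)] for s in samples
            )
            fh.write(f"{format_key(key)}\t{regions}\t{calls}\n")
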