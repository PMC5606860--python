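"""Unphased compound-heterozygote detection per gene.

Without phase information, two heterozygous rare variants in one gene may
sit on opposite parental haplotypes (a true compound heterozygote) or on
the same one (a rare haplotype); both configurations are reported as
*potential* compound heterozygotes.  A gene qualifies when every index
individual carries more than one exonic, nonsynonymous rare variant in it
in the heterozygous state — homozygous-alternate sites do not count toward
the pair, as those are the province of the shared-homozygosity filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotation import functional_filter
from .model import (
    HET,
    AnnotationTable,
    SampleSet,
    VariantKey,
    VariantRecord,
)

#: Minimum heterozygous sites per gene per individual ("more than one").
MIN_HET_SITES = 2


@dataclass
class CompoundHetCall:
    """Per-gene result of the compound-heterozygote scan."""

    gene: str
    variant_keys: list[VariantKey]
    het_counts: dict[str, int]  # sample id -> heterozygous sites in gene
    gene_qualifies: bool
    flagged: dict[str, bool] = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return sum(self.flagged.values())


def _qualifying_by_gene(
    variants: Sequence[VariantRecord],
    annotations: AnnotationTable,
) -> dict[str, list[VariantRecord]]:
    """Group exonic, nonsynonymous annotated variants by gene symbol."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None or ann.gene is None or not functional_filter(ann):
            continue
        by_gene.setdefault(ann.gene, []).append(v)
    return by_gene


def _het_count(
    gene_variants: Sequence[VariantRecord],
    sample_id: str,
    roster: SampleSet,
) -> int:
    idx = roster.index_of(sample_id)
    return sum(1 for v in gene_variants if v.genotypes[idx] == HET)


def find_compound_het_genes(
    variants: Sequence[VariantRecord],
    annotations: AnnotationTable,
    index_individuals: Sequence[str],
    roster: SampleSet,
) -> list[CompoundHetCall]:
    """Scan filtered variants for genes with potential compound heterozygotes.

    ``variants`` must already have passed the QC and rarity filters; the
    scan keeps exonic, nonsynonymous sites, groups them by gene, and marks
    a gene as qualifying iff *every* index individual is heterozygous at
    two or more of its sites.
    """
    if not index_individuals:
        raise ValueError("compound-het scan needs at least one index individual")
    calls = []
    for gene, gene_variants in sorted(_qualifying_by_gene(variants, annotations).items()):
        het_counts = {
            sid: _het_count(gene_variants, sid, roster) for sid in index_individuals
        }
        qualifies = all(c >= MIN_HET_SITES for c in het_counts.values())
        calls.append(
            CompoundHetCall(
                gene=gene,
                variant_keys=[v.key for v in gene_variants],
                het_counts=het_counts,
                gene_qualifies=qualifies,
            )
        )
    return calls


def validate_compound_het(
    genes: Iterable[str],
    validation_variants: Sequence[VariantRecord],
    annotations: AnnotationTable,
    validation_individuals: Sequence[str],
    roster: SampleSet,
) -> list[CompoundHetCall]:
    """Re-assess qualifying genes in an independent genotype set.

    For each gene, every validation individual is flagged as a potential
    compound heterozygote iff they are heterozygous at two or more of the
    gene's exonic, nonsynonymous sites; a gene is validated when at least
    one individual is flagged.  Overlapping individuals between discovery
    and validation must be removed by the caller.  A gene with no
    assessable site in the validation set is reported with an empty variant
    list and no flags rather than raising.
    """
    by_gene = _qualifying_by_gene(validation_variants, annotations)
    results = []
    for gene in genes:
        gene_variants = by_gene.get(gene, [])
        het_counts = {
            sid: _het_count(gene_variants, sid, roster)
            for sid in validation_individuals
        }
        flagged = {sid: c >= MIN_HET_SITES for sid, c in het_counts.items()}
        results.append(
            CompoundHetCall(
                gene=gene,
                variant_keys=[v.key for v in gene_variants],
                het_counts=het_counts,
                gene_qualifies=any(flagged.values()),
                flagged=flagged,
            )
        )
    return results


def write_compound_het_report(path, calls: Iterable[CompoundHetCall]) -> None:
    from .model import format_key

    with open(path, "w") as fh:
        fh.write("gene\tvariants\thet_counts\tqualifies\tflagged\n")
        for c in calls:
            variants = ";".join(format_key(k) for k in c.variant_keys) or "."
            counts = ";".join(f"{s}={n}" for s, n in c.het_counts.items())
            flagged = ";".join(s for s, f in c.flagged.items() if f) or "."
            fh.write(
                f"{c.gene}\t{variants}\t{counts}\t{c.gene_qualifies}\t{flagged}\n"
            )
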