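"""Counting-based discovery filters over sample subsets.

Three sharing criteria, all operating on genotype tallies of affected
individuals:

* population level — at least one case homozygous for the alternate allele
  and at least 20% of all cases carrying it;
* family level — at least two affected members of one family homozygous for
  the alternate allele;
* within-family genome-wide discovery — at least one homozygote and at
  least seven of eight family members carrying the allele (scaled
  proportionally for other family sizes).

Missing genotypes stay in the denominator by default ("all cases") but can
never satisfy a carrier or homozygote requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    FilterConfig,
    GenotypeCounts,
    SampleSet,
    VariantKey,
    VariantRecord,
)


@dataclass
class SharingResult:
    """Outcome of one sharing filter for one variant in one scope."""

    key: Optional[VariantKey]
    scope: str  # population name or family id
    counts: GenotypeCounts
    carrier_fraction: float
    passed: bool


def count_genotypes(
    variant: VariantRecord,
    subset: Sequence[str],
    roster: SampleSet,
) -> GenotypeCounts:
    """Tally AA/AR/RR/missing calls of ``variant`` over a sample subset."""
    tally = {HOM_ALT: 0, HET: 0, HOM_REF: 0, MISSING: 0}
    for sid in subset:
        tally[variant.genotypes[roster.index_of(sid)]] += 1
    return GenotypeCounts(
        n_hom_alt=tally[HOM_ALT],
        n_het=tally[HET],
        n_hom_ref=tally[HOM_REF],
        n_missing=tally[MISSING],
    )


def population_filter(
    counts: GenotypeCounts,
    n_cases: int,
    config: FilterConfig,
    scope: str = "population",
    key: Optional[VariantKey] = None,
) -> SharingResult:
    """Population-level sharing criterion over all cases of one population.

    Passes iff at least ``population_min_hom`` cases are homozygous for the
    alternate allele and the carrier fraction (homozygous or heterozygous)
    reaches ``population_min_carrier_fraction`` of all cases.
    """
    if n_cases <= 0:
        raise ValueError("population filter needs at least one case")
    denom = n_cases
    if config.population_exclude_missing_from_denominator:
        denom = n_cases - counts.n_missing
    fraction = counts.n_carriers / denom if denom > 0 else 0.0
    passed = (
        counts.n_hom_alt >= config.population_min_hom
        and fraction >= config.population_min_carrier_fraction
    )
    return SharingResult(key, scope, counts, fraction, passed)


def family_filter(
    counts_by_family: Mapping[str, GenotypeCounts],
    config: FilterConfig,
    key: Optional[VariantKey] = None,
) -> list[SharingResult]:
    """Family-level criterion: >= 2 affected members homozygous-alternate.

    Every family present must have at least two sequenced affected members;
    families reduced to a single member belong upstream of this filter and
    raise an error here.
    """
    results = []
    for family_id, counts in counts_by_family.items():
        if counts.total < 2:
            raise ValueError(
                f"family {family_id} has fewer than two sequenced affected "
                "members and should have been excluded upstream"
            )
        denom = counts.total
        fraction = counts.n_carriers / denom if denom else 0.0
        passed = counts.n_hom_alt >= config.family_min_hom
        results.append(SharingResult(key, family_id, counts, fraction, passed))
    return results


def wgs_discovery_filter(
    counts: GenotypeCounts,
    n_members: int,
    config: FilterConfig,
    scope: str = "family",
    key: Optional[VariantKey] = None,
) -> SharingResult:
    """Within-family discovery criterion for genome-sequenced families.

    Passes iff at least one member is homozygous for the alternate allele
    and at least ``wgs_carrier_quota(n_members)`` members carry it (7 when
    the family has the reference size of 8).  With
    ``wgs_homozygote_counts_as_carrier=False`` the quota must be met after
    setting aside one obligate homozygote.
    """
    quota = config.wgs_carrier_quota(n_members)
    effective_quota = quota if config.wgs_homozygote_counts_as_carrier else quota + 1
    if n_members < effective_quota:
        raise ValueError(
            f"family of {n_members} cannot meet a carrier quota of "
            f"{effective_quota}"
        )
    fraction = counts.n_carriers / n_members if n_members else 0.0
    passed = (
        counts.n_hom_alt >= config.wgs_min_hom
        and counts.n_carriers >= effective_quota
    )
    return SharingResult(key, scope, counts, fraction, passed)


def write_sharing_results(path, results: Iterable[SharingResult]) -> None:
    """Write sharing results as TSV (scope, key, tallies, fraction, passed)."""
    from .model import format_key

    with open(path, "w") as fh:
        fh.write(
            "scope\tvariant\tAA\tAR\tRR\tmissing\tcarrier_fraction\tpassed\n"
        )
        for r in results:
            key = format_key(r.key) if r.key else "."
            c = r.counts
            fh.write(
                f"{r.scope}\t{key}\t{c.n_hom_alt}\t{c.n_het}\t{c.n_hom_ref}\t"
                f"{c.n_missing}\t{r.carrier_fraction:.6g}\t{r.passed}\n"
            )
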