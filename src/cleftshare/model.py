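"""Core domain types for family-based rare-variant sharing analysis.

The pipeline operates on biallelic variant records with per-sample genotype
calls collapsed to four states relative to the alternate allele:

* ``AA`` — homozygous for the alternate allele
* ``AR`` — heterozygous
* ``RR`` — homozygous for the reference allele
* ``missing`` — no call

Multiallelic sites are split on ingest so that every record carries exactly
one alternate allele; a sample heterozygous for two different alternates is
``AR`` on each split record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import yaml

# Genotype states (relative to the alternate allele of a biallelic record).
HOM_ALT = "AA"
HET = "AR"
HOM_REF = "RR"
MISSING = "missing"

GENOTYPE_STATES = (HOM_ALT, HET, HOM_REF, MISSING)

#: Genotype states that make a sample a carrier of the alternate allele.
CARRIER_STATES = (HOM_ALT, HET)

# The nine pathogenicity predictor sources whose damaging/tolerated calls
# are aggregated into a single damaging-source count.
PREDICTOR_SOURCES = (
    "sift",
    "polyphen2_hdiv",
    "polyphen2_hvar",
    "lrt",
    "mutation_taster",
    "mutation_assessor",
    "fathmm",
    "radial_svm",
    "lr",
)

#: Per-source label sets meaning "predicted damaging".  Predictor tools emit
#: heterogeneous one-letter alphabets; anything outside the set (including a
#: missing value) counts as not damaging.
DAMAGING_LABELS: dict[str, frozenset[str]] = {
    source: frozenset({"D", "damaging", "deleterious", "1"})
    for source in PREDICTOR_SOURCES
}
# Mutation Taster uses A (disease causing automatic) and D (disease causing).
DAMAGING_LABELS["mutation_taster"] = frozenset({"A", "D", "damaging", "1"})
# Mutation Assessor calls H (high) and M (medium) functional.
DAMAGING_LABELS["mutation_assessor"] = frozenset({"H", "M", "damaging", "1"})


class ConsistencyError(ValueError):
    """Raised when cross-file metadata (roster, pedigree, VCF) disagree."""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label by stripping any ``chr`` prefix.

    Region files and variant tables from mixed sources disagree on the
    prefix; all internal comparisons use the stripped form.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tally (AA, AR, RR, missing) over a named sample subset."""

    n_hom_alt: int = 0
    n_het: int = 0
    n_hom_ref: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.n_hom_alt + self.n_het + self.n_hom_ref + self.n_missing

    @property
    def n_carriers(self) -> int:
        """Samples with at least one alternate allele (AA or AR)."""
        return self.n_hom_alt + self.n_het

    @property
    def n_called(self) -> int:
        return self.total - self.n_missing

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_hom_alt + other.n_hom_alt,
            self.n_het + other.n_het,
            self.n_hom_ref + other.n_hom_ref,
            self.n_missing + other.n_missing,
        )


@dataclass
class VariantRecord:
    """One biallelic site with per-sample genotype calls and QC fields.

    ``genotypes`` is ordered to match the sample roster of the source file.
    QC fields may be ``None`` when the source carries no value; the quality
    filter decides (strict vs. permissive) how to treat an absent metric.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: list[str]
    mapping_quality: Optional[float] = None
    depth: Optional[int] = None
    call_rate: Optional[float] = None
    vqsr_pass: Optional[bool] = None
    low_quality_prob: Optional[float] = None
    replicate_discordant_pairs: Optional[int] = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        bad = set(self.genotypes) - set(GENOTYPE_STATES)
        if bad:
            raise ValueError(f"unknown genotype state(s): {sorted(bad)}")
        if self.call_rate is not None and not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call_rate must lie in [0,1], got {self.call_rate}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def is_monomorphic(self) -> bool:
        """True when all non-missing calls are the same state (or none)."""
        called = {g for g in self.genotypes if g != MISSING}
        return len(called) <= 1

    def copy(self, **changes) -> "VariantRecord":
        if "genotypes" not in changes:
            changes["genotypes"] = list(self.genotypes)
        return replace(self, **changes)


def format_key(key: VariantKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    family_id: Optional[str] = None
    population: Optional[str] = None
    affected: bool = False
    is_control: bool = False
    duplicate_partner: Optional[str] = None
    dataset: str = "WES"


class SampleSet:
    """Ordered sample roster with family / population / control structure.

    The order of samples defines the genotype-vector order of every
    :class:`VariantRecord` read alongside it.
    """

    def __init__(self, samples: Sequence[Sample]):
        self.samples = list(samples)
        self._index = {s.sample_id: i for i, s in enumerate(self.samples)}
        if len(self._index) != len(self.samples):
            raise ConsistencyError("duplicate sample ids in roster")
        self._validate()

    def _validate(self) -> None:
        for s in self.samples:
            if s.affected and s.family_id is None:
                raise ConsistencyError(
                    f"affected sample {s.sample_id} has no family_id"
                )
            if s.is_control and s.family_id is not None:
                raise ConsistencyError(
                    f"control sample {s.sample_id} must not belong to a family"
                )
            if s.duplicate_partner is not None:
                partner = self.get(s.duplicate_partner)
                if partner is None:
                    raise ConsistencyError(
                        f"duplicate partner {s.duplicate_partner} of "
                        f"{s.sample_id} is not in the roster"
                    )
                if partner.duplicate_partner != s.sample_id:
                    raise ConsistencyError(
                        f"duplicate pairing {s.sample_id}/{s.duplicate_partner}"
                        " is not symmetric"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def get(self, sample_id: str) -> Optional[Sample]:
        i = self._index.get(sample_id)
        return None if i is None else self.samples[i]

    def index_of(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise ConsistencyError(f"unknown sample id: {sample_id}") from None

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def controls(self) -> list[Sample]:
        return [s for s in self.samples if s.is_control]

    def affected_ids(self, population: Optional[str] = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.affected and (population is None or s.population == population)
        ]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.affected and s.population and s.population not in seen:
                seen.append(s.population)
        return seen

    def family_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.family_id and s.family_id not in seen:
                seen.append(s.family_id)
        return seen

    def family_members(self, family_id: str, affected_only: bool = True) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.family_id == family_id and (s.affected or not affected_only)
        ]

    def duplicate_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for s in self.samples:
            if s.duplicate_partner is not None and s.sample_id < s.duplicate_partner:
                pairs.append((s.sample_id, s.duplicate_partner))
        return pairs

    def subset_order(self, sample_ids: Iterable[str]) -> list[int]:
        return [self.index_of(sid) for sid in sample_ids]

    def reorder_to(self, vcf_sample_order: Sequence[str]) -> "SampleSet":
        """Return a roster reordered to match a VCF's sample column order."""
        missing = [sid for sid in vcf_sample_order if sid not in self._index]
        if missing:
            raise ConsistencyError(
                f"samples in VCF absent from metadata: {missing}"
            )
        return SampleSet([self.samples[self._index[s]] for s in vcf_sample_order])


@dataclass
class AnnotationRecord:
    """Per-variant gene / function / pathogenicity / frequency annotations.

    ``damaging_calls`` holds one boolean per predictor source (nine slots,
    ordered as :data:`PREDICTOR_SOURCES`); an absent predictor value counts
    as not damaging.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str] = None
    location: Optional[str] = None  # exonic | intronic | intergenic | upstream ...
    function: Optional[str] = None  # nonsynonymous | synonymous | None
    damaging_calls: tuple[bool, ...] = (False,) * len(PREDICTOR_SOURCES)
    freq_1000g: Optional[float] = None
    freq_gme: Optional[float] = None
    freq_qg: Optional[float] = None
    dbsnp_common: bool = False

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if len(self.damaging_calls) != len(PREDICTOR_SOURCES):
            raise ValueError(
                f"damaging_calls needs {len(PREDICTOR_SOURCES)} slots, "
                f"got {len(self.damaging_calls)}"
            )
        for name in ("freq_1000g", "freq_gme", "freq_qg"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.function is not None and (self.location or "").lower() != "exonic":
            raise ValueError(
                "function class is defined only for exonic variants "
                f"(location={self.location!r})"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def n_damaging(self) -> int:
        return sum(self.damaging_calls)


AnnotationTable = dict[VariantKey, AnnotationRecord]


class Pedigree:
    """Directed parent-to-child pedigree graph.

    Consanguineous marriage loops are allowed; what is forbidden is an
    individual being its own ancestor (the parent graph must stay acyclic).
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_individual(
        self,
        ind_id: str,
        father: Optional[str] = None,
        mother: Optional[str] = None,
        sex: int = 0,
        affected: bool = False,
        family_id: Optional[str] = None,
    ) -> None:
        self.graph.add_node(
            ind_id, sex=sex, affected=affected, family_id=family_id,
            father=father, mother=mother,
        )
        for parent in (father, mother):
            if parent is not None:
                if parent not in self.graph:
                    self.graph.add_node(
                        parent, sex=0, affected=False, family_id=family_id,
                        father=None, mother=None,
                    )
                self.graph.add_edge(parent, ind_id)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ConsistencyError(f"pedigree contains an ancestry cycle: {cycle}")
        for ind in self.graph:
            parents = self.parents(ind)
            if len(parents) == 1:
                raise ConsistencyError(
                    f"individual {ind} has exactly one parent in the pedigree; "
                    "non-founders need both"
                )

    def parents(self, ind_id: str) -> tuple[str, ...]:
        node = self.graph.nodes[ind_id]
        return tuple(p for p in (node["father"], node["mother"]) if p is not None)

    @property
    def individuals(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.graph if not self.parents(i)]

    def affected_ids(self) -> list[str]:
        return [i for i, d in self.graph.nodes(data=True) if d.get("affected")]

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph))

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) by the standard recursion."""
        return _kinship(self, a, b, {})

    def inbreeding_coefficient(self, ind_id: str) -> float:
        """F of an individual: kinship between its parents (0 for founders)."""
        parents = self.parents(ind_id)
        if len(parents) != 2:
            return 0.0
        return self.kinship(*parents)


def _kinship(ped: Pedigree, a: str, b: str, cache: dict) -> float:
    # Order-normalized memoized kinship recursion over the parent graph.
    if a == b:
        key = (a, a)
        if key not in cache:
            parents = ped.parents(a)
            f = _kinship(ped, *parents, cache) if len(parents) == 2 else 0.0
            cache[key] = 0.5 * (1.0 + f)
        return cache[key]
    key = (a, b) if a < b else (b, a)
    if key in cache:
        return cache[key]
    # Recurse through the parents of the individual appearing later in a
    # topological order, guaranteeing termination on loopy pedigrees.
    order = {ind: i for i, ind in enumerate(ped.topological_order())}
    lower, upper = (a, b) if order[a] >= order[b] else (b, a)
    parents = ped.parents(lower)
    if not parents:
        phi = 0.0
    else:
        phi = 0.5 * sum(_kinship(ped, p, upper, cache) for p in parents)
    cache[key] = phi
    return phi


@dataclass
class FilterConfig:
    """Every tunable threshold of the filtering cascade, in one place.

    Defaults encode the study design this pipeline implements: variant-level
    QC cut-offs, a 5% rarity ceiling, the population 20%-carrier rule, the
    two-homozygote family rule, and the 7-of-8-carrier within-family
    discovery rule for genome sequence data.
    """

    min_mapping_quality: float = 30.0
    min_depth: int = 8
    max_depth: int = 20_000
    min_call_rate: float = 0.98
    max_replicate_discordant_pairs: int = 1
    low_quality_prob_threshold: float = 0.70
    max_maf: float = 0.05
    population_min_carrier_fraction: float = 0.20
    population_min_hom: int = 1
    family_min_hom: int = 2
    wgs_min_hom: int = 1
    wgs_min_carriers: int = 7
    wgs_reference_family_size: int = 8
    # When False, the within-family carrier quota must be met by family
    # members other than one obligate homozygote (the stricter reading).
    wgs_homozygote_counts_as_carrier: bool = True
    # When True, samples with a missing call at the site leave the
    # population-filter denominator ("all cases" then means all called cases).
    population_exclude_missing_from_denominator: bool = False
    strict_qc: bool = True
    # Extended MHC interval on chromosome 6 (1-based, inclusive).
    hla_chrom: str = "6"
    hla_start: int = 28_477_797
    hla_end: int = 33_448_354
    frequent_hitter_genes: frozenset[str] = frozenset()
    enhancer_min_score: float = 5.0
    promoter_max_tss_distance: int = 200_000

    def __post_init__(self) -> None:
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be below max_depth")
        for name in (
            "min_call_rate",
            "low_quality_prob_threshold",
            "max_maf",
            "population_min_carrier_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if isinstance(self.frequent_hitter_genes, (list, set, tuple)):
            self.frequent_hitter_genes = frozenset(self.frequent_hitter_genes)

    def in_hla_region(self, chrom: str, pos: int) -> bool:
        return (
            normalize_chrom(chrom) == normalize_chrom(self.hla_chrom)
            and self.hla_start <= pos <= self.hla_end
        )

    def wgs_carrier_quota(self, n_members: int) -> int:
        """Carrier quota scaled from the reference 7-of-8 rule.

        For ``n_members`` equal to the reference family size the quota is
        ``wgs_min_carriers``; otherwise it is the ceiling of the same
        proportion of ``n_members``.
        """
        if n_members == self.wgs_reference_family_size:
            return self.wgs_min_carriers
        # ceil(min_carriers * n / reference_size) in exact integer arithmetic
        return -(-self.wgs_min_carriers * n_members // self.wgs_reference_family_size)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, frozenset):
                v = sorted(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
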