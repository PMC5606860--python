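"""Synthetic study generator: consanguineous pedigrees, gene-dropping,
planted risk variants, and complete file bundles.

The generator emulates the structure the sharing filters assume: multiplex
families whose affected members are distant relatives (second/third
degree), extensive consanguinity modelled *structurally* through
first-cousin marriage loops (so excess homozygosity emerges from the
pedigree rather than from an inbreeding-coefficient fudge), rare founder
alleles, optional planted recessive shared-homozygous or compound-
heterozygous risk variants, unrelated control samples, duplicate QC
samples, and symmetric genotyping error plus completely-at-random
missingness.

Genotypes are simulated by gene-dropping: founder alleles are drawn
binomially from the population frequency and every non-founder inherits
one uniformly chosen allele from each parent.  All randomness flows from a
single seed; a fixed seed yields byte-identical output bundles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from . import io as csio
from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PREDICTOR_SOURCES,
    AnnotationRecord,
    AnnotationTable,
    ConsistencyError,
    Pedigree,
    Sample,
    SampleSet,
    VariantRecord,
)

_DOSAGE_TO_STATE = {0: HOM_REF, 1: HET, 2: HOM_ALT}


# ---------------------------------------------------------------------------
# Pedigree builders
# ---------------------------------------------------------------------------

def first_cousin_pedigree(family_id: str = "FC") -> tuple[Pedigree, str]:
    """Pedigree whose last individual is the child of a first-cousin mating.

    Returns the pedigree and the id of the inbred offspring (F = 1/16).
    """
    ped = Pedigree()
    p = f"{family_id}:"
    ped.add_individual(p + "gf", sex=1, family_id=family_id)
    ped.add_individual(p + "gm", sex=2, family_id=family_id)
    ped.add_individual(p + "p1", father=p + "gf", mother=p + "gm", sex=1, family_id=family_id)
    ped.add_individual(p + "p2", father=p + "gf", mother=p + "gm", sex=2, family_id=family_id)
    ped.add_individual(p + "s1", sex=2, family_id=family_id)
    ped.add_individual(p + "s2", sex=1, family_id=family_id)
    ped.add_individual(p + "c1", father=p + "p1", mother=p + "s1", sex=1, family_id=family_id)
    ped.add_individual(p + "c2", father=p + "s2", mother=p + "p2", sex=2, family_id=family_id)
    child = p + "x"
    ped.add_individual(child, father=p + "c1", mother=p + "c2", affected=True, family_id=family_id)
    ped.validate()
    return ped, child


def cousin_multiplex_family(
    family_id: str,
    n_affected: int,
    n_unaffected: int = 0,
) -> tuple[Pedigree, list[str], list[str]]:
    """Outbred multiplex family whose affected members are first cousins.

    One founder grandparental couple has ``n_affected`` children, each
    married to an unrelated founder; every couple contributes one affected
    child (so the affected are third-degree relatives of one another).
    Unaffected sequenced members are added as siblings of the first
    affected individuals.
    """
    ped = Pedigree()
    p = f"{family_id}:"
    ped.add_individual(p + "gf", sex=1, family_id=family_id)
    ped.add_individual(p + "gm", sex=2, family_id=family_id)
    affected, unaffected = [], []
    for i in range(n_affected):
        parent, spouse = f"{p}p{i}", f"{p}s{i}"
        ped.add_individual(parent, father=p + "gf", mother=p + "gm", sex=1, family_id=family_id)
        ped.add_individual(spouse, sex=2, family_id=family_id)
        child = f"{p}a{i}"
        ped.add_individual(child, father=parent, mother=spouse, affected=True, family_id=family_id)
        affected.append(child)
    for j in range(n_unaffected):
        sib = f"{p}u{j}"
        couple = j % max(n_affected, 1)
        ped.add_individual(
            sib, father=f"{p}p{couple}", mother=f"{p}s{couple}", family_id=family_id
        )
        unaffected.append(sib)
    ped.validate()
    return ped, affected, unaffected


def consanguineous_multiplex_family(
    family_id: str,
    n_couples: int = 4,
    children_per_couple: int = 2,
) -> tuple[Pedigree, list[str]]:
    """Looped multiplex family: affected children of first-cousin matings.

    Two sibships descend from one founder couple; sibs of one marry first
    cousins from the other, and each cousin couple has affected children
    (each with inbreeding coefficient 1/16).  With the default shape this
    yields eight affected individuals connected through multiple loops.
    """
    ped = Pedigree()
    p = f"{family_id}:"
    ped.add_individual(p + "gf", sex=1, family_id=family_id)
    ped.add_individual(p + "gm", sex=2, family_id=family_id)
    # Two married-in founders anchor the two sibships.
    ped.add_individual(p + "m1", sex=2, family_id=family_id)
    ped.add_individual(p + "m2", sex=1, family_id=family_id)
    ped.add_individual(p + "f1", father=p + "gf", mother=p + "gm", sex=1, family_id=family_id)
    ped.add_individual(p + "f2", father=p + "gf", mother=p + "gm", sex=2, family_id=family_id)
    affected = []
    for i in range(n_couples):
        a, b = f"{p}A{i}", f"{p}B{i}"
        ped.add_individual(a, father=p + "f1", mother=p + "m1", sex=1, family_id=family_id)
        ped.add_individual(b, father=p + "m2", mother=p + "f2", sex=2, family_id=family_id)
        for c in range(children_per_couple):
            child = f"{p}x{i}{c}"
            ped.add_individual(child, father=a, mother=b, affected=True, family_id=family_id)
            affected.append(child)
    ped.validate()
    return ped, affected


# ---------------------------------------------------------------------------
# Gene-dropping
# ---------------------------------------------------------------------------

def simulate_pedigree_genotypes(
    pedigree: Pedigree,
    founder_freqs: np.ndarray,
    seed_or_rng,
) -> dict[str, np.ndarray]:
    """Gene-drop alleles down a pedigree.

    Founder alleles at each site are Bernoulli draws with the site's
    population frequency; each non-founder inherits one uniformly chosen
    allele from each parent.  Returns per-individual allele arrays of shape
    ``(n_variants, 2)`` (0 = reference, 1 = alternate), deterministic under
    a fixed seed.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    freqs = np.asarray(founder_freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("founder allele frequencies must lie in [0,1]")
    n = freqs.shape[0]
    pedigree.validate()  # raises on ancestry cycles

    alleles: dict[str, np.ndarray] = {}
    for ind in pedigree.topological_order():
        parents = pedigree.parents(ind)
        if not parents:
            alleles[ind] = (rng.random((n, 2)) < freqs[:, None]).astype(np.uint8)
        else:
            father, mother = parents
            pick_f = rng.integers(0, 2, n)
            pick_m = rng.integers(0, 2, n)
            idx = np.arange(n)
            alleles[ind] = np.stack(
                [alleles[father][idx, pick_f], alleles[mother][idx, pick_m]], axis=1
            )
    return alleles


def dosage_matrix(alleles: dict[str, np.ndarray], order: Sequence[str]) -> np.ndarray:
    """Alternate-allele dosage (0/1/2), shape (n_individuals, n_variants)."""
    return np.stack([alleles[i].sum(axis=1) for i in order])


def check_mendelian(pedigree: Pedigree, alleles: dict[str, np.ndarray]) -> list[tuple]:
    """Exhaustive transmission check; returns (individual, site) violations.

    A child's dosage is consistent iff it can be composed from one allele
    of each parent: dosage 2 needs both parents to carry the alternate,
    dosage 0 needs both to carry the reference, dosage 1 needs one of each
    available across the two parents.
    """
    violations = []
    for ind in pedigree.individuals:
        parents = pedigree.parents(ind)
        if len(parents) != 2:
            continue
        d = alleles[ind].sum(axis=1)
        d1 = alleles[parents[0]].sum(axis=1)
        d2 = alleles[parents[1]].sum(axis=1)
        bad = np.zeros(d.shape, dtype=bool)
        bad |= (d == 2) & ((d1 == 0) | (d2 == 0))
        bad |= (d == 0) & ((d1 == 2) | (d2 == 2))
        bad |= (d == 1) & (((d1 == 0) & (d2 == 0)) | ((d1 == 2) & (d2 == 2)))
        for site in np.nonzero(bad)[0]:
            violations.append((ind, int(site)))
    return violations


# ---------------------------------------------------------------------------
# Planting risk variants
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    """One planted risk variant (or variant pair) in a named gene.

    ``recessive_shared`` sets the designated homozygous individuals to AA
    at one site, remaining designated carriers to AR and ``non_carriers``
    to RR (the within-family-heterogeneity slot).  ``compound_het_pair``
    sets every designated carrier to AR at each of two or more sites of
    the same gene.
    """

    gene: str
    mode: str  # "recessive_shared" | "compound_het_pair"
    site_indices: list[int]
    hom_individuals: list[str] = dc_field(default_factory=list)
    het_individuals: list[str] = dc_field(default_factory=list)
    non_carriers: list[str] = dc_field(default_factory=list)
    force: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("recessive_shared", "compound_het_pair"):
            raise ValueError(f"unknown planting mode {self.mode!r}")
        if self.mode == "recessive_shared" and len(self.site_indices) != 1:
            raise ValueError("recessive_shared plants exactly one site")
        if self.mode == "compound_het_pair" and len(self.site_indices) < 2:
            raise ValueError("compound_het_pair plants at least two sites")


def plant_causal_variants(
    alleles: dict[str, np.ndarray],
    spec: PlantSpec,
    pedigree: Pedigree,
) -> dict[str, np.ndarray]:
    """Overwrite genotypes at the planted sites and repair ancestry.

    The planted sites are reset to reference in every individual, target
    genotypes are written, and alternate alleles are propagated up through
    ancestors so that every transmission stays Mendelian-consistent.  A
    propagation that would force an alternate allele into a designated
    non-carrier raises unless ``force`` is set.
    """
    out = {ind: arr.copy() for ind, arr in alleles.items()}
    forced_ref = set(spec.non_carriers)
    for site in spec.site_indices:
        for ind in out:
            out[ind][site] = 0
        if spec.mode == "recessive_shared":
            targets = [(i, 2) for i in spec.hom_individuals]
            targets += [(i, 1) for i in spec.het_individuals]
        else:
            targets = [(i, 1) for i in spec.hom_individuals + spec.het_individuals]
        for ind, dosage in targets:
            if ind in forced_ref:
                raise ConsistencyError(
                    f"{ind} is both a designated carrier and non-carrier"
                )
            out[ind][site, 0] = 1 if dosage >= 1 else 0
            out[ind][site, 1] = 1 if dosage == 2 else 0
        _propagate_up(out, pedigree, site, forced_ref, spec.force)
    return out


def _propagate_up(
    alleles: dict[str, np.ndarray],
    pedigree: Pedigree,
    site: int,
    forced_ref: set[str],
    force: bool,
) -> None:
    # Children before parents: reverse topological order guarantees every
    # repair made for a child is seen before that parent's own parents.
    for ind in reversed(pedigree.topological_order()):
        parents = pedigree.parents(ind)
        if len(parents) != 2:
            continue
        d = int(alleles[ind][site].sum())
        if d == 0:
            continue
        need = parents if d == 2 else []
        if d == 1 and all(alleles[p][site].sum() == 0 for p in parents):
            need = [parents[0]]
        for parent in need:
            if alleles[parent][site].sum() == 0:
                if parent in forced_ref and not force:
                    raise ConsistencyError(
                        f"planting at site {site} requires non-carrier "
                        f"{parent} to carry the alternate allele"
                    )
                alleles[parent][site, 0] = 1


# ---------------------------------------------------------------------------
# Observation model and fixture assembly
# ---------------------------------------------------------------------------

def observe_genotypes(
    dosages: np.ndarray,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Apply symmetric allele-flip error and MCAR missingness.

    Input and output are dosage matrices (-1 encodes a missing call).
    """
    obs = dosages.astype(np.int8).copy()
    if error_rate > 0:
        flips = rng.random(obs.shape + (2,)) < error_rate
        # Flip each of the two alleles independently.
        a1 = (obs >= 1).astype(np.int8) ^ flips[..., 0]
        a2 = (obs == 2).astype(np.int8) ^ flips[..., 1]
        obs = (a1 + a2).astype(np.int8)
    if missing_rate > 0:
        obs[rng.random(obs.shape) < missing_rate] = -1
    return obs


@dataclass
class FamilySpec:
    family_id: str
    population: str
    n_affected: int
    n_unaffected: int = 0
    consanguineous: bool = False
    dataset: str = "WES"
    n_overlap: int = 0  # sequenced affected members tagged as in both datasets


@dataclass
class SimulationConfig:
    """Shape of a simulated study; defaults give a small, fast bundle."""

    families: list[FamilySpec] = dc_field(default_factory=lambda: [
        FamilySpec("FAM1", "Syrian", 3, consanguineous=True),
        FamilySpec("FAM2", "Syrian", 2),
        FamilySpec("FAM3", "German", 2),
    ])
    n_variants: int = 120
    novel_fraction: float = 0.10
    common_fraction: float = 0.15
    rare_freq_range: tuple[float, float] = (0.001, 0.05)
    common_freq_range: tuple[float, float] = (0.051, 0.5)
    novel_freq: float = 0.002  # founder frequency of database-absent alleles
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.005
    n_controls: int = 2
    n_duplicates: int = 2
    planted: list[PlantSpec] = dc_field(default_factory=list)
    variants_per_gene: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("novel_fraction", "common_fraction",
                     "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")


@dataclass
class StudyFixture:
    """In-memory simulated study plus writers for the standard formats."""

    variants: list[VariantRecord]
    roster: SampleSet
    annotations: AnnotationTable
    pedigrees: dict[str, Pedigree]
    regions: list[tuple[str, int, int, str]]
    config: SimulationConfig

    def write(self, out_dir) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "vcf": os.path.join(out_dir, "study.vcf"),
            "metadata": os.path.join(out_dir, "samples.tsv"),
            "annotation": os.path.join(out_dir, "annotation.tsv"),
            "ped": os.path.join(out_dir, "study.ped"),
            "regions": os.path.join(out_dir, "regions.bed"),
        }
        csio.write_multisample_vcf(paths["vcf"], self.variants, self.roster.sample_ids)
        csio.write_sample_metadata(paths["metadata"], self.roster)
        csio.write_annotation_table(paths["annotation"], self.annotations)
        merged = Pedigree()
        for ped in self.pedigrees.values():
            merged.graph.update(ped.graph)
        csio.write_pedigree(paths["ped"], merged)
        csio.write_regions_bed(paths["regions"], self.regions)
        return paths


def _site_positions(n_variants: int) -> list[tuple[str, int]]:
    # Cycle autosomes; positions stay clear of the default HLA interval.
    sites = []
    for i in range(n_variants):
        chrom = str(1 + (i % 22))
        pos = 100_000 + (i // 22) * 50_000 + (i % 22) * 137
        sites.append((chrom, pos))
    return sites


def generate_study_fixture(config: SimulationConfig) -> StudyFixture:
    """Build a self-consistent simulated study bundle from a config.

    Founder allele frequencies are drawn from a three-part spectrum (novel
    point mass, rare range, common range), genotypes are gene-dropped down
    each family's pedigree, planted risk variants are written in and
    propagated, and controls / duplicates / annotations / regulatory
    regions are attached.  A fixed seed yields byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants

    # Founder frequency spectrum.
    classes = rng.choice(
        3, size=n,
        p=[config.novel_fraction, config.common_fraction,
           1.0 - config.novel_fraction - config.common_fraction],
    )
    freqs = np.empty(n)
    freqs[classes == 0] = config.novel_freq
    freqs[classes == 1] = rng.uniform(*config.common_freq_range, (classes == 1).sum())
    freqs[classes == 2] = rng.uniform(*config.rare_freq_range, (classes == 2).sum())
    # Planted alleles are private to the designated family: they are novel
    # (absent from databases) and never drawn by controls or other founders.
    planted_sites = sorted({s for p in config.planted for s in p.site_indices})
    freqs[planted_sites] = 0.0
    classes[planted_sites] = 0

    # Pedigrees and gene-dropping per family.
    pedigrees: dict[str, Pedigree] = {}
    sequenced: list[Sample] = []
    alleles: dict[str, np.ndarray] = {}
    for fam in config.families:
        if fam.consanguineous:
            n_couples = max(1, -(-fam.n_affected // 2))
            ped, affected = consanguineous_multiplex_family(fam.family_id, n_couples)
            affected = affected[: fam.n_affected]
            unaffected: list[str] = []
        else:
            ped, affected, unaffected = cousin_multiplex_family(
                fam.family_id, fam.n_affected, fam.n_unaffected
            )
        pedigrees[fam.family_id] = ped
        alleles.update(simulate_pedigree_genotypes(ped, freqs, rng))
        for i, ind in enumerate(affected):
            dataset = "both" if i < fam.n_overlap else fam.dataset
            sequenced.append(Sample(ind, fam.family_id, fam.population, True,
                                    dataset=dataset))
        for ind in unaffected[: fam.n_unaffected]:
            sequenced.append(Sample(ind, fam.family_id, fam.population, False,
                                    dataset=fam.dataset))

    # Planted risk variants, then a full Mendelian audit.
    for spec in config.planted:
        fam_ped = next(
            ped for ped in pedigrees.values()
            if all(i in ped.graph for i in
                   spec.hom_individuals + spec.het_individuals + spec.non_carriers)
        )
        planted = plant_causal_variants(alleles, spec, fam_ped)
        alleles.update(planted)
    violations = []
    for ped in pedigrees.values():
        violations += check_mendelian(ped, {i: alleles[i] for i in ped.individuals})
    if violations:
        raise ConsistencyError(f"simulated genotypes violate transmission: {violations[:5]}")

    # Controls and duplicate QC samples.
    samples = list(sequenced)
    control_dosages = {}
    for c in range(config.n_controls):
        sid = f"CTRL{c + 1}"
        control_dosages[sid] = rng.binomial(2, freqs)
        samples.append(Sample(sid, None, "control", False, is_control=True,
                              dataset="WES"))
    dup_sources = [s.sample_id for s in sequenced[: config.n_duplicates]]
    dup_samples = []
    for src in dup_sources:
        sid = f"DUP_{src.replace(':', '_')}"
        dup_samples.append((sid, src))
    samples = [
        (Sample(s.sample_id, s.family_id, s.population, s.affected,
                s.is_control, f"DUP_{s.sample_id.replace(':', '_')}"
                if s.sample_id in dup_sources else None, s.dataset))
        for s in samples
    ]
    for sid, src in dup_samples:
        samples.append(Sample(sid, None, None, False, False, src, "WES"))
    roster = SampleSet(samples)

    # Observed genotype matrix (error + missingness), duplicates copied
    # verbatim from their source sample so replicate concordance holds.
    order = [s.sample_id for s in sequenced]
    true_dosages = dosage_matrix(alleles, order)
    obs = observe_genotypes(true_dosages, rng,
                            config.genotyping_error_rate, config.missing_rate)
    dosage_by_sample = {sid: obs[i] for i, sid in enumerate(order)}
    dosage_by_sample.update(control_dosages)
    for sid, src in dup_samples:
        dosage_by_sample[sid] = dosage_by_sample[src]

    sites = _site_positions(n)
    bases = ("A", "C", "G", "T")
    refs = rng.integers(0, 4, n)
    alts = (refs + rng.integers(1, 4, n)) % 4

    variants: list[VariantRecord] = []
    roster_ids = roster.sample_ids
    for i in range(n):
        chrom, pos = sites[i]
        dosages = [int(dosage_by_sample[sid][i]) for sid in roster_ids]
        genotypes = [_DOSAGE_TO_STATE.get(d, MISSING) for d in dosages]
        n_called = sum(g != MISSING for g in genotypes)
        v = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref_allele=bases[refs[i]],
            alt_allele=bases[alts[i]],
            genotypes=genotypes,
            mapping_quality=float(np.round(40 + 20 * rng.random(), 2)),
            depth=int(rng.integers(800, 12_000)),
            call_rate=n_called / len(genotypes),
            vqsr_pass=True,
            low_quality_prob=float(np.round(rng.random() * 0.5, 4)),
        )
        v.replicate_discordant_pairs = csio.count_discordant_pairs(v, roster)
        variants.append(v)

    annotations = _generate_annotations(config, rng, variants, freqs, classes)
    regions = _regulatory_regions(variants, rng)
    return StudyFixture(variants, roster, annotations, pedigrees, regions, config)


def _generate_annotations(
    config: SimulationConfig,
    rng: np.random.Generator,
    variants: Sequence[VariantRecord],
    freqs: np.ndarray,
    classes: np.ndarray,
) -> AnnotationTable:
    n = len(variants)
    planted_gene = {}
    planted_sites = set()
    for spec in config.planted:
        for s in spec.site_indices:
            planted_gene[s] = spec.gene
            planted_sites.add(s)
    locations = rng.choice(
        ["exonic", "intronic", "intergenic", "upstream"], size=n,
        p=[0.5, 0.35, 0.1, 0.05],
    )
    func_draw = rng.random(n)
    damaging = rng.random((n, len(PREDICTOR_SOURCES))) < 0.2
    table: AnnotationTable = {}
    for i, v in enumerate(variants):
        if i in planted_sites:
            gene = planted_gene[i]
            location, function = "exonic", "nonsynonymous"
        else:
            gene = f"GENE{i // config.variants_per_gene:04d}"
            location = str(locations[i])
            function = (
                ("nonsynonymous" if func_draw[i] < 0.6 else "synonymous")
                if location == "exonic"
                else None
            )
        novel = classes[i] == 0
        table[v.key] = AnnotationRecord(
            chrom=v.chrom,
            pos=v.pos,
            ref_allele=v.ref_allele,
            alt_allele=v.alt_allele,
            gene=gene,
            location=location,
            function=function,
            damaging_calls=tuple(bool(b) for b in damaging[i]),
            freq_1000g=None if novel else float(np.round(freqs[i], 6)),
            dbsnp_common=bool(classes[i] == 1 and rng.random() < 0.8),
        )
    return table


def _regulatory_regions(
    variants: Sequence[VariantRecord],
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    # A few enhancer/promoter windows over the simulated sites on chrom 1.
    chrom1 = sorted(v.pos for v in variants if v.chrom == "1")
    regions = []
    for j, pos in enumerate(chrom1[:4]):
        kind = "enhancer" if j < 3 else "promoter"
        regions.append(("1", pos - 50, pos + 50, f"{kind}{j + 1}"))
    return regions


# ---------------------------------------------------------------------------
# Study-shaped presets
# ---------------------------------------------------------------------------

def wes_preset_families() -> list[FamilySpec]:
    """52 exome-sequenced families: 4 with three affected, 48 with two.

    Population totals: 22 Syrian affected in 10 families, 22 Filipino in
    11, 26 Indian in 12, 38 German in 19 — 108 affected in all.
    """
    fams = []
    counter = {}

    def add(pop: str, n_affected: int):
        counter[pop] = counter.get(pop, 0) + 1
        fams.append(FamilySpec(f"{pop[:3].upper()}{counter[pop]}", pop, n_affected))

    for _ in range(2):
        add("Syrian", 3)
    for _ in range(8):
        add("Syrian", 2)
    for _ in range(11):
        add("Filipino", 2)
    for _ in range(2):
        add("Indian", 3)
    for _ in range(10):
        add("Indian", 2)
    for _ in range(19):
        add("German", 2)
    return fams


def wgs_preset_families() -> list[FamilySpec]:
    """32 genome-sequenced families: 113 individuals, 107 affected.

    Syrian: 11 families of two, one of three, one of four and one highly
    consanguineous family with eight affected (37 affected, 14 families).
    Filipino: two families of two, three of three (two with one unaffected
    member each), eight of four (two with two unaffected each) and five of
    five (70 affected + 6 unaffected, 18 families).  Three affected members
    of each of two Syrian families are tagged as present in both datasets.
    """
    fams = []
    fams.append(FamilySpec("SYR_F1", "Syrian", 8, consanguineous=True,
                           dataset="WGS", n_overlap=3))
    fams.append(FamilySpec("SYR_F2", "Syrian", 4, dataset="WGS", n_overlap=3))
    fams.append(FamilySpec("SYR_F3", "Syrian", 3, dataset="WGS"))
    for i in range(11):
        fams.append(FamilySpec(f"SYR_G{i + 1}", "Syrian", 2, dataset="WGS"))
    for i in range(2):
        fams.append(FamilySpec(f"FIL_A{i + 1}", "Filipino", 2, dataset="WGS"))
    fams.append(FamilySpec("FIL_B1", "Filipino", 3, dataset="WGS"))
    for i in range(2):
        fams.append(FamilySpec(f"FIL_B{i + 2}", "Filipino", 3, 1, dataset="WGS"))
    for i in range(6):
        fams.append(FamilySpec(f"FIL_C{i + 1}", "Filipino", 4, dataset="WGS"))
    for i in range(2):
        fams.append(FamilySpec(f"FIL_C{i + 7}", "Filipino", 4, 2, dataset="WGS"))
    for i in range(5):
        fams.append(FamilySpec(f"FIL_D{i + 1}", "Filipino", 5, dataset="WGS"))
    return fams


def preset_config(name: str, seed: int = 0) -> SimulationConfig:
    """Named study-shaped configurations: ``wes``, ``wgs`` or ``family1``."""
    if name == "wes":
        return SimulationConfig(
            families=wes_preset_families(), n_variants=150,
            n_controls=2, n_duplicates=4, seed=seed,
        )
    if name == "wgs":
        return SimulationConfig(
            families=wgs_preset_families(), n_variants=150,
            n_controls=0, n_duplicates=0, seed=seed,
        )
    if name == "family1":
        fam = FamilySpec("SYR_F1", "Syrian", 8, consanguineous=True, dataset="WGS")
        ped, affected = consanguineous_multiplex_family("SYR_F1")
        planted = [
            PlantSpec(
                gene="GENE_RS01", mode="recessive_shared", site_indices=[10],
                hom_individuals=affected[:4], het_individuals=affected[4:7],
                non_carriers=affected[7:],
            ),
            PlantSpec(
                gene="GENE_CH01", mode="compound_het_pair", site_indices=[20, 21],
                het_individuals=affected[:3],
            ),
        ]
        return SimulationConfig(
            families=[fam], n_variants=100, n_controls=2, n_duplicates=0,
            planted=planted, seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")
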