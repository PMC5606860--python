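import numpy as np
import pytest

from cleftshare import examples as ex
from cleftshare.model import (
    GENOTYPE_STATES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotationRecord,
    FilterConfig,
    Sample,
    SampleSet,
    VariantRecord,
)


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def family_scan_bundle():
    return ex.family_scan_bundle()


@pytest.fixture
def family1_bundle():
    return ex.family1_wgs_bundle()


@pytest.fixture
def comphet_bundle():
    return ex.comphet_discovery_bundle()


def make_variant(genotypes, chrom="1", pos=1000, ref="A", alt="G", **qc):
    """Variant with passing QC metrics unless overridden."""
    defaults = dict(
        mapping_quality=60.0,
        depth=5000,
        call_rate=1.0,
        vqsr_pass=True,
        low_quality_prob=0.0,
        replicate_discordant_pairs=0,
    )
    defaults.update(qc)
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        genotypes=list(genotypes), **defaults,
    )


def make_roster(n_affected=3, n_controls=0, family_id="F1", population="Syrian"):
    samples = [
        Sample(f"A{i}", family_id, population, True) for i in range(n_affected)
    ]
    samples += [
        Sample(f"C{i}", None, "control", False, is_control=True)
        for i in range(n_controls)
    ]
    return SampleSet(samples)


def random_variants(rng, n_variants, n_samples, chrom="1"):
    """Random variant fixtures with random (sometimes failing) QC fields."""
    states = list(GENOTYPE_STATES)
    variants = []
    for i in range(n_variants):
        genotypes = [states[j] for j in rng.integers(0, 4, n_samples)]
        v = make_variant(
            genotypes,
            chrom=chrom,
            pos=1000 + i,
            mapping_quality=float(rng.uniform(20, 60)),
            depth=int(rng.integers(1, 30000)),
            call_rate=float(rng.uniform(0.9, 1.0)),
            vqsr_pass=bool(rng.random() < 0.8),
            low_quality_prob=float(rng.uniform(0, 1)),
            replicate_discordant_pairs=int(rng.integers(0, 3)),
        )
        variants.append(v)
    return variants


def random_annotations(rng, variants, genes=("G1", "G2", "HITTER")):
    table = {}
    for v in variants:
        loc = ["exonic", "intronic", "intergenic"][rng.integers(0, 3)]
        table[v.key] = AnnotationRecord(
            chrom=v.chrom, pos=v.pos, ref_allele=v.ref_allele,
            alt_allele=v.alt_allele,
            gene=genes[rng.integers(0, len(genes))],
            location=loc,
            function=(
                ["nonsynonymous", "synonymous"][rng.integers(0, 2)]
                if loc == "exonic" else None
            ),
            damaging_calls=tuple(bool(b) for b in rng.random(9) < 0.3),
            freq_1000g=(None if rng.random() < 0.3 else float(rng.uniform(0, 0.1))),
            dbsnp_common=bool(rng.random() < 0.1),
        )
    return table
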