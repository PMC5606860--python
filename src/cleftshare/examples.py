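"""Bundled worked-example data from a multiplex oral-cleft sequencing study.

These small genotype tables are the published candidate-variant results of
a family-based rare-variant analysis of consanguineous oral-cleft
families: the exome-wide family-scan hits across four population cohorts,
and the genome-sequenced genotypes of the eight affected members of the
largest (highly consanguineous) Syrian family for the candidate variants
in *CASP9*, *FAT4*, *COL7A1*, *CELSR3*, *TKT* and *NLRP14*.  They serve as
desk-scale worked examples and regression fixtures: every headline count
of the original analysis can be recomputed from them.

Only the per-variant damaging-source *count* was published, not which of
the nine predictors fired, so ``damaging_calls`` tuples here are synthetic
(the first *k* slots set) and only their sum is meaningful.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    PREDICTOR_SOURCES,
    AnnotationRecord,
    AnnotationTable,
    Sample,
    SampleSet,
    VariantRecord,
)

_N_SOURCES = len(PREDICTOR_SOURCES)


def _calls(n_damaging: Optional[int]) -> tuple[bool, ...]:
    k = n_damaging or 0
    return tuple(i < k for i in range(_N_SOURCES))


def _annotation(chrom, pos, ref, alt, gene, location, function, freq, dam,
                freq_gme=None, freq_qg=None) -> AnnotationRecord:
    return AnnotationRecord(
        chrom=str(chrom), pos=pos, ref_allele=ref, alt_allele=alt, gene=gene,
        location=location, function=function, damaging_calls=_calls(dam),
        freq_1000g=freq, freq_gme=freq_gme, freq_qg=freq_qg,
    )


# ---------------------------------------------------------------------------
# Exome family-scan hits, all cohorts
# ---------------------------------------------------------------------------
# Columns: population, family, gene, chrom, pos, alt, ref, AA, AR, RR,
# location, function, 1000G frequency (None = absent from the database),
# damaging-source count (None = no prediction available).
FAMILY_SCAN_HITS = [
    ("Syrian", "1", "CASP9", "1", 15831171, "C", "T", 3, 0, 0, "exonic", "nonsynonymous", None, 2),
    ("Syrian", "3", "HCN2", "19", 603971, "G", "A", 2, 1, 0, "intronic", None, 0.006, None),
    ("Syrian", "6", "CHRNG", "2", 233408449, "T", "A", 2, 0, 0, "intronic", None, 0.0012, None),
    ("Syrian", "7", "SLC24A4", "14", 92792313, "G", "A", 2, 0, 0, "exonic", "nonsynonymous", 0.0004, 2),
    ("Syrian", "7", "LGMN", "14", 93179134, "T", "C", 2, 0, 0, "intronic", None, 0.0002, None),
    ("Syrian", "7", "SERPINA6", "14", 94776036, "A", "G", 2, 0, 0, "intronic", None, 0.0002, None),
    ("Syrian", "7", "HHIPL1", "14", 100126748, "A", "G", 2, 0, 0, "intronic", None, 0.0006, None),
    ("Syrian", "9", "PTGDR", "14", 52734696, "A", "G", 2, 0, 0, "exonic", "nonsynonymous", 0.0006, 0),
    ("Syrian", "10", "FCHO1", "19", 17889669, "A", "G", 2, 0, 0, "exonic", "nonsynonymous", None, 3),
    ("Syrian", "10", "SUMO3", "21", 46228597, "T", "C", 2, 0, 0, "intronic", None, None, None),
    ("Syrian", "10", "FTCD", "21", 47572892, "G", "A", 2, 0, 0, "exonic", "nonsynonymous", None, 1),
    ("German", "7", "MYO16", "13", 109792825, "T", "C", 2, 0, 0, "exonic", "nonsynonymous", 0.0058, 0),
    ("German", "7", "PRCD", "17", 74534592, "C", "A", 2, 0, 0, "upstream", None, 0.0002, None),
    ("German", "10", "PALM", "19", 740436, "A", "G", 2, 0, 0, "exonic", "nonsynonymous", 0.0018, 0),
    ("German", "12", "CHAC1", "15", 41245692, "G", "A", 2, 0, 0, "exonic", "nonsynonymous", 0.0008, 1),
    ("German", "20", "HMHA1", "19", 1081558, "A", "G", 2, 0, 0, "exonic", "nonsynonymous", None, 7),
    ("Indian", "60", "DGKQ", "4", 967071, "A", "G", 2, 0, 0, "exonic", "nonsynonymous", 0.027, 5),
    ("Filipino", "8", "TNK2", "3", 195595358, "T", "A", 2, 0, 0, "exonic", "nonsynonymous", 0.0004, 4),
    ("Filipino", "10", "HLA-DPA2", "6", 33059894, "G", "A", 2, 0, 0, "intergenic", None, 0.013, None),
]


def family_scan_bundle() -> tuple[list[VariantRecord], SampleSet, AnnotationTable]:
    """Reconstruct a full analysis input from the family-scan hit table.

    Each published hit becomes one variant: the reporting family carries
    the published AA/AR/RR pattern, every other sample (including two
    control samples) is homozygous reference, and QC metrics are set to
    passing values.  Running the family analysis on this bundle reproduces
    the published table exactly.
    """
    family_sizes: dict[tuple[str, str], int] = {}
    for pop, fam, *_rest in FAMILY_SCAN_HITS:
        aa, ar, rr = _rest[5], _rest[6], _rest[7]
        key = (pop, fam)
        family_sizes[key] = max(family_sizes.get(key, 0), aa + ar + rr)

    samples: list[Sample] = []
    member_ids: dict[tuple[str, str], list[str]] = {}
    for (pop, fam), size in family_sizes.items():
        fam_id = f"{pop}-{fam}"
        ids = [f"{fam_id}_{i + 1}" for i in range(size)]
        member_ids[(pop, fam)] = ids
        samples += [Sample(sid, fam_id, pop, True) for sid in ids]
    samples += [
        Sample("CTRL1", None, "control", False, is_control=True),
        Sample("CTRL2", None, "control", False, is_control=True),
    ]
    roster = SampleSet(samples)

    variants: list[VariantRecord] = []
    annotations: AnnotationTable = {}
    for pop, fam, gene, chrom, pos, alt, ref, aa, ar, rr, loc, func, freq, dam in FAMILY_SCAN_HITS:
        genotypes = [HOM_REF] * len(roster)
        pattern = [HOM_ALT] * aa + [HET] * ar + [HOM_REF] * rr
        for sid, state in zip(member_ids[(pop, fam)], pattern):
            genotypes[roster.index_of(sid)] = state
        v = VariantRecord(
            chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            genotypes=genotypes, mapping_quality=60.0, depth=5_000,
            call_rate=1.0, vqsr_pass=True, low_quality_prob=0.0,
            replicate_discordant_pairs=0,
        )
        variants.append(v)
        annotations[v.key] = _annotation(chrom, pos, ref, alt, gene, loc, func, freq, dam)
    return variants, roster, annotations


# ---------------------------------------------------------------------------
# Genome-sequenced genotypes of the largest consanguineous Syrian family
# ---------------------------------------------------------------------------

#: The three exome-sequenced index individuals ...
FAMILY1_INDEX_IDS = ["111", "118", "125"]
#: ... and the five additional genome-sequenced affected relatives.
FAMILY1_EXTRA_IDS = ["38", "114", "129", "150", "157"]
FAMILY1_IDS = FAMILY1_INDEX_IDS + FAMILY1_EXTRA_IDS

# (gene, chrom, pos, alt, ref, genotype column over FAMILY1_IDS,
#  1000G freq, GME freq, QG freq, damaging-source count)
FAMILY1_WGS_VARIANTS = [
    ("CASP9", "1", 15831171, "C", "T",
     [HOM_ALT, HOM_ALT, HOM_ALT, HOM_ALT, HET, HOM_REF, HET, HET],
     None, None, None, 2),
    ("FAT4", "4", 126367606, "T", "G",
     [HET, HOM_REF, HET, HET, HET, HOM_ALT, HOM_ALT, HET],
     0.003, 0.006, 0.002, 3),
    ("FAT4", "4", 126336105, "G", "A",
     [HET, HOM_REF, HET, HET, HET, HOM_ALT, HOM_ALT, HET],
     0.002, 0.007, 0.002, 0),
    ("FAT4", "4", 126400922, "T", "C",
     [HET, HOM_REF, HET, HET, HET, HOM_ALT, HOM_ALT, HET],
     0.004, 0.006, None, 0),
    ("COL7A1", "3", 48602623, "A", "G",
     [HET, HET, HET, HET, HOM_REF, HET, HOM_REF, HOM_REF],
     0.001, 0.005, 0.003, 5),
    ("COL7A1", "3", 48620046, "A", "G",
     [HET, HET, HET, HET, HOM_REF, HET, HOM_REF, HOM_REF],
     0.001, 0.005, 0.002, 7),
    ("TKT", "3", 53267183, "T", "C",
     [HET, HET, HET, HET, HOM_REF, HET, HOM_REF, HOM_REF],
     0.002, 0.011, 0.010, 3),
    ("TKT", "3", 53269028, "T", "G",
     [HET, HET, HET, HET, HOM_REF, HET, HOM_REF, HOM_REF],
     0.002, 0.011, 0.010, 1),
]


def family1_wgs_bundle() -> tuple[list[VariantRecord], SampleSet, AnnotationTable]:
    """Genome-sequencing genotypes of the eight affected family members.

    The three index individuals carry a dataset tag of ``both`` (present
    in the exome analysis too); the remaining five are genome-only.
    """
    samples = [
        Sample(sid, "SYR-1", "Syrian", True,
               dataset="both" if sid in FAMILY1_INDEX_IDS else "WGS")
        for sid in FAMILY1_IDS
    ]
    roster = SampleSet(samples)
    variants, annotations = [], {}
    for gene, chrom, pos, alt, ref, column, f1kg, fgme, fqg, dam in FAMILY1_WGS_VARIANTS:
        v = VariantRecord(
            chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            genotypes=list(column), mapping_quality=60.0, depth=5_000,
            call_rate=1.0, vqsr_pass=True, low_quality_prob=0.0,
            replicate_discordant_pairs=0,
        )
        variants.append(v)
        annotations[v.key] = _annotation(
            chrom, pos, ref, alt, gene, "exonic", "nonsynonymous", f1kg, dam,
            freq_gme=fgme, freq_qg=fqg,
        )
    return variants, roster, annotations


#: Key of the nonsynonymous *CASP9* variant identified in the exome scan.
CASP9_KEY = ("1", 15831171, "T", "C")


# ---------------------------------------------------------------------------
# Compound-heterozygote discovery variants (exome data, index individuals)
# ---------------------------------------------------------------------------

# (gene, chrom, pos, alt, ref, 1000G freq, GME freq, QG freq, damaging count);
# all three index individuals are heterozygous at every site.
COMPHET_DISCOVERY_VARIANTS = [
    ("COL7A1", "3", 48602623, "A", "G", 0.001, 0.005, 0.003, 5),
    ("COL7A1", "3", 48620046, "A", "G", 0.001, 0.005, 0.002, 7),
    ("CELSR3", "3", 48677114, "G", "C", 0.019, 0.011, 0.013, 4),
    ("CELSR3", "3", 48691197, "T", "C", 0.005, 0.005, 0.005, 0),
    ("TKT", "3", 53267183, "T", "C", 0.002, 0.011, 0.010, 3),
    ("TKT", "3", 53269028, "T", "G", 0.002, 0.011, 0.010, 1),
    ("NLRP14", "11", 7060948, "T", "C", 0.014, 0.040, 0.046, 0),
    ("NLRP14", "11", 7083610, "A", "T", 0.015, 0.039, 0.048, 5),
    ("NLRP14", "11", 7083620, "C", "T", 0.022, 0.043, 0.051, 0),
]


def comphet_discovery_bundle() -> tuple[list[VariantRecord], SampleSet, AnnotationTable]:
    """Exome variants of the compound-heterozygote scan (3 index samples)."""
    samples = [Sample(sid, "SYR-1", "Syrian", True, dataset="WES")
               for sid in FAMILY1_INDEX_IDS]
    roster = SampleSet(samples)
    variants, annotations = [], {}
    for gene, chrom, pos, alt, ref, f1kg, fgme, fqg, dam in COMPHET_DISCOVERY_VARIANTS:
        v = VariantRecord(
            chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            genotypes=[HET] * len(roster), mapping_quality=60.0, depth=5_000,
            call_rate=1.0, vqsr_pass=True, low_quality_prob=0.0,
            replicate_discordant_pairs=0,
        )
        variants.append(v)
        annotations[v.key] = _annotation(
            chrom, pos, ref, alt, gene, "exonic", "nonsynonymous", f1kg, dam,
            freq_gme=fgme, freq_qg=fqg,
        )
    return variants, roster, annotations
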