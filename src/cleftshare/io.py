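"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open.  A
  1-based position ``p`` lies inside BED interval ``[start, end)`` iff
  ``start < p <= end``.
* Multiallelic VCF records are split into one biallelic
  :class:`~cleftshare.model.VariantRecord` per alternate allele.  A sample
  heterozygous for two different alternates is ``AR`` on each split record.
* Chromosome labels are normalized (``chr`` prefix stripped) at ingest.
* QC metrics with no standard VCF tag (low-quality probability, replicate
  discordance, call rate) are accepted either as INFO keys
  (``MQ``, ``DP``, ``LOWQ_PROB``, ``REP_DISC``) or as a per-variant sidecar
  TSV keyed by ``chrom, pos, ref, alt``.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PREDICTOR_SOURCES,
    AnnotationRecord,
    AnnotationTable,
    ConsistencyError,
    DAMAGING_LABELS,
    Pedigree,
    Sample,
    SampleSet,
    VariantRecord,
    normalize_chrom,
)

_NA_STRINGS = {"", ".", "-", "–", "na", "nan", "none"}


def _is_na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and pd.isna(value):
        return True
    return str(value).strip().lower() in _NA_STRINGS


def _parse_bool(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "t", "yes", "y"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_state(gt: tuple, alt_index: int) -> str:
    """Collapse a GT allele-index tuple to AA/AR/RR for one alternate."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt >= 2:
        return HOM_ALT
    if n_alt == 1:
        return HET
    return HOM_REF


def read_multisample_vcf(
    path,
    qc_sidecar=None,
    roster: Optional[SampleSet] = None,
) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF into biallelic variant records.

    Returns the records plus the VCF's sample order.  ``FILTER`` of ``PASS``
    maps to ``vqsr_pass=True``, any named filter to ``False`` and ``.`` to
    ``None``.  Call rate is computed from the genotype vector when not
    supplied by a sidecar; replicate discordance is computed from the
    roster's declared duplicate pairs when a roster is given and the VCF
    carries no ``REP_DISC`` key.
    """
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if roster is not None:
        roster = roster.reorder_to(samples)

    records: list[VariantRecord] = []
    for rec in vcf:
        if "GT" not in rec.format:
            raise ValueError(
                f"VCF record {rec.chrom}:{rec.pos} has no GT field; "
                "genotype calls are required"
            )
        filters = list(rec.filter.keys())
        vqsr_pass = None if not filters else (filters == ["PASS"])
        info = rec.info
        mq = float(info["MQ"]) if "MQ" in info else None
        dp = int(info["DP"]) if "DP" in info else None
        lowq = float(info["LOWQ_PROB"]) if "LOWQ_PROB" in info else None
        rep = int(info["REP_DISC"]) if "REP_DISC" in info else None

        gts = [rec.samples[s].get("GT") for s in samples]
        for alt_i, alt in enumerate(rec.alts or (), start=1):
            genotypes = [_genotype_state(gt, alt_i) for gt in gts]
            n_called = sum(1 for g in genotypes if g != MISSING)
            call_rate = n_called / len(genotypes) if genotypes else 1.0
            v = VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alt,
                genotypes=genotypes,
                mapping_quality=mq,
                depth=dp,
                call_rate=call_rate,
                vqsr_pass=vqsr_pass,
                low_quality_prob=lowq,
                replicate_discordant_pairs=rep,
            )
            records.append(v)
    vcf.close()

    if roster is not None:
        for v in records:
            if v.replicate_discordant_pairs is None:
                v.replicate_discordant_pairs = count_discordant_pairs(v, roster)
    if qc_sidecar is not None:
        apply_qc_sidecar(records, qc_sidecar)
    return records, samples


def count_discordant_pairs(variant: VariantRecord, roster: SampleSet) -> int:
    """Number of declared duplicate pairs with a genotype mismatch here.

    A pair with one or both calls missing is not counted as discordant.
    """
    n = 0
    for a, b in roster.duplicate_pairs():
        ga = variant.genotypes[roster.index_of(a)]
        gb = variant.genotypes[roster.index_of(b)]
        if MISSING not in (ga, gb) and ga != gb:
            n += 1
    return n


_SIDECAR_FIELDS = (
    "mapping_quality",
    "depth",
    "call_rate",
    "vqsr_pass",
    "low_quality_prob",
    "replicate_discordant_pairs",
)


def apply_qc_sidecar(records: Sequence[VariantRecord], path) -> None:
    """Overlay per-variant QC metrics from a sidecar TSV onto records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"QC sidecar needs columns {sorted(required)}")
    table = {}
    for row in df.itertuples(index=False):
        key = (normalize_chrom(row.chrom), int(row.pos), row.ref, row.alt)
        table[key] = row
    for rec in records:
        row = table.get(rec.key)
        if row is None:
            continue
        for field in _SIDECAR_FIELDS:
            if not hasattr(row, field):
                continue
            value = getattr(row, field)
            if _is_na(value):
                continue
            if field == "vqsr_pass":
                rec.vqsr_pass = _parse_bool(value)
            elif field in ("depth", "replicate_discordant_pairs"):
                setattr(rec, field, int(float(value)))
            else:
                setattr(rec, field, float(value))


def write_multisample_vcf(
    path,
    records: Sequence[VariantRecord],
    sample_ids: Sequence[str],
) -> None:
    """Write biallelic variant records as a VCF 4.2 text file."""
    header = pysam.VariantHeader()
    header.add_meta("source", "cleftshare")
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    header.filters.add("LOWQUAL", None, None, "Failed variant recalibration")
    header.info.add("MQ", 1, "Float", "Mapping quality")
    header.info.add("DP", 1, "Integer", "Total site depth across samples")
    header.info.add("LOWQ_PROB", 1, "Float", "Probability of being a low-quality variant")
    header.info.add("REP_DISC", 1, "Integer", "Discordant duplicate pairs at this site")
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in sample_ids:
        header.add_sample(sid)

    gt_map = {HOM_ALT: (1, 1), HET: (0, 1), HOM_REF: (0, 0), MISSING: (None, None)}
    out = pysam.VariantFile(os.fspath(path), "w", header=header)
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele)):
        if len(rec.genotypes) != len(sample_ids):
            raise ConsistencyError(
                f"variant {rec.key} has {len(rec.genotypes)} genotypes for "
                f"{len(sample_ids)} samples"
            )
        v = out.new_record(
            contig=rec.chrom,
            start=rec.pos - 1,
            alleles=(rec.ref_allele, rec.alt_allele),
        )
        if rec.vqsr_pass is not None:
            v.filter.add("PASS" if rec.vqsr_pass else "LOWQUAL")
        if rec.mapping_quality is not None:
            v.info["MQ"] = rec.mapping_quality
        if rec.depth is not None:
            v.info["DP"] = rec.depth
        if rec.low_quality_prob is not None:
            v.info["LOWQ_PROB"] = rec.low_quality_prob
        if rec.replicate_discordant_pairs is not None:
            v.info["REP_DISC"] = rec.replicate_discordant_pairs
        for sid, g in zip(sample_ids, rec.genotypes):
            v.samples[sid]["GT"] = gt_map[g]
            v.samples[sid].phased = False
        out.write(v)
    out.close()


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = (
    "sample_id",
    "family_id",
    "population",
    "affection",
    "is_control",
    "duplicate_partner",
    "dataset",
)


def read_sample_metadata(path) -> SampleSet:
    """Read the sample metadata TSV into a validated :class:`SampleSet`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            Sample(
                sample_id=row.sample_id,
                family_id=None if _is_na(row.family_id) else row.family_id,
                population=None if _is_na(row.population) else row.population,
                affected=str(row.affection).strip().lower() in {"affected", "2"},
                is_control=_parse_bool(row.is_control),
                duplicate_partner=(
                    None if _is_na(row.duplicate_partner) else row.duplicate_partner
                ),
                dataset=row.dataset if not _is_na(row.dataset) else "WES",
            )
        )
    return SampleSet(samples)


def write_sample_metadata(path, roster: SampleSet) -> None:
    rows = []
    for s in roster:
        rows.append(
            {
                "sample_id": s.sample_id,
                "family_id": s.family_id or "",
                "population": s.population or "",
                "affection": "affected" if s.affected else "unaffected",
                "is_control": str(s.is_control),
                "duplicate_partner": s.duplicate_partner or "",
                "dataset": s.dataset,
            }
        )
    pd.DataFrame(rows, columns=list(_METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> AnnotationTable:
    """Read the per-variant annotation TSV keyed by (chrom, pos, ref, alt).

    The nine pathogenicity predictor columns must all be present; each cell
    is a categorical label and counts as damaging iff it falls in that
    source's damaging label set.  An absent value is not damaging.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_pred = [c for c in PREDICTOR_SOURCES if c not in df.columns]
    if missing_pred:
        raise ValueError(
            f"annotation table is missing predictor columns: {missing_pred}"
        )
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")

    table: AnnotationTable = {}
    for row in df.itertuples(index=False):
        calls = tuple(
            (not _is_na(getattr(row, src)))
            and str(getattr(row, src)).strip() in DAMAGING_LABELS[src]
            for src in PREDICTOR_SOURCES
        )
        rec = AnnotationRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            gene=None if _is_na(getattr(row, "gene", None)) else row.gene,
            location=(
                None
                if _is_na(getattr(row, "location", None))
                else str(row.location).strip().lower()
            ),
            function=(
                None
                if _is_na(getattr(row, "function", None))
                else str(row.function).strip().lower()
            ),
            damaging_calls=calls,
            freq_1000g=(
                None if _is_na(getattr(row, "freq_1000g", None)) else float(row.freq_1000g)
            ),
            freq_gme=(
                None if _is_na(getattr(row, "freq_gme", None)) else float(row.freq_gme)
            ),
            freq_qg=(
                None if _is_na(getattr(row, "freq_qg", None)) else float(row.freq_qg)
            ),
            dbsnp_common=_parse_bool(getattr(row, "dbsnp_common", "false")),
        )
        if rec.key in table:
            raise ValueError(f"duplicate annotation key {rec.key}")
        table[rec.key] = rec
    return table


def write_annotation_table(path, table: AnnotationTable) -> None:
    rows = []
    for key in sorted(table):
        rec = table[key]
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref_allele,
            "alt": rec.alt_allele,
            "gene": rec.gene or ".",
            "location": rec.location or ".",
            "function": rec.function or ".",
            "freq_1000g": "." if rec.freq_1000g is None else f"{rec.freq_1000g:.6g}",
            "freq_gme": "." if rec.freq_gme is None else f"{rec.freq_gme:.6g}",
            "freq_qg": "." if rec.freq_qg is None else f"{rec.freq_qg:.6g}",
            "dbsnp_common": str(rec.dbsnp_common),
        }
        for src, call in zip(PREDICTOR_SOURCES, rec.damaging_calls):
            # Use a label each source's damaging set actually contains.
            labels = DAMAGING_LABELS[src]
            row[src] = ("D" if "D" in labels else sorted(labels)[-1]) if call else "T"
        rows.append(row)
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "location", "function",
        *PREDICTOR_SOURCES, "freq_1000g", "freq_gme", "freq_qg", "dbsnp_common",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

class RegionSet:
    """Genomic intervals queryable by (chrom, 1-based position).

    Intervals are stored 0-based half-open, as in BED; a 1-based position
    ``p`` is inside ``[start, end)`` iff ``start < p <= end``.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.regions: list[tuple[str, int, int, str]] = []

    def add(self, chrom: str, start: int, end: int, name: str = ".") -> None:
        if end <= start:
            raise ValueError(f"interval end must exceed start: {chrom}:{start}-{end}")
        chrom = normalize_chrom(chrom)
        self._trees.setdefault(chrom, IntervalTree())[start:end] = name
        self.regions.append((chrom, start, end, name))

    def __len__(self) -> int:
        return len(self.regions)

    def __bool__(self) -> bool:
        return bool(self.regions)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(normalize_chrom(chrom))
        return bool(tree is not None and tree[pos - 1])

    def regions_at(self, chrom: str, pos: int) -> list[str]:
        """Names of regions covering a 1-based position (deduplicated)."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree[pos - 1]})


def read_regions_bed(path) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a RegionSet."""
    regions = RegionSet()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"region{line_no}"
            regions.add(parts[0], int(parts[1]), int(parts[2]), name)
    return regions


def write_regions_bed(path, regions: Iterable[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# PED pedigree files
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file into a Pedigree."""
    ped = Pedigree()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{line_no}: PED needs 6 columns")
            fid, iid, father, mother, sex, pheno = parts[:6]
            ped.add_individual(
                iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=int(sex) if sex in ("1", "2") else 0,
                affected=pheno == "2",
                family_id=fid,
            )
    ped.validate()
    return ped


def write_pedigree(path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for ind in ped.topological_order():
            node = ped.graph.nodes[ind]
            fh.write(
                "\t".join(
                    [
                        node.get("family_id") or "0",
                        ind,
                        node.get("father") or "0",
                        node.get("mother") or "0",
                        str(node.get("sex") or 0),
                        "2" if node.get("affected") else "1",
                    ]
                )
                + "\n"
            )
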