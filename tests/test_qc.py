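"""Drop rules: threshold boundaries, the joint VQSR+classifier rule,
exclusion lists, rarity, and the cascade's algebraic properties."""

import numpy as np
import pytest

from cleftshare.model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotationRecord,
    FilterConfig,
)
from cleftshare.qc import (
    DropReason,
    MissingQCFieldError,
    apply_exclusion_lists,
    apply_quality_filter,
    apply_rarity_filter,
    control_genotypes_of,
    filter_variants,
)

from conftest import make_roster, make_variant, random_annotations, random_variants

POLY = [HOM_ALT, HET, HOM_REF]  # polymorphic genotype vector


@pytest.mark.parametrize(
    "qc_overrides, expected_reasons",
    [
        ({"mapping_quality": 29.9}, [DropReason.MQ_LOW]),
        ({"mapping_quality": 30.0}, []),
        ({"depth": 7}, [DropReason.DEPTH_LOW]),
        ({"depth": 8}, []),
        ({"depth": 20_000}, []),
        ({"depth": 20_001}, [DropReason.DEPTH_HIGH]),
        ({"call_rate": 0.979}, [DropReason.CALL_RATE_LOW]),
        ({"call_rate": 0.98}, []),
        ({"replicate_discordant_pairs": 2}, [DropReason.REPLICATE_DISCORDANT]),
        ({"replicate_discordant_pairs": 1}, []),
        # The joint rule drops only on failing VQSR AND probability > 0.70.
        ({"vqsr_pass": False, "low_quality_prob": 0.70}, []),
        ({"vqsr_pass": False, "low_quality_prob": 0.71}, [DropReason.VQSR_AND_ML_FAIL]),
        ({"vqsr_pass": True, "low_quality_prob": 0.99}, []),
    ],
)
def test_quality_thresholds(config, qc_overrides, expected_reasons):
    variant = make_variant(POLY, **qc_overrides)
    decision = apply_quality_filter(variant, config)
    assert decision.reasons == expected_reasons
    assert decision.kept == (not expected_reasons)


def test_monomorphic_vectors_dropped(config):
    for vector in ([HET, HET, HET], [HOM_REF, HOM_REF, MISSING], [MISSING] * 3):
        decision = apply_quality_filter(make_variant(vector), config)
        assert DropReason.MONOMORPHIC in decision.reasons


def test_call_rate_rule_skipped_on_y(config):
    variant = make_variant(POLY, chrom="Y", call_rate=0.5)
    assert apply_quality_filter(variant, config).kept


def test_missing_metric_strict_vs_permissive():
    variant = make_variant(POLY, mapping_quality=None)
    with pytest.raises(MissingQCFieldError):
        apply_quality_filter(variant, FilterConfig(strict_qc=True))
    assert apply_quality_filter(variant, FilterConfig(strict_qc=False)).kept


def _ann(variant, gene="GENEX", freq=None, dbsnp=False):
    return AnnotationRecord(
        chrom=variant.chrom, pos=variant.pos, ref_allele=variant.ref_allele,
        alt_allele=variant.alt_allele, gene=gene, location="exonic",
        function="nonsynonymous", freq_1000g=freq, dbsnp_common=dbsnp,
    )


def test_exclusion_lists(config):
    config = FilterConfig(frequent_hitter_genes={"MUC4"})
    v = make_variant(POLY)
    assert apply_exclusion_lists(v, _ann(v, gene="MUC4"), config).reasons == [
        DropReason.FREQUENT_HITTER
    ]
    assert apply_exclusion_lists(v, _ann(v, gene="OTHER"), config).kept
    assert apply_exclusion_lists(v, None, config).kept  # unannotated passes

    # Position inside the extended MHC on chromosome 6 is dropped only when
    # the per-analysis HLA toggle is on.
    hla_variant = make_variant(POLY, chrom="6", pos=33_059_894)
    d = apply_exclusion_lists(hla_variant, _ann(hla_variant), config, exclude_hla=True)
    assert d.reasons == [DropReason.HLA_REGION]
    d = apply_exclusion_lists(hla_variant, _ann(hla_variant), config, exclude_hla=False)
    assert d.kept


@pytest.mark.parametrize(
    "freq, dbsnp, controls, expected",
    [
        (0.027, False, [HOM_REF, HOM_REF], []),
        (None, False, [HOM_REF, HOM_REF], []),  # absent frequency = novel
        (0.04, False, [HET, HOM_REF], [DropReason.CONTROL_CARRIER]),
        (0.051, False, [HOM_REF, HOM_REF], [DropReason.COMMON_1000G]),
        (0.05, False, [HOM_REF, HOM_REF], []),  # strictly greater than 5%
        (0.001, True, [HOM_REF, HOM_REF], [DropReason.DBSNP_COMMON]),
        (0.001, False, [HOM_ALT, MISSING], [DropReason.CONTROL_CARRIER]),
    ],
)
def test_rarity_filter(config, freq, dbsnp, controls, expected):
    v = make_variant(POLY)
    d = apply_rarity_filter(v, _ann(v, freq=freq, dbsnp=dbsnp), controls, config)
    assert d.reasons == expected


def _kept_set(variants, annotations, roster, config):
    decisions = filter_variants(variants, annotations, roster, config)
    return {k for k, d in decisions.items() if d.kept}


def test_cascade_oracle_and_order_independence(config):
    """The cascade's kept set equals one-predicate-at-a-time brute force,
    in any evaluation order, and re-filtering is a no-op."""
    rng = np.random.default_rng(11)
    roster = make_roster(n_affected=8, n_controls=2)
    variants = random_variants(rng, 50, len(roster))
    annotations = random_annotations(rng, variants)
    config = FilterConfig(frequent_hitter_genes={"HITTER"})

    kept = _kept_set(variants, annotations, roster, config)

    # Brute force: each predicate independently, conjunction at the end.
    brute = set()
    for v in variants:
        preds = [
            apply_quality_filter(v, config, roster).kept,
            apply_exclusion_lists(v, annotations[v.key], config).kept,
            apply_rarity_filter(
                v, annotations[v.key], control_genotypes_of(v, roster), config
            ).kept,
        ]
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            assert all(preds[i] for i in order) == all(preds)
        if all(preds):
            brute.add(v.key)
    assert kept == brute

    # Idempotence: filtering the kept subset again changes nothing.
    kept_variants = [v for v in variants if v.key in kept]
    assert _kept_set(kept_variants, annotations, roster, config) == kept


def test_cascade_monotonicity(config):
    """Tightening the MAF ceiling or growing the exclusion list can only
    shrink the kept set."""
    rng = np.random.default_rng(13)
    roster = make_roster(n_affected=8, n_controls=2)
    variants = random_variants(rng, 50, len(roster))
    annotations = random_annotations(rng, variants)

    base = _kept_set(variants, annotations, roster, FilterConfig())
    tighter = _kept_set(variants, annotations, roster, FilterConfig(max_maf=0.01))
    assert tighter <= base
    excluded = _kept_set(
        variants, annotations, roster, FilterConfig(frequent_hitter_genes={"G1", "G2"})
    )
    assert excluded <= base


def test_decision_log_round_trip(tmp_path, config):
    rng = np.random.default_rng(17)
    roster = make_roster(n_affected=4, n_controls=1)
    variants = random_variants(rng, 10, len(roster))
    annotations = random_annotations(rng, variants)
    decisions = filter_variants(variants, annotations, roster, config)
    from cleftshare.qc import write_decision_log

    path = tmp_path / "drops.tsv"
    write_decision_log(path, decisions)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 11  # header + one line per variant
    for line in lines[1:]:
        _, kept, reasons = line.split("\t")
        assert (kept == "True") == (reasons == "")
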