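"""Genotype tallies and the three sharing criteria, with brute-force
oracles and the published family-scan table as a regression fixture."""

import numpy as np
import pytest

from cleftshare import examples as ex
from cleftshare.model import FilterConfig, GenotypeCounts, HET, HOM_ALT, HOM_REF, MISSING
from cleftshare.sharing import (
    count_genotypes,
    family_filter,
    population_filter,
    wgs_discovery_filter,
)

from conftest import make_roster, make_variant


def test_count_genotypes_on_published_columns(family1_bundle):
    """Tallies over the eight genome-sequenced family members match the
    published counts: CASP9 (4,3,1) and FAT4 (2,5,1)."""
    variants, roster, _ = family1_bundle
    by_key = {v.key: v for v in variants}
    casp9 = count_genotypes(by_key[ex.CASP9_KEY], ex.FAMILY1_IDS, roster)
    assert (casp9.n_hom_alt, casp9.n_het, casp9.n_hom_ref) == (4, 3, 1)
    fat4 = count_genotypes(by_key[("4", 126367606, "G", "T")], ex.FAMILY1_IDS, roster)
    assert (fat4.n_hom_alt, fat4.n_het, fat4.n_hom_ref) == (2, 5, 1)
    assert count_genotypes(by_key[ex.CASP9_KEY], [], roster).total == 0


def test_count_genotypes_unknown_sample(family1_bundle):
    variants, roster, _ = family1_bundle
    with pytest.raises(Exception):
        count_genotypes(variants[0], ["NOT_A_SAMPLE"], roster)


def test_conservation_property():
    """AA + AR + RR + missing always equals the subset size."""
    rng = np.random.default_rng(3)
    roster = make_roster(n_affected=10)
    states = [HOM_ALT, HET, HOM_REF, MISSING]
    for _ in range(50):
        v = make_variant([states[j] for j in rng.integers(0, 4, 10)])
        k = int(rng.integers(0, 11))
        subset = list(rng.choice(roster.sample_ids, size=k, replace=False))
        assert count_genotypes(v, subset, roster).total == k


@pytest.mark.parametrize(
    "counts, n_cases, expect_pass",
    [
        # 5 of 22 carriers (~0.227) with one homozygote: passes.
        (GenotypeCounts(1, 4, 17, 0), 22, True),
        (GenotypeCounts(0, 10, 12, 0), 22, False),  # no homozygote
        (GenotypeCounts(5, 0, 17, 0), 22, True),
        (GenotypeCounts(1, 2, 19, 0), 22, False),  # 3/22 < 20%
    ],
)
def test_population_filter(config, counts, n_cases, expect_pass):
    result = population_filter(counts, n_cases, config)
    assert result.passed == expect_pass
    assert result.carrier_fraction == pytest.approx(counts.n_carriers / n_cases)


def test_population_filter_rejects_zero_cases(config):
    with pytest.raises(ValueError):
        population_filter(GenotypeCounts(), 0, config)


def test_population_filter_missing_denominator_toggle():
    """Missing calls stay in the denominator by default but can be excluded."""
    counts = GenotypeCounts(1, 2, 11, 6)  # 3/20 = 0.15 but 3/14 ~ 0.21
    assert not population_filter(counts, 20, FilterConfig()).passed
    cfg = FilterConfig(population_exclude_missing_from_denominator=True)
    assert population_filter(counts, 20, cfg).passed


@pytest.mark.parametrize(
    "counts, expect_pass",
    [
        (GenotypeCounts(3, 0, 0), True),   # three homozygous affected members
        (GenotypeCounts(2, 1, 0), True),   # two homozygotes, one het
        (GenotypeCounts(1, 1, 0), False),
        (GenotypeCounts(0, 2, 0), False),
    ],
)
def test_family_filter(config, counts, expect_pass):
    (result,) = family_filter({"FAM": counts}, config)
    assert result.passed == expect_pass


def test_family_filter_rejects_single_member_family(config):
    with pytest.raises(ValueError):
        family_filter({"FAM": GenotypeCounts(1, 0, 0)}, config)


@pytest.mark.parametrize(
    "counts, n_members, expect_pass",
    [
        (GenotypeCounts(4, 3, 1), 8, True),   # 7 carriers, 4 homozygotes
        (GenotypeCounts(2, 5, 1), 8, True),   # 7 carriers, 2 homozygotes
        (GenotypeCounts(0, 7, 1), 8, False),  # no homozygote
        (GenotypeCounts(1, 5, 2), 8, False),  # 6 carriers < 7
    ],
)
def test_wgs_discovery_filter(config, counts, n_members, expect_pass):
    assert wgs_discovery_filter(counts, n_members, config).passed == expect_pass


def test_wgs_quota_scales_with_family_size(config):
    """The 7-of-8 quota generalizes as the ceiling of the same proportion."""
    assert config.wgs_carrier_quota(8) == 7
    assert config.wgs_carrier_quota(16) == 14
    assert config.wgs_carrier_quota(4) == 4   # ceil(3.5)
    assert config.wgs_carrier_quota(10) == 9  # ceil(8.75)
    # A family of 4 passes only if every member carries the allele.
    assert wgs_discovery_filter(GenotypeCounts(1, 3, 0), 4, config).passed
    assert not wgs_discovery_filter(GenotypeCounts(1, 2, 1), 4, config).passed


def test_wgs_alternative_homozygote_reading():
    """Under the stricter reading, the carrier quota excludes one obligate
    homozygote, so 7 of the 8 *other* members must carry the allele."""
    cfg = FilterConfig(wgs_homozygote_counts_as_carrier=False)
    assert not wgs_discovery_filter(GenotypeCounts(4, 3, 1), 8, cfg).passed
    assert wgs_discovery_filter(GenotypeCounts(4, 4, 0), 8, cfg).passed


def test_threshold_monotonicity():
    """Raising a sharing threshold never adds variants to the pass set."""
    rng = np.random.default_rng(21)
    tallies = [
        GenotypeCounts(*map(int, rng.multinomial(10, [0.2, 0.3, 0.4, 0.1])))
        for _ in range(200)
    ]
    loose = FilterConfig(population_min_carrier_fraction=0.2, family_min_hom=2)
    tight = FilterConfig(population_min_carrier_fraction=0.4, family_min_hom=3)
    for counts in tallies:
        if population_filter(counts, 10, tight).passed:
            assert population_filter(counts, 10, loose).passed
        (tf,) = family_filter({"F": counts}, tight)
        (lf,) = family_filter({"F": counts}, loose)
        if tf.passed:
            assert lf.passed


def test_sharing_oracle_equivalence(config):
    """Each filter's pass verdict matches a from-scratch re-evaluation of
    its predicate on random variant-by-sample matrices."""
    rng = np.random.default_rng(29)
    roster = make_roster(n_affected=10)
    states = [HOM_ALT, HET, HOM_REF, MISSING]
    for _ in range(200):
        vector = [states[j] for j in rng.integers(0, 4, 10)]
        v = make_variant(vector)
        counts = count_genotypes(v, roster.sample_ids, roster)
        aa = vector.count(HOM_ALT)
        carriers = aa + vector.count(HET)
        assert population_filter(counts, 10, config).passed == (
            aa >= 1 and carriers / 10 >= 0.20
        )
        (fam,) = family_filter({"F": counts}, config)
        assert fam.passed == (aa >= 2)
        assert wgs_discovery_filter(counts, 10, config).passed == (
            aa >= 1 and carriers >= 9  # ceil(7/8 * 10)
        )


def test_family_scan_fixture_reproduces_published_pass_counts(config):
    """The published family-scan table is reproduced exactly: 11 Syrian,
    5 German, 1 Indian and 2 Filipino passing variant rows."""
    per_population = {}
    for pop, fam, gene, _chrom, _pos, _alt, _ref, aa, ar, rr, *_ in ex.FAMILY_SCAN_HITS:
        (res,) = family_filter({fam: GenotypeCounts(aa, ar, rr)}, config)
        assert res.passed, (pop, gene)
        per_population[pop] = per_population.get(pop, 0) + 1
    assert per_population == {"Syrian": 11, "German": 5, "Indian": 1, "Filipino": 2}
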