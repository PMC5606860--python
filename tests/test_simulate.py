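"""Gene-dropping simulator: transmission fidelity, inbreeding behaviour,
planting, determinism, and the study-shaped presets."""

import hashlib

import numpy as np
import pytest

from cleftshare.model import ConsistencyError, Pedigree
from cleftshare.simulate import (
    PlantSpec,
    SimulationConfig,
    check_mendelian,
    consanguineous_multiplex_family,
    cousin_multiplex_family,
    dosage_matrix,
    first_cousin_pedigree,
    generate_study_fixture,
    plant_causal_variants,
    preset_config,
    simulate_pedigree_genotypes,
    wes_preset_families,
    wgs_preset_families,
)


def test_degenerate_frequencies():
    """Fixed founder alleles propagate unchanged: freq 0 gives all
    homozygous-reference, freq 1 all homozygous-alternate."""
    ped, child = first_cousin_pedigree()
    alleles = simulate_pedigree_genotypes(ped, np.array([0.0, 1.0]), 1)
    d = dosage_matrix(alleles, ped.individuals)
    assert (d[:, 0] == 0).all()
    assert (d[:, 1] == 2).all()


def test_mendelian_consistency_exhaustive():
    """Every simulated child genotype is composable from parental alleles."""
    ped, _ = consanguineous_multiplex_family("FAM")
    rng = np.random.default_rng(2)
    alleles = simulate_pedigree_genotypes(ped, rng.uniform(0, 1, 300), rng)
    assert check_mendelian(ped, alleles) == []


def test_cyclic_pedigree_rejected():
    ped = Pedigree()
    ped.add_individual("a", father="b", mother="c")
    ped.add_individual("b", father="a", mother="c")
    ped.add_individual("c")
    with pytest.raises(ConsistencyError):
        simulate_pedigree_genotypes(ped, np.array([0.5]), 0)


def test_first_cousin_inbreeding_coefficient():
    ped, child = first_cousin_pedigree()
    assert ped.inbreeding_coefficient(child) == pytest.approx(1 / 16)


def test_first_cousin_homozygosity_matches_closed_form():
    """Offspring of first cousins are homozygous for a rare allele at rate
    F*q + (1-F)*q^2 with F = 1/16; the gene-dropped estimate over 1e5
    replicates falls within 3 standard errors of the closed form."""
    ped, child = first_cousin_pedigree()
    q, n = 0.01, 100_000
    alleles = simulate_pedigree_genotypes(ped, np.full(n, q), 12345)
    rate = (alleles[child].sum(axis=1) == 2).mean()
    F = 1 / 16
    expected = F * q + (1 - F) * q * q
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rate - expected) < 3 * se


def test_founder_frequency_recovery():
    """The founder sample allele frequency converges to the requested value
    within binomial confidence bounds."""
    ped = Pedigree()
    for i in range(400):
        ped.add_individual(f"f{i}")
    q = 0.3
    alleles = simulate_pedigree_genotypes(ped, np.full(50, q), 9)
    freq = np.mean([alleles[f].mean() for f in ped.individuals])
    se = np.sqrt(q * (1 - q) / (2 * 400 * 50))
    assert abs(freq - q) < 4 * se


def test_planting_recessive_and_repair():
    """Planted homozygotes acquire Mendelian-consistent carrier ancestors;
    the heterogeneity slot stays homozygous-reference."""
    ped, affected = consanguineous_multiplex_family("FAM")
    alleles = simulate_pedigree_genotypes(ped, np.zeros(5), 3)
    spec = PlantSpec(
        gene="G", mode="recessive_shared", site_indices=[2],
        hom_individuals=affected[:4], het_individuals=affected[4:7],
        non_carriers=affected[7:],
    )
    planted = plant_causal_variants(alleles, spec, ped)
    assert check_mendelian(ped, planted) == []
    for ind in affected[:4]:
        assert planted[ind][2].sum() == 2
    for ind in affected[4:7]:
        assert planted[ind][2].sum() == 1
    assert planted[affected[7]][2].sum() == 0  # exactly one designated RR


def test_planting_conflict_detected():
    """A non-carrier who is an obligate transmitting ancestor raises."""
    ped, affected, _ = cousin_multiplex_family("FAM", 2)
    parent = ped.parents(affected[0])[0]
    alleles = simulate_pedigree_genotypes(ped, np.zeros(3), 4)
    spec = PlantSpec(
        gene="G", mode="recessive_shared", site_indices=[0],
        hom_individuals=[affected[0]], het_individuals=[affected[1]],
        non_carriers=[parent],
    )
    with pytest.raises(ConsistencyError):
        plant_causal_variants(alleles, spec, ped)
    # force=True overrides the conflict.
    spec.force = True
    planted = plant_causal_variants(alleles, spec, ped)
    assert planted[affected[0]][0].sum() == 2


def _bundle_digest(out_dir, seed):
    fixture = generate_study_fixture(preset_config("family1", seed=seed))
    paths = fixture.write(out_dir)
    h = hashlib.sha256()
    for name in sorted(paths):
        with open(paths[name], "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()


def test_fixture_bundles_are_byte_identical_under_seed(tmp_path):
    assert _bundle_digest(tmp_path / "a", 11) == _bundle_digest(tmp_path / "b", 11)
    assert _bundle_digest(tmp_path / "c", 12) != _bundle_digest(tmp_path / "a", 11)


def test_exome_preset_cohort_shape():
    """52 families, 4 of them with three affected members, 108 affected."""
    fams = wes_preset_families()
    assert len(fams) == 52
    assert sum(f.n_affected for f in fams) == 108
    assert sum(1 for f in fams if f.n_affected == 3) == 4
    fixture = generate_study_fixture(preset_config("wes", seed=0))
    affected = [s for s in fixture.roster if s.affected]
    assert len(affected) == 108
    assert len({s.family_id for s in affected}) == 52
    assert len(fixture.roster.controls) == 2
    assert len(fixture.roster.duplicate_pairs()) == 4


def test_genome_preset_cohort_shape():
    """32 families, 113 sequenced individuals of whom 107 are affected."""
    fams = wgs_preset_families()
    assert len(fams) == 32
    fixture = generate_study_fixture(preset_config("wgs", seed=0))
    members = [s for s in fixture.roster if s.family_id is not None]
    assert len(members) == 113
    assert sum(s.affected for s in members) == 107
    assert len({s.family_id for s in members}) == 32
    overlap = [s for s in members if s.dataset == "both"]
    assert len(overlap) == 6
    assert len({s.family_id for s in overlap}) == 2


def test_fixture_files_parse_back(tmp_path):
    """The emitted bundle is self-consistent: the VCF, metadata, pedigree
    and annotation files read back and reconcile."""
    import cleftshare.io as csio

    fixture = generate_study_fixture(preset_config("family1", seed=5))
    paths = fixture.write(tmp_path)
    roster = csio.read_sample_metadata(paths["metadata"])
    variants, order = csio.read_multisample_vcf(paths["vcf"])
    roster = roster.reorder_to(order)
    assert len(variants) == len(fixture.variants)
    annotations = csio.read_annotation_table(paths["annotation"])
    assert set(annotations) == {v.key for v in fixture.variants}
    ped = csio.read_pedigree(paths["ped"])
    for s in roster:
        if s.family_id is not None:
            assert s.sample_id in ped.graph.nodes
    regions = csio.read_regions_bed(paths["regions"])
    assert len(regions) > 0
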