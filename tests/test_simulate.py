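"""Synthetic-data generator: determinism, truth completeness, rates, masses."""

import numpy as np
import pytest

from rrnphase.simulate import (CommunityDesign, ERROR_FREE, ErrorModel,
                               genome_dna_mass, make_community,
                               make_gene_copy_set, make_species_database,
                               pooled_mass_for_copies, random_gene,
                               replay_events, simulate_ccs_reads)
from rrnphase.compare import unique_copy_count

from conftest import random_seq


def test_no_loci_means_identical_copies():
    gcs, truth = make_gene_copy_set(random_gene(300, 1), C=5, n_snp_loci=0,
                                    copies_per_locus=[], seed=2)
    assert unique_copy_count(gcs) == 1
    assert truth.planted_variants["genome"] == []


def test_planted_loci_hit_exactly_the_stated_copies(rng):
    base = random_gene(400, 3)
    gcs, truth = make_gene_copy_set(base, C=7, n_snp_loci=3,
                                    copies_per_locus=[1, 3, 5], seed=4)
    for pos, carriers in truth.planted_variants["genome"]:
        ref_base = gcs.reference_copy[pos - 1]
        for ci, copy in enumerate(gcs.copies):
            if ci in carriers:
                assert copy[pos - 1] != ref_base
            else:
                assert copy[pos - 1] == ref_base


def test_pairwise_copy_differences_equal_truth_symmetric_difference():
    base = random_gene(350, 5)
    gcs, truth = make_gene_copy_set(base, C=4, n_snp_loci=4,
                                    copies_per_locus=[1, 2, 3, 1], seed=6)
    loci = {ci: set() for ci in range(4)}
    for pos, carriers in truth.planted_variants["genome"]:
        for c in carriers:
            loci[c].add(pos)
    for a in range(4):
        for b in range(4):
            diff = sum(x != y for x, y in zip(gcs.copies[a], gcs.copies[b]))
            assert diff == len(loci[a] ^ loci[b])


def test_too_many_loci_rejected():
    with pytest.raises(ValueError):
        make_gene_copy_set("ACGTACGT", C=3, n_snp_loci=50,
                           copies_per_locus=[1] * 50)
    with pytest.raises(ValueError):
        make_gene_copy_set(random_gene(100, 0), C=3, n_snp_loci=1,
                           copies_per_locus=[3])  # must be <= C-1


def test_error_free_reads_equal_source_copies():
    gcs, truth = make_gene_copy_set(random_gene(300, 7), C=3, n_snp_loci=2,
                                    copies_per_locus=[1, 2], seed=8)
    reads = simulate_ccs_reads(truth, 30, ERROR_FREE, seed=9)
    by_id = {p.read_id: p for p in truth.reads}
    for rid, seq in reads:
        prov = by_id[rid]
        assert seq == gcs.copies[prov.copy_index]
        assert prov.events == []


def test_seed_determinism_byte_identical():
    gcs, t1 = make_gene_copy_set(random_gene(400, 11), C=4, n_snp_loci=2,
                                 copies_per_locus=[1, 2], seed=12)
    _, t2 = make_gene_copy_set(random_gene(400, 11), C=4, n_snp_loci=2,
                               copies_per_locus=[1, 2], seed=12)
    model = ErrorModel()
    r1 = simulate_ccs_reads(t1, 50, model, seed=99)
    r2 = simulate_ccs_reads(t2, 50, model, seed=99)
    assert r1 == r2


def test_truth_completeness_replay_reconstructs_reads():
    gcs, truth = make_gene_copy_set(random_gene(500, 13), C=5, n_snp_loci=3,
                                    copies_per_locus=[2, 3, 4], seed=14)
    model = ErrorModel(substitution_rate=0.01, insertion_rate=0.005,
                       deletion_rate_base=0.01, homopolymer_factor=2.0)
    reads = simulate_ccs_reads(truth, 40, model, seed=15)
    by_id = {p.read_id: p for p in truth.reads}
    assert len(by_id) == 40
    for rid, seq in reads:
        prov = by_id[rid]
        assert replay_events(gcs.copies[prov.copy_index], prov.events) == seq


def test_substitution_rate_recovered_binomially():
    base = random_gene(1000, 17)
    gcs, truth = make_gene_copy_set(base, C=1, n_snp_loci=0,
                                    copies_per_locus=[], seed=18)
    e = 0.01
    model = ErrorModel(substitution_rate=e, insertion_rate=0.0,
                       deletion_rate_base=0.0, homopolymer_factor=1.0)
    reads = simulate_ccs_reads(truth, 100, model, seed=19)
    mismatches = sum(sum(a != b for a, b in zip(seq, base))
                     for _, seq in reads)
    n = 100 * len(base)
    assert abs(mismatches / n - e) < 3 * np.sqrt(e * (1 - e) / n)


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        ErrorModel(substitution_rate=1.2)
    with pytest.raises(ValueError):
        ErrorModel(homopolymer_factor=0.0)


def test_community_mixing_binomial_and_validation(rng):
    a, _ = make_gene_copy_set(random_gene(300, 21), C=2, n_snp_loci=0,
                              copies_per_locus=[], seed=21, genome_id="ga")
    b, _ = make_gene_copy_set(random_gene(300, 22), C=2, n_snp_loci=0,
                              copies_per_locus=[], seed=22, genome_id="gb")
    reads, truth = make_community([a, b], [0.5, 0.5], 1000, ERROR_FREE,
                                  seed=23)
    n_a = sum(p.genome_id == "ga" for p in truth.reads)
    assert abs(n_a - 500) < 3 * np.sqrt(1000 * 0.25)
    with pytest.raises(ValueError):
        make_community([a, b], [0.9, 0.2], 10, ERROR_FREE)
    with pytest.raises(ValueError):
        make_community([a], [0.5, 0.5], 10, ERROR_FREE)


def test_genome_dna_mass_formula():
    assert genome_dna_mass(1e6) == pytest.approx(1.096e-15)
    assert genome_dna_mass(0) == 0.0
    assert genome_dna_mass(2e6) == pytest.approx(2 * genome_dna_mass(1e6))
    with pytest.raises(ValueError):
        genome_dna_mass(-1)


def test_pooled_mass_equalizes_16s_copies():
    design = CommunityDesign([("seven", 4_000_000, 7),
                              ("one", 4_000_000, 1)])
    masses = pooled_mass_for_copies(design, target_copies=7e9)
    # same genome size: member with 7 copies needs 7x less DNA
    assert masses["one"] / masses["seven"] == pytest.approx(7.0)
    single = CommunityDesign([("only", 2_000_000, 4)])
    m = pooled_mass_for_copies(single, target_copies=1e9)
    assert m["only"] == pytest.approx(1e9 / 4 * genome_dna_mass(2_000_000))
    doubled = pooled_mass_for_copies(design, target_copies=14e9)
    assert doubled["seven"] == pytest.approx(2 * masses["seven"])
    with pytest.raises(ValueError):
        CommunityDesign([("bad", 1000, 0)])


def test_species_database_confines_variation_to_windows(rng):
    motif = "AGAGTTTGATCCTGGCTCAG"
    db = make_species_database(10, length=800,
                               variable_windows=[(300, 500)],
                               n_variable_sites=12,
                               conserved=[(1, motif)], seed=31)
    assert len(db) == 10
    ref = db[0][1]
    for _, seq in db:
        assert seq[:20] == motif
        for p, (x, y) in enumerate(zip(seq, ref)):
            if x != y:
                assert 299 <= p < 500
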