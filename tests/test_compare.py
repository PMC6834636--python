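"""Predicted profiles, zeta_w, profile comparison and unique counting."""

import itertools

import numpy as np
import pytest

from rrnphase.compare import (GeneCopySet, count_unique_profiles,
                              count_unique_profiles_by_otu,
                              estimate_measurement_error, map_positions,
                              predicted_profile, profiles_differ,
                              project_calls, sample_zeta_w,
                              unique_copy_count)
from rrnphase.simulate import make_gene_copy_set
from rrnphase.snp import QC_FAIL_LOW_DEPTH, QC_PASS, SNPCallSet, SnpThresholds
from rrnphase.profiles import SubstitutionProfile

from conftest import random_seq


def calls(fractions, qc=QC_PASS):
    return SNPCallSet(reference_id="r", qc_status=qc,
                      thresholds=SnpThresholds(), snp_fractions=fractions)


def test_identical_copies_predict_empty_profile(rng):
    gcs = GeneCopySet("g", [random_seq(rng, 300)] * 5)
    assert predicted_profile(gcs).expected_fraction == {}
    assert unique_copy_count(gcs) == 1


def test_three_of_seven_copies_give_43_percent(rng):
    base = random_seq(rng, 400)
    gcs, truth = make_gene_copy_set(base, 7, n_snp_loci=1,
                                    copies_per_locus=[3], seed=9)
    prof = predicted_profile(gcs)
    pos, carriers = truth.planted_variants["genome"][0]
    assert prof.expected_fraction == {pos: pytest.approx(3 / 7)}
    assert round(100 * prof.expected_fraction[pos]) == 43


def test_predicted_profile_matches_counting_oracle(rng):
    base = random_seq(rng, 350)
    for seed in range(5):
        gcs, _ = make_gene_copy_set(base, 6, n_snp_loci=8,
                                    copies_per_locus=[1, 2, 3, 4, 5, 1, 2, 3],
                                    seed=seed)
        prof = predicted_profile(gcs)
        ref = gcs.reference_copy
        expect = {}
        for p in range(len(ref)):  # brute-force per-position count
            k = sum(c[p] != ref[p] for c in gcs.copies)
            if k:
                expect[p + 1] = k / len(gcs.copies)
        assert {p: pytest.approx(f) for p, f in expect.items()} \
            == prof.expected_fraction


def test_predicted_profile_equals_generator_truth(rng):
    base = random_seq(rng, 500)
    gcs, truth = make_gene_copy_set(base, 7, n_snp_loci=6,
                                    copies_per_locus=[1, 2, 3, 4, 5, 6],
                                    seed=4)
    prof = predicted_profile(gcs)
    expect = {pos: len(car) / 7
              for pos, car in truth.planted_variants["genome"]}
    assert set(prof.expected_fraction) == set(expect)
    for pos, f in expect.items():
        assert prof.expected_fraction[pos] == pytest.approx(f)


def test_unique_copy_count_set_cardinality(rng):
    seqs = [random_seq(rng, 100) for _ in range(4)]
    gcs = GeneCopySet("g", seqs + [seqs[1]])  # 5 copies, one duplicate pair
    assert unique_copy_count(gcs) == 4
    assert unique_copy_count(GeneCopySet("g", [seqs[0].lower(),
                                               seqs[0]])) == 1


def profile_with(fractions, L=100, n_reads=400):
    vf = np.zeros(L)
    for pos, f in fractions.items():
        vf[pos - 1] = f
    return SubstitutionProfile(reference_id="r", reference="A" * L,
                               n_reads=n_reads,
                               depth=np.full(L, n_reads, dtype=np.int64),
                               variant_fraction=vf,
                               deletion_fraction=np.zeros(L),
                               insertion_fraction=np.zeros(L))


def test_zeta_w_zero_for_identical_replicates():
    profs = [profile_with({10: 0.5}), profile_with({10: 0.5})]
    cs = [calls({10: 0.5}), calls({10: 0.5})]
    assert sample_zeta_w(profs, cs) == 0.0


def test_zeta_w_two_point_closed_form():
    profs = [profile_with({10: 0.50}), profile_with({10: 0.52})]
    cs = [calls({10: 0.50}), calls({10: 0.52})]
    # |0.50 - 0.52| / sqrt(2) = 0.01414 -> 1.414%
    assert sample_zeta_w(profs, cs) == pytest.approx(100 * 0.02 / np.sqrt(2))


def test_zeta_w_requires_replicates():
    with pytest.raises(ValueError):
        sample_zeta_w([profile_with({10: 0.5})], [calls({10: 0.5})])


def test_cohort_threshold_is_mean_plus_three_sd():
    replicates = {
        "s1": ([profile_with({5: 0.50}), profile_with({5: 0.52})],
               [calls({5: 0.50}), calls({5: 0.52})]),
        "s2": ([profile_with({7: 0.30}), profile_with({7: 0.30})],
               [calls({7: 0.30}), calls({7: 0.30})]),
    }
    est = estimate_measurement_error(replicates)
    vals = np.array(list(est.per_sample.values()))
    assert est.mean == pytest.approx(vals.mean())
    assert est.difference_threshold == pytest.approx(
        vals.mean() + 3 * vals.std(ddof=1))
    assert est.difference_threshold >= est.mean


def test_profiles_differ_threshold_and_symmetry():
    a = calls({10: 0.50})
    b = calls({10: 0.60})
    c = calls({10: 0.55})
    assert profiles_differ(a, b, 6.58)
    assert not profiles_differ(a, c, 6.58)
    assert not profiles_differ(a, calls({10: 0.50}), 6.58)
    # absent locus counts as fraction zero
    assert profiles_differ(a, calls({}), 6.58)
    for x, y in itertools.combinations([a, b, c], 2):
        assert profiles_differ(x, y, 6.58) == profiles_differ(y, x, 6.58)


def test_unique_profiles_identical_and_zero_snp_isolates_collapse():
    group = {f"i{k}": calls({10: 0.50}) for k in range(5)}
    n, assign = count_unique_profiles(group)
    assert n == 1 and set(assign.values()) == {"i0"}
    group = {f"i{k}": calls({}) for k in range(4)}
    n, _ = count_unique_profiles(group)
    assert n == 1


def test_unique_profiles_match_exhaustive_grouping_oracle():
    """Two well-separated groups; greedy equals brute-force partitioning."""
    group = {
        "a1": calls({10: 0.14}), "a2": calls({10: 0.15}),
        "a3": calls({10: 0.16}),
        "b1": calls({10: 0.85}), "b2": calls({10: 0.86}),
    }
    n, assign = count_unique_profiles(group, threshold_percent=6.58)
    assert n == 2
    assert assign["a2"] == "a1" and assign["b2"] == "b1"
    # brute force: minimal number of representatives such that every
    # isolate is within-threshold of its representative (greedy order)
    ids = sorted(group)
    best = None
    for size in range(1, len(ids) + 1):
        for reps in itertools.combinations(ids, size):
            if all(any(not profiles_differ(group[i], group[r], 6.58)
                       for r in reps) for i in ids):
                best = size
                break
        if best:
            break
    assert n == best


def test_qc_failed_isolates_excluded():
    group = {"ok": calls({10: 0.5}),
             "bad": calls({10: 0.9}, qc=QC_FAIL_LOW_DEPTH)}
    n, assign = count_unique_profiles(group)
    assert n == 1 and "bad" not in assign


def test_count_by_otu_totals():
    otus = {"otu1": {"a": calls({10: 0.14}), "b": calls({10: 0.85})},
            "otu2": {"c": calls({5: 0.3})}}
    total, assignments = count_unique_profiles_by_otu(otus)
    assert total == 3
    assert set(assignments) == {"otu1", "otu2"}


def test_position_mapping_projects_calls_onto_centroid(rng):
    centroid = random_seq(rng, 200)
    # isolate reference: centroid with a 3-base deletion at 50..52
    ref = centroid[:50] + centroid[53:]
    mapping = map_positions(ref, centroid)
    assert mapping[50] == 50
    assert mapping[51] == 54  # shifted past the deleted block
    cs = calls({51: 0.4})
    projected = project_calls(cs, ref, centroid)
    assert projected.snp_fractions == {54: 0.4}
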