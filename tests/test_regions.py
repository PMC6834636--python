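"""Primer search, amplicon extraction, curation, column entropy."""

import numpy as np
import pytest

from rrnphase.alignment import reverse_complement
from rrnphase.regions import (AmpliconRecord, PrimerPair,
                              column_entropy_profile, curate_amplicons,
                              extract_amplicon, primer_mismatch_scan)

from conftest import random_seq

F = "AGAGTTTGATCCTGGCTCAG"
R_SITE = "AAGTCGTAACAAGGTAACCG"  # site on the template strand
R = reverse_complement(R_SITE)  # primer as published


def make_pair(max_mm=3, label="V"):
    return PrimerPair(label, F, R, max_mismatches=max_mm)


def test_exact_primers_trimmed_core():
    core = "GGATCCGGATCC"
    seq = "AA" + F + core + R_SITE + "TT"
    rec = extract_amplicon(seq, make_pair())
    assert rec is not None
    assert rec.sequence == core
    assert rec.length == len(core)


def test_three_mismatches_tolerated_four_rejected(rng):
    core = random_seq(rng, 120)
    site = list(F)
    for k in (2, 7, 13):  # 3 mismatches in the forward site
        site[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[k]]
    seq3 = "".join(site) + core + R_SITE
    rec = extract_amplicon(seq3, make_pair(max_mm=3))
    assert rec is not None and rec.sequence == core
    site[17] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[17]]
    seq4 = "".join(site) + core + R_SITE
    assert extract_amplicon(seq4, make_pair(max_mm=3)) is None


def test_reverse_complemented_template_found(rng):
    core = random_seq(rng, 200)
    seq = F + core + R_SITE
    rec = extract_amplicon(reverse_complement(seq), make_pair())
    assert rec is not None and rec.sequence == core


def test_degenerate_primer_positions_match_any_compatible_base():
    primer = PrimerPair("V", "ACGTN", "AAAAA", max_mismatches=0)
    for b in "ACGT":
        seq = "ACGT" + b + "GGCCGGCC" + "TTTTT"
        rec = extract_amplicon(seq, primer)
        assert rec is not None and rec.sequence == "GGCCGGCC"


def test_too_short_sequence_rejected():
    assert extract_amplicon("ACGT", make_pair()) is None


def test_primer_scan_equals_sliding_window_oracle(rng):
    """Hit positions identical to a brute-force Hamming scan."""
    iupac = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
             "N": {"A", "C", "G", "T"}, "Y": {"C", "T"}, "R": {"A", "G"},
             "M": {"A", "C"}, "W": {"A", "T"}}
    for _ in range(30):
        n = int(rng.integers(50, 400))
        template = random_seq(rng, n)
        primer = "".join(rng.choice(list(iupac), 12))
        got = primer_mismatch_scan(template, primer)
        expect = [sum(template[o + i] not in iupac[p]
                      for i, p in enumerate(primer))
                  for o in range(n - 12 + 1)]
        assert got.tolist() == expect


def test_planted_primers_recovered_at_known_offsets(rng):
    """100 random sequences with primers planted at known offsets."""
    pair = make_pair()
    for _ in range(100):
        off_f = int(rng.integers(0, 200))
        core_len = int(rng.integers(50, 700))
        seq = (random_seq(rng, off_f) + F + random_seq(rng, core_len)
               + R_SITE + random_seq(rng, int(rng.integers(0, 150))))
        rec = extract_amplicon(seq, pair)
        assert rec is not None
        assert rec.sequence == seq[off_f + len(F):off_f + len(F) + core_len]


def rec(sid, region, seq):
    return AmpliconRecord(source_id=sid, region_label=region, sequence=seq)


def test_curation_removes_length_outlier(rng):
    records = {"V": [rec(f"s{i}", "V", random_seq(rng, 250))
                     for i in range(20)]
               + [rec("s_long", "V", random_seq(rng, 400))]}
    out = curate_amplicons(records)
    assert {r.source_id for r in out["V"]} == {f"s{i}" for i in range(20)}


def test_curation_keeps_uniform_input_unchanged(rng):
    seqs = [random_seq(rng, 100) for _ in range(5)]
    records = {"V": [rec(f"s{i}", "V", s) for i, s in enumerate(seqs)],
               "FULL": [rec(f"s{i}", "FULL", s + s)
                        for i, s in enumerate(seqs)]}
    out = curate_amplicons(records)
    assert [r.sequence for r in out["V"]] == seqs


def test_curation_drops_failed_sources_and_ns(rng):
    a = random_seq(rng, 100)
    records = {
        "V": [rec("s0", "V", a), rec("s1", "V", a), rec("s2", "V", a),
              rec("sN", "V", a[:50] + "N" + a[51:])],
        "FULL": [rec("s0", "FULL", a), rec("s1", "FULL", a),
                 rec("sN", "FULL", a)],  # s2 failed FULL extraction
    }
    out = curate_amplicons(records)
    # sN's V record contains an N; its FULL record is clean and survives
    assert {r.source_id for r in out["V"]} == {"s0", "s1"}
    assert {r.source_id for r in out["FULL"]} == {"s0", "s1", "sN"}
    # s2 extracted for V only, so it is removed everywhere
    assert all("s2" != r.source_id for recs in out.values() for r in recs)


def test_curation_matches_direct_mean_sd_oracle(rng):
    for _ in range(10):
        lengths = rng.integers(80, 140, size=25)
        seqs = [random_seq(rng, int(n)) for n in lengths]
        records = {"V": [rec(f"s{i}", "V", s) for i, s in enumerate(seqs)]}
        out = curate_amplicons(records)
        mean, sd = lengths.mean(), lengths.std(ddof=1)
        expect = {f"s{i}" for i, n in enumerate(lengths)
                  if abs(n - mean) <= 2 * sd}
        assert {r.source_id for r in out["V"]} == expect


def test_curation_empty_input():
    assert curate_amplicons({}) == {}
    assert curate_amplicons({"V": []}) == {"V": []}


def test_entropy_monomorphic_and_two_state(rng):
    ref = random_seq(rng, 60)
    prof = column_entropy_profile([ref] * 8, ref)
    assert np.nanmax(prof.entropy) == 0.0
    # 50/50 A/C at one position -> exactly 1 bit
    pos = 30
    alt = "C" if ref[pos] != "C" else "A"
    other = ref[:pos] + alt + ref[pos + 1:]
    prof = column_entropy_profile([ref] * 4 + [other] * 4, ref)
    assert prof.entropy[pos] == pytest.approx(1.0)
    assert 0 <= np.nanmin(prof.entropy) and np.nanmax(prof.entropy) <= 2.0


def test_entropy_matches_closed_form_oracle(rng):
    import math
    ref = random_seq(rng, 150)
    variants = []
    for _ in range(12):
        variants.append("".join(
            rng.choice(list("ACGT")) if rng.random() < 0.05 else b
            for b in ref))
    prof = column_entropy_profile(variants, ref)
    for p in range(len(ref)):
        col = [v[p] for v in variants]
        H = 0.0
        for b in "ACGT":
            f = col.count(b) / len(col)
            if f > 0:
                H -= f * math.log2(f)
        assert prof.entropy[p] == pytest.approx(H)


def test_entropy_uncovered_positions_missing(rng):
    ref = random_seq(rng, 100)
    prof = column_entropy_profile([ref[40:60]], ref)
    assert np.isnan(prof.entropy[0]) and np.isnan(prof.entropy[-1])
    assert not np.isnan(prof.entropy[45])
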