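"""Predicted copy-variant profiles, replicate error, and strain comparison.

A genome carries C near-identical 16S gene copies; aligning all copies
to a designated reference copy predicts the substitution profile an
ideal sequencing experiment would observe: at each reference position
the expected variant fraction is k/C, where k copies carry a
non-reference base.  Observed SNP profiles from different isolates of
the same 99%-identity cluster are compared locus by locus; two isolates
are called different when any locus differs by more than a threshold
derived from replicate-to-replicate measurement error (mean + 3 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (OP_DEL, OP_INS, OP_SUB, PROFILE_SCORING,
                        ReadAlignment, ScoringScheme, glocal_align)
from .profiles import SubstitutionProfile
from .snp import QC_PASS, SNPCallSet


@dataclass
class GeneCopySet:
    """All intragenomic 16S copies of one genome, one designated reference."""

    genome_id: str
    copies: list[str]
    reference_copy_index: int = 0

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError("a gene copy set needs at least one copy")
        if not 0 <= self.reference_copy_index < len(self.copies):
            raise ValueError("reference copy index out of range")

    @property
    def copy_count(self) -> int:
        return len(self.copies)

    @property
    def reference_copy(self) -> str:
        return self.copies[self.reference_copy_index]


@dataclass
class PredictedProfile:
    """Expected variant fractions k/C on the reference copy's coordinates."""

    genome_id: str
    copy_count: int
    expected_fraction: dict[int, float]  # 1-based position -> k/C

    def to_frame(self) -> pd.DataFrame:
        pos = sorted(self.expected_fraction)
        return pd.DataFrame({
            "genome_id": self.genome_id,
            "pos": pos,
            "expected_fraction": [self.expected_fraction[p] for p in pos],
        })


def predicted_profile(copies: GeneCopySet,
                      scoring: ScoringScheme = PROFILE_SCORING
                      ) -> PredictedProfile:
    """Predict the substitution profile implied by a genome's gene copies.

    Every copy is pairwise-aligned to the designated reference copy; at
    each reference position the expected fraction is (copies carrying a
    substituted base) / C.  Copy-level deletions contribute no base,
    consistent with substitution-only profiling, and insertions
    relative to the reference copy are not represented.
    """
    ref = copies.reference_copy
    C = copies.copy_count
    sub_counts = np.zeros(len(ref), dtype=np.int64)
    for idx, copy in enumerate(copies.copies):
        if idx == copies.reference_copy_index:
            continue
        aln = glocal_align(copy, ref, scoring)
        subs = aln.ref_pos[aln.op_codes == OP_SUB]
        sub_counts[subs - 1] += 1
    variant = np.flatnonzero(sub_counts)
    return PredictedProfile(
        genome_id=copies.genome_id, copy_count=C,
        expected_fraction={int(p) + 1: sub_counts[p] / C for p in variant})


def unique_copy_count(copies: GeneCopySet) -> int:
    """Number of distinct sequences among a genome's gene copies."""
    return len({c.upper() for c in copies.copies})


@dataclass
class ReplicateErrorEstimate:
    """Cohort summary of replicate-derived SNP measurement error (zeta_w)."""

    per_sample: dict[str, float]  # sample id -> zeta_w in percent
    median: float
    mean: float
    sd: float

    @property
    def difference_threshold(self) -> float:
        """Percent difference regarded as real: mean + 3 SD."""
        return self.mean + 3.0 * self.sd


def sample_zeta_w(profiles: Sequence[SubstitutionProfile],
                  call_sets: Sequence[SNPCallSet]) -> float:
    """Within-sample SNP measurement error for one isolate, in percent.

    For every locus called as a SNP in any replicate, the sample
    standard deviation (ddof=1; for two replicates |x1 - x2|/sqrt(2))
    of the variant fractions across replicates is computed from the
    replicate profiles; zeta_w is the mean of the per-locus SDs.
    Isolates whose replicates share no SNP locus get zeta_w = 0.
    """
    if len(profiles) < 2:
        raise ValueError("zeta_w needs at least two technical replicates")
    if len(profiles) != len(call_sets):
        raise ValueError("one call set per replicate profile required")
    loci = sorted({p for cs in call_sets for p in cs.snp_fractions})
    if not loci:
        return 0.0
    per_locus = []
    for pos in loci:
        vals = []
        for prof in profiles:
            if pos <= len(prof.variant_fraction) and prof.depth[pos - 1] > 0:
                vals.append(prof.variant_fraction[pos - 1])
        if len(vals) >= 2:
            per_locus.append(np.std(vals, ddof=1))
    if not per_locus:
        return 0.0
    return 100.0 * float(np.mean(per_locus))


def estimate_measurement_error(
    replicates: Mapping[str, tuple[Sequence[SubstitutionProfile],
                                   Sequence[SNPCallSet]]]
) -> ReplicateErrorEstimate:
    """Cohort zeta_w summary over isolates with replicate sequencing.

    ``replicates`` maps sample id to that sample's replicate profiles
    and call sets.  Returns per-sample zeta_w plus cohort median, mean,
    SD and the derived difference threshold (mean + 3 SD, percent).
    """
    per_sample = {sid: sample_zeta_w(profs, calls)
                  for sid, (profs, calls) in replicates.items()}
    if not per_sample:
        raise ValueError("no samples with replicates")
    vals = np.array(list(per_sample.values()))
    return ReplicateErrorEstimate(per_sample=per_sample,
                                  median=float(np.median(vals)),
                                  mean=float(np.mean(vals)),
                                  sd=float(np.std(vals, ddof=1))
                                  if vals.size > 1 else 0.0)


def map_positions(ref_seq: str, centroid_seq: str,
                  scoring: ScoringScheme = PROFILE_SCORING) -> dict[int, int]:
    """Map 1-based positions on ``ref_seq`` onto ``centroid_seq``.

    Positions that align to a gap in the centroid are dropped.  Used to
    put SNP loci from isolates phased against their own internal
    references onto the shared coordinates of their OTU centroid.
    """
    aln = glocal_align(ref_seq, centroid_seq, scoring)
    mapping: dict[int, int] = {}
    read_pos = 0
    for code, cpos in zip(aln.op_codes, aln.ref_pos):
        if code == OP_DEL:
            continue
        read_pos += 1
        if code != OP_INS:
            mapping[read_pos] = int(cpos)
    return mapping


def project_calls(calls: SNPCallSet, ref_seq: str, centroid_seq: str,
                  scoring: ScoringScheme = PROFILE_SCORING) -> SNPCallSet:
    """Re-express a call set's SNP loci in OTU-centroid coordinates."""
    mapping = map_positions(ref_seq, centroid_seq, scoring)
    projected = {mapping[p]: f for p, f in calls.snp_fractions.items()
                 if p in mapping}
    return SNPCallSet(reference_id=calls.reference_id,
                      qc_status=calls.qc_status, thresholds=calls.thresholds,
                      snp_fractions=projected, n_reads=calls.n_reads,
                      n_positions=calls.n_positions,
                      n_candidates=calls.n_candidates, cutoff=calls.cutoff)


def profiles_differ(a: SNPCallSet, b: SNPCallSet,
                    threshold_percent: float = 6.58) -> bool:
    """Whether two SNP profiles represent distinguishable strains.

    True when the variant fraction at one or more loci (union of both
    SNP sets; a locus absent from one profile counts as fraction 0)
    differs by more than ``threshold_percent`` percentage points.  The
    relation is symmetric but not transitive.
    """
    loci = set(a.snp_fractions) | set(b.snp_fractions)
    for pos in loci:
        fa = a.snp_fractions.get(pos, 0.0)
        fb = b.snp_fractions.get(pos, 0.0)
        if abs(fa - fb) * 100.0 > threshold_percent:
            return True
    return False


def count_unique_profiles(calls_by_isolate: Mapping[str, SNPCallSet],
                          threshold_percent: float = 6.58
                          ) -> tuple[int, dict[str, str]]:
    """Greedy grouping of isolates (one OTU) into unique SNP profiles.

    Isolates are scanned in sorted-id order; each joins the first
    existing representative it does not differ from, else founds a new
    profile.  Deterministic ordering matters because the pairwise
    "differ" relation is not transitive.  Returns the number of unique
    profiles and the isolate -> representative assignment.  Only
    QC-passing call sets participate.
    """
    reps: list[tuple[str, SNPCallSet]] = []
    assignment: dict[str, str] = {}
    for iso_id in sorted(calls_by_isolate):
        cs = calls_by_isolate[iso_id]
        if cs.qc_status != QC_PASS:
            continue
        for rep_id, rep_cs in reps:
            if not profiles_differ(cs, rep_cs, threshold_percent):
                assignment[iso_id] = rep_id
                break
        else:
            reps.append((iso_id, cs))
            assignment[iso_id] = iso_id
    return len(reps), assignment


def count_unique_profiles_by_otu(
    calls_by_otu: Mapping[str, Mapping[str, SNPCallSet]],
    threshold_percent: float = 6.58,
) -> tuple[int, dict[str, dict[str, str]]]:
    """Unique-profile counting per OTU and in total."""
    total = 0
    assignments: dict[str, dict[str, str]] = {}
    for otu_id in sorted(calls_by_otu):
        n, assign = count_unique_profiles(calls_by_otu[otu_id],
                                          threshold_percent)
        total += n
        assignments[otu_id] = assign
    return total, assignments
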