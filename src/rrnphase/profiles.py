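"""Per-position error tallies and nucleotide substitution profiles.

Reads aligned to a single reference gene are reduced to per-position
counts (depth, base counts, deletions, insertions) and then to a
substitution profile: the fraction of spanning reads that carry a
non-reference base at each position.  Insertion and deletion errors are
tallied for diagnostics but ignored by the substitution profile, which
is the signature used for intragenomic SNP phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import (OP_DEL, OP_INS, OP_MATCH, OP_SUB, ReadAlignment,
                        encode)


@dataclass
class PositionTallies:
    """Per-position event counts for one reference gene.

    ``base_counts[p-1, b]`` counts reads with base ``b`` (A,C,G,T order)
    aligned to reference position ``p``; insertions are anchored to the
    preceding reference position.  At every position
    ``base_counts.sum() + deletion_count == depth`` (reads spanning the
    position).
    """

    reference_id: str
    reference: str
    depth: np.ndarray  # int64 (L,)
    base_counts: np.ndarray  # int64 (L, 4)
    deletion_count: np.ndarray  # int64 (L,)
    insertion_count: np.ndarray  # int64 (L,) inserted bases anchored left
    n_reads: int = 0

    def to_frame(self) -> pd.DataFrame:
        L = len(self.reference)
        return pd.DataFrame({
            "ref_id": self.reference_id,
            "pos": np.arange(1, L + 1),
            "depth": self.depth,
            "A": self.base_counts[:, 0],
            "C": self.base_counts[:, 1],
            "G": self.base_counts[:, 2],
            "T": self.base_counts[:, 3],
            "del": self.deletion_count,
            "ins": self.insertion_count,
        })


@dataclass
class SubstitutionProfile:
    """Per-position variant fractions (substitutions only) for one gene.

    ``variant_fraction[p-1] = (depth - reference base count - deletions)
    / depth``: deletions are removed from the numerator so that only
    substituted bases count as variant signal.  Positions with zero
    depth carry NaN and are excluded downstream.
    """

    reference_id: str
    reference: str
    n_reads: int
    depth: np.ndarray  # int64 (L,)
    variant_fraction: np.ndarray  # float64 (L,), NaN where depth == 0
    deletion_fraction: np.ndarray  # diagnostics only
    insertion_fraction: np.ndarray  # diagnostics only

    @property
    def positions(self) -> np.ndarray:
        """1-based positions with nonzero depth (aligned positions)."""
        return np.flatnonzero(self.depth > 0) + 1

    def fraction_at(self, position: int) -> float:
        return float(self.variant_fraction[position - 1])

    def to_frame(self) -> pd.DataFrame:
        L = len(self.reference)
        return pd.DataFrame({
            "ref_id": self.reference_id,
            "pos": np.arange(1, L + 1),
            "depth": self.depth,
            "variant_fraction": self.variant_fraction,
            "deletion_fraction": self.deletion_fraction,
            "insertion_fraction": self.insertion_fraction,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference: str = "",
                   n_reads: int = 0) -> "SubstitutionProfile":
        frame = frame.sort_values("pos")
        L = int(frame["pos"].max())
        depth = np.zeros(L, dtype=np.int64)
        vf = np.full(L, np.nan)
        df = np.zeros(L)
        inf = np.zeros(L)
        idx = frame["pos"].to_numpy() - 1
        depth[idx] = frame["depth"].to_numpy()
        vf[idx] = frame["variant_fraction"].to_numpy()
        if "deletion_fraction" in frame:
            df[idx] = frame["deletion_fraction"].to_numpy()
        if "insertion_fraction" in frame:
            inf[idx] = frame["insertion_fraction"].to_numpy()
        return cls(reference_id=str(frame["ref_id"].iloc[0]),
                   reference=reference, n_reads=n_reads, depth=depth,
                   variant_fraction=vf, deletion_fraction=df,
                   insertion_fraction=inf)


def tally_positions(alignments: Iterable[ReadAlignment],
                    reference: str,
                    reference_id: str = "ref") -> PositionTallies:
    """Accumulate per-position base/deletion/insertion counts.

    Depth at a position counts reads whose alignment spans it (from the
    first to the last reference base the read consumes); spanning reads
    contribute either a base or a deletion, so base counts plus
    deletions equal depth everywhere.
    """
    L = len(reference)
    span_edges = np.zeros(L + 1, dtype=np.int64)
    base_counts = np.zeros((L, 4), dtype=np.int64)
    deletions = np.zeros(L, dtype=np.int64)
    insertions = np.zeros(L, dtype=np.int64)
    n_reads = 0
    for aln in alignments:
        n_reads += 1
        lo, hi = aln.span()
        if hi < lo:
            continue
        span_edges[lo - 1] += 1
        span_edges[hi] -= 1
        codes, pos, base = aln.op_codes, aln.ref_pos, aln.read_base
        aligned = (codes == OP_MATCH) | (codes == OP_SUB)
        good = aligned & (base >= 0) & (base < 4)
        np.add.at(base_counts, (pos[good] - 1, base[good].astype(np.int64)), 1)
        np.add.at(deletions, pos[codes == OP_DEL] - 1, 1)
        ins_pos = pos[codes == OP_INS]
        ins_pos = ins_pos[ins_pos >= 1]  # drop insertions before ref start
        np.add.at(insertions, ins_pos - 1, 1)
    depth = np.cumsum(span_edges[:-1])
    return PositionTallies(reference_id=reference_id, reference=reference,
                           depth=depth, base_counts=base_counts,
                           deletion_count=deletions,
                           insertion_count=insertions, n_reads=n_reads)


def substitution_profile(tallies: PositionTallies) -> SubstitutionProfile:
    """Reduce tallies to per-position variant fractions.

    Only substituted bases count: ``(depth - ref base - deletions) /
    depth``.  Indel fractions are carried alongside for diagnostics.
    """
    ref_codes = encode(tallies.reference)
    L = len(tallies.reference)
    depth = tallies.depth.astype(np.float64)
    ref_count = np.zeros(L, dtype=np.int64)
    ok = ref_codes < 4
    ref_count[ok] = tallies.base_counts[np.arange(L)[ok], ref_codes[ok]]
    with np.errstate(invalid="ignore", divide="ignore"):
        vf = (tallies.depth - ref_count - tallies.deletion_count) / depth
        df = tallies.deletion_count / depth
        inf = tallies.insertion_count / depth
    vf[tallies.depth == 0] = np.nan
    df[tallies.depth == 0] = 0.0
    inf[tallies.depth == 0] = 0.0
    return SubstitutionProfile(reference_id=tallies.reference_id,
                               reference=tallies.reference,
                               n_reads=tallies.n_reads,
                               depth=tallies.depth,
                               variant_fraction=vf,
                               deletion_fraction=df,
                               insertion_fraction=inf)


def homopolymer_runs(reference: str) -> np.ndarray:
    """Label every position with the length of its maximal single-base run.

    ``"AAGT" -> [2, 2, 1, 1]``.  Used to relate deletion errors to the
    homopolymer context that produces them in long-read consensus data.
    """
    if not reference:
        return np.zeros(0, dtype=np.int64)
    codes = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8)
    boundaries = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(codes)]))
    out = np.empty(len(codes), dtype=np.int64)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def deletion_rate_by_runlength(tallies: PositionTallies,
                               run_lengths: np.ndarray | None = None
                               ) -> pd.DataFrame:
    """Mean per-position deletion fraction grouped by homopolymer run length.

    Positions with zero depth are excluded; empty run-length groups are
    omitted.  Returns a frame with columns ``run_length``,
    ``mean_deletion_fraction``, ``n_positions``.
    """
    if run_lengths is None:
        run_lengths = homopolymer_runs(tallies.reference)
    if len(run_lengths) != len(tallies.reference):
        raise ValueError("run lengths do not match the reference length")
    covered = tallies.depth > 0
    frac = np.zeros(len(tallies.reference))
    frac[covered] = (tallies.deletion_count[covered]
                     / tallies.depth[covered])
    frame = pd.DataFrame({"run_length": run_lengths[covered],
                          "deletion_fraction": frac[covered]})
    out = (frame.groupby("run_length")["deletion_fraction"]
           .agg(mean_deletion_fraction="mean", n_positions="size")
           .reset_index())
    return out
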