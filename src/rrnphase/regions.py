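"""In-silico amplicon extraction, curation, and column entropy.

Variable sub-regions of the 16S gene (V1-V9 and internal windows) are
demarcated by primer pairs.  Amplicons are cut in silico by locating
primer sites with a fixed-offset Hamming scan under IUPAC expansion
(no indels inside primer sites: fixed-length sites keep downstream
filtering testable), curated with the same three filters applied to
reference databases, and summarised by per-position Shannon entropy on
the coordinates of a single reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (OP_MATCH, OP_SUB, PROFILE_SCORING, glocal_align,
                        reverse_complement)

_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}


def _bitmask(seq: str) -> np.ndarray:
    out = np.zeros(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _IUPAC_BITS.get(ch, 0)
    return out


@dataclass(frozen=True)
class PrimerPair:
    """A published primer pair demarcating one variable region.

    ``reverse`` is stored as published, i.e. in reverse-complement
    orientation relative to the template strand.
    """

    region_label: str
    forward: str
    reverse: str
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class AmpliconRecord:
    """One in-silico amplicon with primers removed."""

    source_id: str
    region_label: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def primer_mismatch_scan(template: str, primer: str) -> np.ndarray:
    """Mismatch count of the primer at every template offset (Hamming).

    A template base matches a (possibly degenerate) primer character
    when its IUPAC set is contained in the primer character's set.
    """
    t = _bitmask(template)
    p = _bitmask(primer)
    k = len(p)
    if len(t) < k:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(t, k)
    ok = (windows & p) == windows
    ok &= windows != 0
    return (k - ok.sum(axis=1)).astype(np.int64)


def _best_site(mismatches: np.ndarray, max_mm: int,
               prefer_left: bool, min_offset: int = 0) -> int | None:
    """Offset of the best primer site, or None.  Ties: leftmost when
    ``prefer_left`` else rightmost (maximal amplicon convention)."""
    if mismatches.size == 0:
        return None
    mm = mismatches[min_offset:]
    if mm.size == 0:
        return None
    best = mm.min()
    if best > max_mm:
        return None
    hits = np.flatnonzero(mm == best) + min_offset
    return int(hits[0] if prefer_left else hits[-1])


def extract_amplicon(seq: str, primers: PrimerPair,
                     source_id: str = "seq") -> AmpliconRecord | None:
    """Cut the subsequence strictly between the best primer sites.

    Both primer sequences are removed.  Primer sites are located by the
    minimum-Hamming offset within ``max_mismatches`` (forward primer as
    given, reverse primer reverse-complemented onto the template); when
    no orientation of the template yields both sites, ``None``.
    Sequences shorter than the combined primer length are rejected.
    """
    flen, rlen = len(primers.forward), len(primers.reverse)
    if len(seq) < flen + rlen:
        return None
    rc_reverse = reverse_complement(primers.reverse)
    for template in (seq, reverse_complement(seq)):
        f_off = _best_site(primer_mismatch_scan(template, primers.forward),
                           primers.max_mismatches, prefer_left=True)
        if f_off is None:
            continue
        start = f_off + flen
        r_scan = primer_mismatch_scan(template, rc_reverse)
        r_off = _best_site(r_scan, primers.max_mismatches,
                           prefer_left=False, min_offset=start)
        if r_off is None:
            continue
        return AmpliconRecord(source_id=source_id,
                              region_label=primers.region_label,
                              sequence=template[start:r_off])
    return None


def read_primer_table(path) -> list[PrimerPair]:
    """Primer TSV: region_label, forward, reverse[, max_mismatches]."""
    frame = pd.read_csv(path, sep="\t")
    out = []
    for _, row in frame.iterrows():
        out.append(PrimerPair(region_label=str(row["region_label"]),
                              forward=str(row["forward"]),
                              reverse=str(row["reverse"]),
                              max_mismatches=int(row.get("max_mismatches", 3))))
    return out


def curate_amplicons(records_by_region: Mapping[str, Sequence[AmpliconRecord]]
                     ) -> dict[str, list[AmpliconRecord]]:
    """Apply the three curation filters to per-region amplicon sets.

    A record survives iff (1) its source sequence yielded an amplicon
    for *every* region attempted (full-length included), (2) its
    sequence contains no 'N', and (3) its length lies within 2 sample
    SDs of the per-region mean.  Length statistics are computed after
    filters (1) and (2), per region.
    """
    if not records_by_region:
        return {}
    sources_per_region = [{r.source_id for r in recs}
                          for recs in records_by_region.values()]
    complete = set.intersection(*sources_per_region) if sources_per_region \
        else set()
    out: dict[str, list[AmpliconRecord]] = {}
    for region, recs in records_by_region.items():
        kept = [r for r in recs
                if r.source_id in complete and "N" not in r.sequence.upper()]
        if not kept:
            out[region] = []
            continue
        lengths = np.array([r.length for r in kept], dtype=float)
        mean = lengths.mean()
        sd = lengths.std(ddof=1) if len(kept) > 1 else 0.0
        out[region] = [r for r, ln in zip(kept, lengths)
                       if abs(ln - mean) <= 2.0 * sd]
    return out


@dataclass
class EntropyProfile:
    """Per-position Shannon entropy (bits) on reference coordinates."""

    reference_id: str
    entropy: np.ndarray  # float64, NaN where no coverage
    coverage: np.ndarray  # int64 bases observed per position

    @property
    def values(self) -> list[tuple[int, float]]:
        return [(i + 1, float(h)) for i, h in enumerate(self.entropy)
                if not np.isnan(h)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ref_id": self.reference_id,
                             "pos": np.arange(1, len(self.entropy) + 1),
                             "entropy": self.entropy,
                             "coverage": self.coverage})


def column_entropy_profile(sequences: Iterable[str], reference: str,
                           reference_id: str = "ref") -> EntropyProfile:
    """Shannon entropy of base frequencies at each reference position.

    Each sequence is pairwise-aligned to the reference; matched and
    substituted bases contribute to their reference column, positions
    deleted in a query contribute nothing, and insertions relative to
    the reference are not represented.  Positions never covered report
    NaN.
    """
    from .alignment import encode

    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    for seq in sequences:
        aln = glocal_align(seq, reference, PROFILE_SCORING)
        aligned = (aln.op_codes == OP_MATCH) | (aln.op_codes == OP_SUB)
        good = aligned & (aln.read_base >= 0) & (aln.read_base < 4)
        np.add.at(counts, (aln.ref_pos[good] - 1,
                           aln.read_base[good].astype(np.int64)), 1)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / total[:, None]
        terms = np.where(p > 0, p * np.log2(p), 0.0)
        H = -terms.sum(axis=1)
    H[total == 0] = np.nan
    return EntropyProfile(reference_id=reference_id, entropy=H,
                          coverage=total)
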