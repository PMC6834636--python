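"""Pairwise glocal alignment of amplicon reads against reference genes.

The aligner implements an affine-gap ("Gotoh") dynamic program with a
*glocal* contract: the full read must be aligned, while reference
overhangs on either side are free.  This matches the geometry of a
full-length amplicon read aligned to a 16S gene: the read is a complete
molecule, the reference may extend past it.

Conventions
-----------
* Coordinates are 1-based inclusive on the reference.
* A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the first
  gap base pays the opening penalty).
* "deletion" means a reference base absent from the read; "insertion"
  means read bases absent from the reference, anchored to the preceding
  reference position (anchor 0 for insertions before the first aligned
  reference base).
* Ties are broken deterministically: diagonal (match/substitution) is
  preferred over deletion, which is preferred over insertion; equal
  end-point scores resolve to the leftmost reference column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numba import njit

# op codes shared between the kernel and the tally layer
OP_MATCH = 0
OP_SUB = 1
OP_DEL = 2
OP_INS = 3

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Cross_match-style scoring used for read-to-gene alignment.

    Defaults follow the published analysis where stated (substitution
    penalty -9, minimum alignment score 750 for community data; use 1200
    for isolates) with conventional affine gap penalties where not.
    """

    match: int = 1
    mismatch: int = -9
    gap_open: int = -12
    gap_extend: int = -2
    min_score: int = 750

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


#: scheme used for isolate reads (minimum alignment score 1200)
ISOLATE_SCORING = ScoringScheme(min_score=1200)

#: permissive scheme used when only an identity fraction is needed
IDENTITY_SCORING = ScoringScheme(match=1, mismatch=-2, gap_open=-2,
                                 gap_extend=-1, min_score=-(10 ** 9))

#: substitution-favoring scheme for projecting near-identical sequences
#: onto reference coordinates (gene copies and amplicons differ mostly by
#: substitutions; gaps must not fragment adjacent mismatches)
PROFILE_SCORING = ScoringScheme(match=1, mismatch=-1, gap_open=-4,
                                gap_extend=-2, min_score=-(10 ** 9))


@dataclass
class ReadAlignment:
    """A glocal alignment of one read against one reference."""

    read_id: str
    reference_id: str
    score: int
    strand: str  # '+' or '-'
    op_codes: np.ndarray  # int8, OP_* codes in reference order
    ref_pos: np.ndarray  # int32, 1-based; insertion anchors to preceding pos
    read_base: np.ndarray  # int8 base codes (match/sub/ins), -1 for deletions

    @property
    def ops(self) -> list[tuple[int, str]]:
        """Alignment events as (ref_pos, event) tuples, insertions merged."""
        out: list[tuple[int, str]] = []
        i = 0
        codes, pos, base = self.op_codes, self.ref_pos, self.read_base
        n = len(codes)
        while i < n:
            c = codes[i]
            if c == OP_MATCH:
                out.append((int(pos[i]), "match"))
            elif c == OP_SUB:
                out.append((int(pos[i]), f"substitution({chr(_CODE_BASE[base[i]])})"))
            elif c == OP_DEL:
                out.append((int(pos[i]), "deletion"))
            else:  # merge a run of insertions anchored at the same position
                j = i
                ins = []
                while j < n and codes[j] == OP_INS and pos[j] == pos[i]:
                    ins.append(chr(_CODE_BASE[base[j]]))
                    j += 1
                out.append((int(pos[i]), f"insertion({''.join(ins)})"))
                i = j
                continue
            i += 1
        return out

    @property
    def n_sub(self) -> int:
        return int(np.count_nonzero(self.op_codes == OP_SUB))

    @property
    def n_del(self) -> int:
        return int(np.count_nonzero(self.op_codes == OP_DEL))

    @property
    def n_ins(self) -> int:
        return int(np.count_nonzero(self.op_codes == OP_INS))

    def span(self) -> tuple[int, int]:
        """First and last 1-based reference positions consumed by the read."""
        consumed = self.ref_pos[self.op_codes != OP_INS]
        if consumed.size == 0:
            return (0, -1)
        return int(consumed[0]), int(consumed[-1])


_NEG = -(10 ** 9)


@njit(cache=True)
def _gotoh(q, r, match, mismatch, gap_open, gap_extend, band):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    if band <= 0 or band >= n:
        band = n  # full matrix

    # banded storage: row i covers reference columns [lo[i], hi[i]]
    lo = np.empty(m + 1, dtype=np.int64)
    hi = np.empty(m + 1, dtype=np.int64)
    for i in range(m + 1):
        c = (i * n) // max(m, 1)
        a = c - band
        if a < 1:
            a = 1
        b = c + band
        if b > n:
            b = n
        lo[i] = a
        hi[i] = b
    lo[0] = 0
    hi[0] = n

    width = 0
    for i in range(1, m + 1):
        w = hi[i] - lo[i] + 1
        if w > width:
            width = w

    M = np.full((m + 1, width), _NEG, dtype=np.int64)
    D = np.full((m + 1, width), _NEG, dtype=np.int64)
    I = np.full((m + 1, width), _NEG, dtype=np.int64)
    pM = np.zeros((m + 1, width), dtype=np.int8)
    pD = np.zeros((m + 1, width), dtype=np.int8)
    pI = np.zeros((m + 1, width), dtype=np.int8)

    # virtual column 0: leading insertions (read bases before the reference)
    I0 = np.full(m + 1, _NEG, dtype=np.int64)
    for i in range(1, m + 1):
        I0[i] = gap_open + (i - 1) * gap_extend

    for i in range(1, m + 1):
        li = lo[i]
        lp = lo[i - 1]
        hp = hi[i - 1]
        for j in range(li, hi[i] + 1):
            k = j - li
            # previous-row values at j-1 and j (row 0 is the free start row)
            if i == 1:
                mp_d = 0
                dp_d = _NEG
                ip_d = _NEG
                mp_v = 0
                dp_v = _NEG
                ip_v = _NEG
            else:
                if j - 1 == 0:
                    mp_d = _NEG
                    dp_d = _NEG
                    ip_d = I0[i - 1]
                elif lp <= j - 1 <= hp:
                    mp_d = M[i - 1, j - 1 - lp]
                    dp_d = D[i - 1, j - 1 - lp]
                    ip_d = I[i - 1, j - 1 - lp]
                else:
                    mp_d = _NEG
                    dp_d = _NEG
                    ip_d = _NEG
                if lp <= j <= hp:
                    mp_v = M[i - 1, j - lp]
                    dp_v = D[i - 1, j - lp]
                    ip_v = I[i - 1, j - lp]
                else:
                    mp_v = _NEG
                    dp_v = _NEG
                    ip_v = _NEG

            s = match if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else mismatch

            # M: diagonal step, predecessor priority M > D > I
            best = mp_d
            ptr = 0
            if dp_d > best:
                best = dp_d
                ptr = 1
            if ip_d > best:
                best = ip_d
                ptr = 2
            M[i, k] = best + s if best > _NEG // 2 else _NEG
            pM[i, k] = ptr

            # D: horizontal step from (i, j-1)
            if j - 1 == 0:
                mc = _NEG
                dc = _NEG
                ic = I0[i]
            elif j - 1 >= li:
                mc = M[i, k - 1]
                dc = D[i, k - 1]
                ic = I[i, k - 1]
            else:
                mc = _NEG
                dc = _NEG
                ic = _NEG
            best = mc + gap_open
            ptr = 0
            if dc + gap_extend > best:
                best = dc + gap_extend
                ptr = 1
            if ic + gap_open > best:
                best = ic + gap_open
                ptr = 2
            D[i, k] = best if best > _NEG // 2 else _NEG
            pD[i, k] = ptr

            # I: vertical step from (i-1, j)
            best = mp_v + gap_open
            ptr = 0
            if dp_v + gap_open > best:
                best = dp_v + gap_open
                ptr = 1
            if ip_v + gap_extend > best:
                best = ip_v + gap_extend
                ptr = 2
            I[i, k] = best if best > _NEG // 2 else _NEG
            pI[i, k] = ptr

    # end point: read fully consumed, trailing reference overhang free.
    # The end state consumes the last read base, hence M or I only.
    best = I0[m]
    end_j = 0
    end_state = 2
    for j in range(lo[m], hi[m] + 1):
        k = j - lo[m]
        if M[m, k] > best:
            best = M[m, k]
            end_j = j
            end_state = 0
        if I[m, k] > best:
            best = I[m, k]
            end_j = j
            end_state = 2

    # traceback
    max_ops = m + n + 1
    codes = np.empty(max_ops, dtype=np.int8)
    pos = np.empty(max_ops, dtype=np.int32)
    bases = np.empty(max_ops, dtype=np.int8)
    t = 0
    i = m
    j = end_j
    state = end_state
    while i > 0:
        if state == 0:  # M
            codes[t] = OP_MATCH if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else OP_SUB
            pos[t] = j
            bases[t] = q[i - 1]
            if j == lo[i] and j - 1 > 0 and i > 1:
                state = pM[i, j - lo[i]]
            else:
                state = pM[i, j - lo[i]]
            i -= 1
            j -= 1
        elif state == 1:  # D
            codes[t] = OP_DEL
            pos[t] = j
            bases[t] = -1
            state = pD[i, j - lo[i]]
            j -= 1
        else:  # I
            codes[t] = OP_INS
            pos[t] = j
            bases[t] = q[i - 1]
            if j == 0:
                state = 0 if i == 1 else 2
            else:
                state = pI[i, j - lo[i]]
            i -= 1
        t += 1

    return best, codes[:t][::-1].copy(), pos[:t][::-1].copy(), bases[:t][::-1].copy()


def glocal_align(
    read: str,
    reference: str,
    scoring: ScoringScheme = ScoringScheme(),
    band: int | None = None,
    read_id: str = "read",
    reference_id: str = "ref",
    strand: str = "+",
) -> ReadAlignment:
    """Align the full read against the reference with free reference ends.

    ``band`` restricts the dynamic program to a diagonal band of the
    given half-width, an optimisation valid when the read is a
    near-full-length copy of the reference (the optimum stays inside the
    band); ``None`` computes the full matrix.
    """
    if len(read) == 0:
        raise ValueError("empty read")
    if len(reference) == 0:
        raise ValueError("empty reference")
    score, codes, pos, bases = _gotoh(
        encode(read), encode(reference),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        0 if band is None else int(band),
    )
    return ReadAlignment(read_id=read_id, reference_id=reference_id,
                         score=int(score), strand=strand,
                         op_codes=codes, ref_pos=pos, read_base=bases)


def orient_read(read: str, reference: str,
                scoring: ScoringScheme = ScoringScheme(),
                band: int | None = None) -> tuple[str, str] | None:
    """Return ``(oriented_sequence, strand)`` for the better-scoring strand.

    The read is reverse-complemented when its reverse strand aligns
    better; ``None`` when neither strand reaches ``scoring.min_score``.
    Ties keep the forward strand.
    """
    fwd = glocal_align(read, reference, scoring, band)
    rc = reverse_complement(read)
    rev = glocal_align(rc, reference, scoring, band)
    if fwd.score < scoring.min_score and rev.score < scoring.min_score:
        return None
    if rev.score > fwd.score:
        return rc, "-"
    return read, "+"


def align_read_best_hit(
    read: str,
    references: Sequence[tuple[str, str]],
    scoring: ScoringScheme = ScoringScheme(),
    band: int | None = None,
    read_id: str = "read",
    orient: bool = False,
) -> ReadAlignment | None:
    """Best-hit alignment of one read against a panel of reference genes.

    ``references`` is a sequence of ``(reference_id, sequence)``.  Only
    the single highest-scoring alignment is returned (score ties broken
    by reference input order); ``None`` when the best score falls below
    ``scoring.min_score``.  With ``orient=True`` both strands are tried
    and the better one kept.
    """
    if not references:
        raise ValueError("empty reference set")
    best: ReadAlignment | None = None
    candidates = [(read, "+")]
    if orient:
        candidates.append((reverse_complement(read), "-"))
    for ref_id, ref_seq in references:
        for seq, strand in candidates:
            aln = glocal_align(seq, ref_seq, scoring, band,
                               read_id=read_id, reference_id=ref_id,
                               strand=strand)
            if best is None or aln.score > best.score:
                best = aln
    assert best is not None
    if best.score < scoring.min_score:
        return None
    return best


def global_identity(a: str, b: str,
                    scoring: ScoringScheme = IDENTITY_SCORING) -> float:
    """Global identity = matches / alignment columns, terminal gaps excluded.

    The shorter sequence is aligned in full against the longer; columns
    in the terminal overhang of the longer sequence do not count.
    Identity definitions differ between tools, so the definition used
    for OTU clustering is pinned down here.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sequence")
    if len(a) > len(b):
        a, b = b, a
    aln = glocal_align(a, b, scoring)
    columns = len(aln.op_codes)
    if columns == 0:
        return 0.0
    matches = int(np.count_nonzero(aln.op_codes == OP_MATCH))
    return matches / columns
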