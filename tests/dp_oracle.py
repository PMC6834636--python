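"""Independent full-matrix affine-gap glocal aligner used as a test oracle.

Plain-Python three-state (match / deletion / insertion) dynamic program
with the same contract as the package aligner: full read aligned,
reference end overhangs free, gap of length L costs open + (L-1)*extend,
tie priority diagonal > deletion > insertion, leftmost end column.
Kept deliberately naive and separate from the implementation it checks.
"""

NEG = float("-inf")


def oracle_glocal(read, ref, match, mismatch, gap_open, gap_extend):
    """Return (score, ops) where ops is a list of (ref_pos, kind, read_base).

    kind is one of 'match', 'sub', 'del', 'ins'; ref_pos is 1-based
    (insertions anchored to the preceding reference position).
    """
    m, n = len(read), len(ref)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    pM = [[0] * (n + 1) for _ in range(m + 1)]
    pD = [[0] * (n + 1) for _ in range(m + 1)]
    pI = [[0] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0  # free leading reference overhang / start anywhere
    for i in range(1, m + 1):
        I[i][0] = gap_open + (i - 1) * gap_extend
        pI[i][0] = 0 if i == 1 else 2
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if read[i - 1].upper() == ref[j - 1].upper() and \
                read[i - 1].upper() in "ACGT" else mismatch
            cands = (M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            best, ptr = cands[0], 0
            for k in (1, 2):
                if cands[k] > best:
                    best, ptr = cands[k], k
            M[i][j] = best + s
            pM[i][j] = ptr
            cands = (M[i][j - 1] + gap_open, D[i][j - 1] + gap_extend,
                     I[i][j - 1] + gap_open)
            best, ptr = cands[0], 0
            for k in (1, 2):
                if cands[k] > best:
                    best, ptr = cands[k], k
            D[i][j] = best
            pD[i][j] = ptr
            cands = (M[i - 1][j] + gap_open, D[i - 1][j] + gap_open,
                     I[i - 1][j] + gap_extend)
            best, ptr = cands[0], 0
            for k in (1, 2):
                if cands[k] > best:
                    best, ptr = cands[k], k
            I[i][j] = best
            pI[i][j] = ptr

    # end: last read base consumed by M or I; leftmost column on ties,
    # M preferred over I at the same column
    best, end_j, state = I[m][0], 0, 2
    for j in range(1, n + 1):
        if M[m][j] > best:
            best, end_j, state = M[m][j], j, 0
        if I[m][j] > best:
            best, end_j, state = I[m][j], j, 2

    ops = []
    i, j = m, end_j
    while i > 0:
        if state == 0:
            kind = "match" if read[i - 1].upper() == ref[j - 1].upper() and \
                read[i - 1].upper() in "ACGT" else "sub"
            ops.append((j, kind, read[i - 1]))
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append((j, "del", None))
            state = pD[i][j]
            j -= 1
        else:
            ops.append((j, "ins", read[i - 1]))
            state = pI[i][j]
            i -= 1
    ops.reverse()
    return best, ops


def score_ops(ops, match, mismatch, gap_open, gap_extend):
    """Re-score an operation list under the affine scheme (oracle check)."""
    total = 0.0
    prev = None
    for _, kind, _base in ops:
        if kind == "match":
            total += match
        elif kind == "sub":
            total += mismatch
        elif kind in ("del", "ins"):
            total += gap_extend if prev == kind else gap_open
        prev = kind
    return total
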