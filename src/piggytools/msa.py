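"""Global pairwise alignment and center-star multiple alignment.

Scoring is fixed across the package: match +1, mismatch -1, gap -2,
end gaps penalized (true global alignment).  The multiple alignment is the
classic center-star construction: every sequence is aligned pairwise to
the center sequence (the one maximizing its summed pairwise score; ties go
to the earliest in input order) and the pairwise alignments are merged
under "once a gap, always a gap".  Deterministic given input order.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2
GAP_CHAR = "-"


def nw_score(a: str, b: str) -> int:
    """Needleman-Wunsch global alignment score (score only, vectorized).

    Row recurrence uses the max-plus prefix trick to resolve the
    within-row gap chain: H[i][j] = max over i' <= j of t[i'] - 2*(j - i'),
    where t[j] = max(diag, up).
    """
    if not a:
        return GAP * len(b)
    if not b:
        return GAP * len(a)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    m = len(b)
    jidx = np.arange(m + 1, dtype=np.int64)
    prev = GAP * jidx
    for i, ca in enumerate(a):
        sub = np.where(bv == ord(ca), MATCH, MISMATCH)
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = GAP * (i + 1)
        t[1:] = np.maximum(prev[:-1] + sub, prev[1:] + GAP)
        # close the left-gap chain
        chain = np.maximum.accumulate(t - GAP * jidx) + GAP * jidx
        prev = np.maximum(t, chain)
    return int(prev[-1])


def needleman_wunsch(a: str, b: str) -> tuple[int, str, str]:
    """Global alignment with traceback: returns (score, aligned_a, aligned_b).

    Traceback ties prefer diagonal, then up (gap in ``b``), then left;
    this makes the alignment deterministic.
    """
    n, m = len(a), len(b)
    if n == 0:
        return GAP * m, GAP_CHAR * m, b
    if m == 0:
        return GAP * n, a, GAP_CHAR * n
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    jidx = np.arange(m + 1, dtype=np.int64)
    H[0] = GAP * jidx
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH)
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = GAP * i
        t[1:] = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        chain = np.maximum.accumulate(t - GAP * jidx) + GAP * jidx
        H[i] = np.maximum(t, chain)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + (MATCH if av[i - 1] == bv[j - 1] else MISMATCH):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and h == H[i - 1, j] + GAP:
            out_a.append(a[i - 1])
            out_b.append(GAP_CHAR)
            i -= 1
        else:
            out_a.append(GAP_CHAR)
            out_b.append(b[j - 1])
            j -= 1
    return int(H[n, m]), "".join(reversed(out_a)), "".join(reversed(out_b))


def center_star_align(seqs: list[str]) -> list[str]:
    """Center-star multiple alignment; returns rows in input order."""
    if len(seqs) < 2:
        raise ValueError("center-star alignment needs at least 2 sequences")
    k = len(seqs)
    # choose center: maximal summed pairwise score, ties -> first in order
    sums = [0] * k
    for i in range(k):
        for j in range(i + 1, k):
            s = nw_score(seqs[i], seqs[j])
            sums[i] += s
            sums[j] += s
    center = max(range(k), key=lambda i: (sums[i], -i))

    master = list(seqs[center])  # master alignment of the center sequence
    rows: dict[int, list[str]] = {center: list(seqs[center])}

    for i in range(k):
        if i == center:
            continue
        _, ac, ai = needleman_wunsch("".join(c for c in master if c != GAP_CHAR), seqs[i])
        # map center residues (skipping gaps) to master columns
        res_cols = [ci for ci, ch in enumerate(master) if ch != GAP_CHAR]
        new_row: list[str] = [GAP_CHAR] * len(master)
        res_idx = 0
        inserts: list[tuple[int, str]] = []  # (master column insert-before, base)
        for ca, cb in zip(ac, ai):
            if ca != GAP_CHAR:
                col = res_cols[res_idx]
                if cb != GAP_CHAR:
                    new_row[col] = cb
                res_idx += 1
            else:
                # gap in center: new column, "once a gap always a gap"
                before = res_cols[res_idx] if res_idx < len(res_cols) else len(master)
                inserts.append((before, cb))
        if inserts:
            # materialize new columns right-to-left to keep indices valid
            for before, base in reversed(inserts):
                master.insert(before, GAP_CHAR)
                for r in rows.values():
                    r.insert(before, GAP_CHAR)
                new_row.insert(before, base)
            # master column bookkeeping changed; recompute nothing else
        rows[i] = new_row
    width = len(master)
    out = []
    for i in range(k):
        row = rows[i]
        assert len(row) == width
        out.append("".join(row))
    return out
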