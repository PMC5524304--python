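"""Slow, brute-force reference implementations used to validate the fast paths.

These deliberately take the most literal route — exhaustive enumeration of
candidate intervals, top-down recursion over alignment paths — and share no
algorithmic machinery with the production implementations they check. They are
practical only on tiny inputs.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .cne_scan import ScanParams, conserved_columns
from .io_formats import AlignmentBlock


def brute_scan_spans(block: AlignmentBlock, params: ScanParams) -> list[tuple[int, int]]:
    """All maximal qualifying element spans, by exhaustive interval enumeration.

    An interval [s, e] (inclusive columns) qualifies when its end columns are
    conserved and some seed window — ``seed_length`` consecutive
    reference-base columns with enough conserved columns — has its conserved
    core inside the interval with at most ``max_nonconserved_per_side``
    non-conserved columns between the interval edge and the window on each
    side. Overlapping qualifying intervals are merged.
    """
    c = conserved_columns(block, params)
    n = block.n_columns
    L = params.seed_length
    B = params.max_nonconserved_per_side
    need = math.ceil(params.seed_identity * L)
    ref = block.matrix()[0]
    refbase = ref != ord("-")
    windows = []
    for w0 in range(0, n - L + 1):
        w1 = w0 + L - 1
        if not refbase[w0 : w1 + 1].all():
            continue
        if int(c[w0 : w1 + 1].sum()) < need:
            continue
        cons_cols = [j for j in range(w0, w1 + 1) if c[j]]
        windows.append((w0, w1, cons_cols[0], cons_cols[-1]))
    if not windows:
        return []
    nc = (~c).astype(int)
    cum = np.concatenate([[0], np.cumsum(nc)])

    def qualifies(s, e):
        if not (c[s] and c[e]):
            return False
        for w0, w1, fc, lc in windows:
            if s > fc or e < lc:
                continue
            left = cum[w0] - cum[s] if s < w0 else 0
            right = cum[e + 1] - cum[w1 + 1] if e > w1 else 0
            if left <= B and right <= B:
                return True
        return False

    spans = [(s, e) for s in range(n) for e in range(s, n) if qualifies(s, e)]
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def brute_local_align_score(
    query: str,
    subject: str,
    *,
    match: int = 1,
    mismatch: int = 1,
    gap_open: int = 2,
    gap_extend: int = 2,
) -> int:
    """Optimal local-alignment score by top-down recursion over alignment paths.

    A gap of length k costs gap_open + k * gap_extend. Returns 0 when no
    positive-scoring local alignment exists. Exponential without the memo;
    intended for sequences of length <= ~10.
    """
    q, s = query.upper(), subject.upper()
    n, m = len(q), len(s)

    @lru_cache(maxsize=None)
    def best_suffix(i: int, j: int, state: int) -> float:
        """Best score of any alignment continuation starting at (i, j).

        state: 0 = no open gap, 1 = gap in subject open, 2 = gap in query open.
        The continuation may stop at any time (score 0).
        """
        options = [0.0]
        if i < n and j < m:
            sub = match if (q[i] == s[j] and q[i] in "ACGT") else -mismatch
            options.append(sub + best_suffix(i + 1, j + 1, 0))
        if i < n:
            cost = gap_extend if state == 1 else gap_open + gap_extend
            options.append(-cost + best_suffix(i + 1, j, 1))
        if j < m:
            cost = gap_extend if state == 2 else gap_open + gap_extend
            options.append(-cost + best_suffix(i, j + 1, 2))
        return max(options)

    best = 0.0
    for i in range(n):
        for j in range(m):
            # a positive local alignment must start on a match/mismatch column
            if q[i] == s[j] and q[i] in "ACGT":
                start = match + best_suffix(i + 1, j + 1, 0)
                best = max(best, start)
    best_suffix.cache_clear()
    return int(best)
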