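"""Pairwise local-alignment search for fish-specific conserved elements.

A full Smith-Waterman/Gotoh dynamic program with BLASTN-like scoring
(match +1, mismatch -1, gap of length k costs open + k*extend with
open = extend = 2) aligns a masked query region against both strands of a
subject region. Hits are discovered iteratively: the optimal local alignment
is reported, its query footprint is hard-masked with N (which matches
nothing), and the search repeats until no alignment can still pass the
retention filter. Retained hits must span more than ``min_hit_length``
alignment columns and reach ``min_identity`` identity.

Tie-breaking is deterministic: among equal-scoring alignments the one with the
smaller query start wins, then smaller subject start, then shorter alignment;
the '+' strand wins ties against '-'.

The DP is quadratic in sequence length (no heuristic word seeding), intended
for gene-neighbourhood windows up to a few tens of kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ValidationError
from .io_formats import GenomicInterval, reverse_complement

_CODE = np.full(256, 4, np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

OP_MATCH, OP_GAP_SUBJECT, OP_GAP_QUERY = 0, 1, 2


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (incl. N) -> 4, which never matches."""
    return _CODE[np.frombuffer(seq.encode(), np.uint8)]


@dataclass
class PairwiseParams:
    """BLASTN-style scoring and retention filters for the fish-specific search."""

    match_reward: int = 1
    mismatch_penalty: int = 1  # magnitude; applied as a negative score
    gap_open_cost: int = 2
    gap_extend_cost: int = 2
    min_hit_length: int = 50  # retained hits are strictly longer than this
    min_identity: float = 0.60
    window: int = 800_000
    identity_denominator: str = "columns"  # 'columns' (no gaps) or 'with-gaps'
    min_report_score: int = 11  # iteration floor; below this nothing is retainable

    def __post_init__(self):
        if not (0 < self.min_identity <= 1):
            raise ValidationError("min_identity must be in (0, 1]")
        if min(self.gap_open_cost, self.gap_extend_cost) < 0:
            raise ValidationError("gap costs must be >= 0")
        if self.identity_denominator not in ("columns", "with-gaps"):
            raise ValidationError("identity_denominator must be 'columns' or 'with-gaps'")


@dataclass
class PairwiseHit:
    """One local alignment between query and subject regions."""

    query_interval: GenomicInterval
    subject_interval: GenomicInterval
    score: int
    identity: float
    aligned_columns: int  # total alignment columns, gap columns included
    gapped_columns: int
    matches: int
    strand: str
    ops: np.ndarray = field(repr=False, default=None)


@njit(cache=True)
def _better(s1, a1, b1, l1, s2, a2, b2, l2):
    """Is candidate 1 (score, qstart, sstart, length) preferable to candidate 2?"""
    if s1 != s2:
        return s1 > s2
    if a1 != a2:
        return a1 < a2
    if b1 != b2:
        return b1 < b2
    return l1 < l2


@njit(cache=True)
def _gotoh(q, s, match, mismatch, gopen, gext):
    n, m = q.size, s.size
    NEG = np.int32(-(10**9) // 2)
    shape = (n + 1, m + 1)
    Ms = np.full(shape, NEG, np.int32)
    Xs = np.full(shape, NEG, np.int32)
    Ys = np.full(shape, NEG, np.int32)
    Ma = np.zeros(shape, np.int32); Mb = np.zeros(shape, np.int32); Ml = np.zeros(shape, np.int32)
    Xa = np.zeros(shape, np.int32); Xb = np.zeros(shape, np.int32); Xl = np.zeros(shape, np.int32)
    Ya = np.zeros(shape, np.int32); Yb = np.zeros(shape, np.int32); Yl = np.zeros(shape, np.int32)
    Mp = np.zeros(shape, np.uint8); Xp = np.zeros(shape, np.uint8); Yp = np.zeros(shape, np.uint8)
    go = np.int32(gopen + gext)
    ge = np.int32(gext)
    best_s = np.int32(0)
    best_a = np.int32(2**30); best_b = np.int32(2**30); best_l = np.int32(2**30)
    bi = np.int32(-1); bj = np.int32(-1)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            # --- M: q[i-1] aligned to s[j-1]
            if qi < 4 and qi == s[j - 1]:
                sub = match
            else:
                sub = -mismatch
            ps = np.int32(0); pa = np.int32(i - 1); pb = np.int32(j - 1); pl = np.int32(0)
            ptr = np.uint8(0)
            if _better(Ms[i - 1, j - 1], Ma[i - 1, j - 1], Mb[i - 1, j - 1], Ml[i - 1, j - 1], ps, pa, pb, pl):
                ps = Ms[i - 1, j - 1]; pa = Ma[i - 1, j - 1]; pb = Mb[i - 1, j - 1]; pl = Ml[i - 1, j - 1]
                ptr = np.uint8(1)
            if _better(Xs[i - 1, j - 1], Xa[i - 1, j - 1], Xb[i - 1, j - 1], Xl[i - 1, j - 1], ps, pa, pb, pl):
                ps = Xs[i - 1, j - 1]; pa = Xa[i - 1, j - 1]; pb = Xb[i - 1, j - 1]; pl = Xl[i - 1, j - 1]
                ptr = np.uint8(2)
            if _better(Ys[i - 1, j - 1], Ya[i - 1, j - 1], Yb[i - 1, j - 1], Yl[i - 1, j - 1], ps, pa, pb, pl):
                ps = Ys[i - 1, j - 1]; pa = Ya[i - 1, j - 1]; pb = Yb[i - 1, j - 1]; pl = Yl[i - 1, j - 1]
                ptr = np.uint8(3)
            Ms[i, j] = ps + sub; Ma[i, j] = pa; Mb[i, j] = pb; Ml[i, j] = pl + 1; Mp[i, j] = ptr
            # --- X: gap in subject (consumes q[i-1])
            ps = Ms[i - 1, j] - go; pa = Ma[i - 1, j]; pb = Mb[i - 1, j]; pl = Ml[i - 1, j]
            ptr = np.uint8(1)
            if _better(Xs[i - 1, j] - ge, Xa[i - 1, j], Xb[i - 1, j], Xl[i - 1, j], ps, pa, pb, pl):
                ps = Xs[i - 1, j] - ge; pa = Xa[i - 1, j]; pb = Xb[i - 1, j]; pl = Xl[i - 1, j]
                ptr = np.uint8(2)
            if _better(Ys[i - 1, j] - go, Ya[i - 1, j], Yb[i - 1, j], Yl[i - 1, j], ps, pa, pb, pl):
                ps = Ys[i - 1, j] - go; pa = Ya[i - 1, j]; pb = Yb[i - 1, j]; pl = Yl[i - 1, j]
                ptr = np.uint8(3)
            Xs[i, j] = ps; Xa[i, j] = pa; Xb[i, j] = pb; Xl[i, j] = pl + 1; Xp[i, j] = ptr
            # --- Y: gap in query (consumes s[j-1])
            ps = Ms[i, j - 1] - go; pa = Ma[i, j - 1]; pb = Mb[i, j - 1]; pl = Ml[i, j - 1]
            ptr = np.uint8(1)
            if _better(Xs[i, j - 1] - go, Xa[i, j - 1], Xb[i, j - 1], Xl[i, j - 1], ps, pa, pb, pl):
                ps = Xs[i, j - 1] - go; pa = Xa[i, j - 1]; pb = Xb[i, j - 1]; pl = Xl[i, j - 1]
                ptr = np.uint8(2)
            if _better(Ys[i, j - 1] - ge, Ya[i, j - 1], Yb[i, j - 1], Yl[i, j - 1], ps, pa, pb, pl):
                ps = Ys[i, j - 1] - ge; pa = Ya[i, j - 1]; pb = Yb[i, j - 1]; pl = Yl[i, j - 1]
                ptr = np.uint8(3)
            Ys[i, j] = ps; Ya[i, j] = pa; Yb[i, j] = pb; Yl[i, j] = pl + 1; Yp[i, j] = ptr
            # --- best local alignment ends on a match/mismatch column
            if Ms[i, j] > 0 and _better(
                Ms[i, j], Ma[i, j], Mb[i, j], Ml[i, j], best_s, best_a, best_b, best_l
            ):
                best_s = Ms[i, j]; best_a = Ma[i, j]; best_b = Mb[i, j]; best_l = Ml[i, j]
                bi = np.int32(i); bj = np.int32(j)
    if bi < 0:
        return (np.int32(0), np.int32(0), np.int32(0), np.int32(0), np.int32(0),
                np.zeros(0, np.int8))
    # traceback
    ops = np.zeros(best_l, np.int8)
    k = best_l - 1
    i, j = int(bi), int(bj)
    state = np.uint8(1)  # 1=M, 2=X, 3=Y
    while k >= 0:
        if state == 1:
            ops[k] = OP_MATCH
            nxt = Mp[i, j]
            i -= 1
            j -= 1
        elif state == 2:
            ops[k] = OP_GAP_SUBJECT
            nxt = Xp[i, j]
            i -= 1
        else:
            ops[k] = OP_GAP_QUERY
            nxt = Yp[i, j]
            j -= 1
        k -= 1
        if nxt == 0:
            break
        state = nxt
    return best_s, best_a, np.int32(bi), best_b, np.int32(bj), ops


def _hit_stats(q: np.ndarray, s: np.ndarray, qs: int, ss: int, ops: np.ndarray):
    matches = gapped = 0
    i, j = qs, ss
    for op in ops:
        if op == OP_MATCH:
            if q[i] < 4 and q[i] == s[j]:
                matches += 1
            i += 1
            j += 1
        elif op == OP_GAP_SUBJECT:
            gapped += 1
            i += 1
        else:
            gapped += 1
            j += 1
    return matches, gapped


def local_align(
    query: str,
    subject: str,
    params: PairwiseParams | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_strand: str = "+",
) -> PairwiseHit | None:
    """Optimal local alignment of two sequences; None when no positive score exists."""
    params = params or PairwiseParams()
    if not query or not subject:
        raise ValidationError("empty sequence")
    q, s = encode(query), encode(subject)
    score, qs, qe, ss, se, ops = _gotoh(
        q, s, params.match_reward, params.mismatch_penalty,
        params.gap_open_cost, params.gap_extend_cost,
    )
    if score <= 0:
        return None
    matches, gapped = _hit_stats(q, s, int(qs), int(ss), ops)
    cols = len(ops)
    denom = cols if params.identity_denominator == "with-gaps" else cols - gapped
    identity = matches / denom if denom else 0.0
    return PairwiseHit(
        query_interval=GenomicInterval(query_id, int(qs), int(qe), "+"),
        subject_interval=GenomicInterval(subject_id, int(ss), int(se), subject_strand),
        score=int(score),
        identity=identity,
        aligned_columns=cols,
        gapped_columns=gapped,
        matches=matches,
        strand=subject_strand,
        ops=ops,
    )


def _retained(hit: PairwiseHit, params: PairwiseParams) -> bool:
    return hit.aligned_columns > params.min_hit_length and hit.identity >= params.min_identity


def find_hits(
    query_region: str,
    subject_region: str,
    params: PairwiseParams | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    search_both_strands: bool = True,
) -> list[PairwiseHit]:
    """Iterative best-hit-and-mask search; returns retained hits sorted by query start.

    The query should arrive pre-masked (exon/UTR stretches as N). After each
    round the best hit's query footprint is hard-masked so subsequent rounds
    find non-overlapping (in the query) hits, mimicking BLAST's practical
    behaviour of reporting multiple separate local hits.
    """
    params = params or PairwiseParams()
    if not query_region or not subject_region:
        raise ValidationError("empty sequence")
    query = list(query_region.upper())
    subject = subject_region.upper()
    subject_rc = reverse_complement(subject)
    m = len(subject)
    hits: list[PairwiseHit] = []
    while True:
        qstr = "".join(query)
        fwd = local_align(qstr, subject, params, query_id=query_id,
                          subject_id=subject_id, subject_strand="+")
        best = fwd
        if search_both_strands:
            rev = local_align(qstr, subject_rc, params, query_id=query_id,
                              subject_id=subject_id, subject_strand="-")
            if rev is not None and (best is None or rev.score > best.score):
                best = rev
        if best is None or best.score < params.min_report_score:
            break
        if best.strand == "-":
            ss, se = best.subject_interval.start, best.subject_interval.end
            best.subject_interval = GenomicInterval(subject_id, m - se, m - ss, "-")
        if _retained(best, params):
            hits.append(best)
        for k in range(best.query_interval.start, best.query_interval.end):
            query[k] = "N"
    hits.sort(key=lambda h: (h.query_interval.start, h.query_interval.end))
    return hits


def hits_to_table(hits: list[PairwiseHit]):
    """Hits as a pandas DataFrame mirroring BLAST outfmt-6 column order."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "qseqid": h.query_interval.sequence_id,
                "sseqid": h.subject_interval.sequence_id,
                "pident": round(100 * h.identity, 3),
                "length": h.aligned_columns,
                "mismatch": h.aligned_columns - h.gapped_columns - h.matches,
                "gaps": h.gapped_columns,
                "qstart": h.query_interval.start,
                "qend": h.query_interval.end,
                "sstart": h.subject_interval.start,
                "send": h.subject_interval.end,
                "strand": h.strand,
                "score": h.score,
            }
        )
    return pd.DataFrame(rows)
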