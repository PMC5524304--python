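"""Seed-and-extend scanner for conserved non-coding elements in a multi-species alignment.

The scanner works column-wise on a reference-anchored alignment block. A column
is *conserved* when the fraction of informative (non-gap, non-reference) rows
whose base differs from the reference base is strictly below a substitution
threshold, with a minimum number of informative rows. Seeds are fixed-length
windows of reference-base columns that are nearly all conserved; each seed is
extended outward, tolerating a bounded number of non-conserved columns per
side, and trimmed so elements start and end on conserved columns. Overlapping
elements are merged. Elements are finally filtered on fish presence: an
element is kept only if at least one fish-class row has aligned (non-gap)
bases over a minimum fraction of its columns.

Exon/repeat masks split blocks before scanning, so no element ever crosses or
overlaps a masked region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import AlignmentBlock, GenomicInterval, MaskTrack

logger = logging.getLogger(__name__)

GAP = ord("-")
N = ord("N")


@dataclass
class ScanParams:
    """Tuning knobs of the conservation scanner.

    Defaults follow the published search protocol: 10-column seeds at 90%
    conservation, up to 3 non-conserved columns tolerated per side during
    extension, a 12% per-column substitution ceiling, and 1 Mb windows on
    either side of the focal gene.
    """

    seed_length: int = 10
    seed_identity: float = 0.90
    max_nonconserved_per_side: int = 3
    column_substitution_threshold: float = 0.12
    min_species_in_column: int = 3
    window_up: int = 1_000_000
    window_down: int = 1_000_000
    fish_presence_min_cover: float = 0.50
    consensus_mode: str = "reference"  # or "consensus"

    def __post_init__(self):
        if not (0 < self.seed_identity <= 1):
            raise ValidationError("seed_identity must be in (0, 1]")
        if not (0 <= self.column_substitution_threshold < 1):
            raise ValidationError("column_substitution_threshold must be in [0, 1)")
        if self.seed_length < 1:
            raise ValidationError("seed_length must be >= 1")
        if self.max_nonconserved_per_side < 0:
            raise ValidationError("max_nonconserved_per_side must be >= 0")
        if self.consensus_mode not in ("reference", "consensus"):
            raise ValidationError("consensus_mode must be 'reference' or 'consensus'")


@dataclass
class CNE:
    """A conserved non-coding element in reference coordinates."""

    interval: GenomicInterval
    conserved_column_count: int
    supporting_species: set[str] = field(default_factory=set)
    fish_support: bool = False
    tetrapod_support: bool = False

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def score_percent(self) -> float:
        return 100.0 * self.conserved_column_count / self.length


def conserved_columns(block: AlignmentBlock, params: ScanParams) -> np.ndarray:
    """Boolean per-column conservation vector for a block (vectorised).

    Reference-gap columns are never conserved. N never counts as identical.
    """
    mat = block.matrix()
    ref = mat[0]
    others = mat[1:]
    nongap = others != GAP
    informative = nongap.sum(axis=0)
    if params.consensus_mode == "consensus" and others.shape[0]:
        # per-column modal base among non-gap rows (ties -> smaller byte code)
        target = np.full(ref.shape, GAP, np.uint8)
        for j in range(mat.shape[1]):
            col = others[nongap[:, j], j]
            if col.size:
                vals, counts = np.unique(col, return_counts=True)
                target[j] = vals[np.argmax(counts)]
    else:
        target = ref
    mismatch = (others != target) & nongap
    # N mismatches everything, including another N
    mismatch |= (others == N) & nongap
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(informative > 0, mismatch.sum(axis=0) / np.maximum(informative, 1), 1.0)
    ok = (
        (ref != GAP)
        & (ref != N)
        & (informative >= params.min_species_in_column)
        & (frac < params.column_substitution_threshold)
    )
    return ok


def column_conserved(block: AlignmentBlock, column_index: int, params: ScanParams) -> bool:
    """Is one alignment column conserved? (Scalar view of :func:`conserved_columns`.)"""
    if not (0 <= column_index < block.n_columns):
        raise IndexError(f"column {column_index} out of range 0..{block.n_columns - 1}")
    return bool(conserved_columns(block, params)[column_index])


def _seed_windows(block: AlignmentBlock, conserved: np.ndarray, params: ScanParams) -> list[tuple[int, int]]:
    """All qualifying seed windows as inclusive column intervals (w0, w1)."""
    L = params.seed_length
    n = block.n_columns
    if n < L:
        return []
    ref = block.matrix()[0]
    refbase = ref != GAP
    run_ok = np.lib.stride_tricks.sliding_window_view(refbase, L).all(axis=1)
    cons_count = np.lib.stride_tricks.sliding_window_view(
        conserved.astype(np.int32), L
    ).sum(axis=1)
    need = math.ceil(params.seed_identity * L)
    starts = np.nonzero(run_ok & (cons_count >= need))[0]
    return [(int(s), int(s) + L - 1) for s in starts]


def find_seeds(block: AlignmentBlock, params: ScanParams) -> list[tuple[int, int]]:
    """Qualifying seed windows (inclusive column intervals), merged when overlapping."""
    wins = _seed_windows(block, conserved_columns(block, params), params)
    merged: list[list[int]] = []
    for w0, w1 in wins:
        if merged and w0 <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], w1)
        else:
            merged.append([w0, w1])
    return [tuple(m) for m in merged]


def _extend_window(
    conserved: np.ndarray,
    w0: int,
    w1: int,
    budget: int,
    cum: np.ndarray,
    prev_cons: np.ndarray,
    next_cons: np.ndarray,
) -> tuple[int, int] | None:
    """Maximal extension of one seed window; trimmed to conserved endpoints."""
    n = conserved.size
    # rightmost j with (# non-conserved in (w1, j]) <= budget
    limit = cum[w1 + 1] + budget
    j = int(np.searchsorted(cum, limit, side="right")) - 2
    j = min(j, n - 1)
    e = int(prev_cons[j]) if j >= 0 else -1
    # leftmost i with (# non-conserved in [i, w0)) <= budget
    target = cum[w0] - budget
    i = int(np.searchsorted(cum, target, side="left"))
    i = max(i, 0)
    s = int(next_cons[i]) if i < n else n
    if s > e:
        return None
    return s, e


def _extension_tables(conserved: np.ndarray):
    n = conserved.size
    cum = np.zeros(n + 1, np.int64)
    np.cumsum(~conserved, out=cum[1:])
    idx = np.arange(n)
    prev_cons = np.maximum.accumulate(np.where(conserved, idx, -1))
    next_rev = np.maximum.accumulate(np.where(conserved[::-1], idx, -1))
    next_cons = np.where(next_rev >= 0, n - 1 - next_rev, n)[::-1]
    return cum, prev_cons, next_cons


def extend_seed(
    block: AlignmentBlock, seed: tuple[int, int], params: ScanParams
) -> tuple[int, int] | None:
    """Extend one seed window outward; returns the inclusive column interval."""
    conserved = conserved_columns(block, params)
    cum, prev_c, next_c = _extension_tables(conserved)
    return _extend_window(
        conserved, seed[0], seed[1], params.max_nonconserved_per_side, cum, prev_c, next_c
    )


def mask_block(block: AlignmentBlock, masks: list[MaskTrack] | MaskTrack | None) -> list[AlignmentBlock]:
    """Split a block at masked reference positions; masked columns are dropped."""
    if masks is None:
        return [block]
    if isinstance(masks, MaskTrack):
        masks = [masks]
    coords = block.ref_coordinates()
    masked = np.zeros(block.n_columns, bool)
    lo, hi = block.ref_start, block.ref_start + int((coords >= 0).sum())
    for track in masks:
        for iv in track.intervals:
            if iv.sequence_id != block.ref_sequence_id:
                continue
            if iv.end <= lo or iv.start >= hi:
                logger.warning(
                    "mask %s:%d-%d outside block %s:%d-%d; ignored",
                    iv.sequence_id, iv.start, iv.end, block.ref_sequence_id, lo, hi,
                )
                continue
            masked |= (coords >= iv.start) & (coords < iv.end)
    if not masked.any():
        return [block]
    keep = ~masked
    out = []
    j = 0
    n = block.n_columns
    while j < n:
        if not keep[j]:
            j += 1
            continue
        k = j
        while k < n and keep[k]:
            k += 1
        out.append(block.slice_columns(j, k))
        j = k
    return out


def _element_support(
    block: AlignmentBlock, s: int, e: int, params: ScanParams
) -> tuple[set[str], bool, bool]:
    width = e - s + 1
    supporting: set[str] = set()
    fish = tetra = False
    for sp, seq in block.rows.items():
        if sp == block.reference_species:
            continue
        cover = sum(c != "-" for c in seq[s : e + 1]) / width
        if cover >= params.fish_presence_min_cover:
            supporting.add(sp)
            cls = block.species_class.get(sp, "other")
            fish = fish or cls == "fish"
            tetra = tetra or cls == "tetrapod"
    return supporting, fish, tetra


def _scan_subblock(block: AlignmentBlock, params: ScanParams) -> list[CNE]:
    conserved = conserved_columns(block, params)
    wins = _seed_windows(block, conserved, params)
    if not wins:
        return []
    cum, prev_c, next_c = _extension_tables(conserved)
    spans: list[list[int]] = []
    for w0, w1 in wins:
        ext = _extend_window(
            conserved, w0, w1, params.max_nonconserved_per_side, cum, prev_c, next_c
        )
        if ext is None:
            continue
        s, e = ext
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])
    coords = block.ref_coordinates()
    out = []
    for s, e in spans:
        cols = coords[s : e + 1]
        refcols = cols[cols >= 0]
        if refcols.size == 0:
            continue
        supporting, fish, tetra = _element_support(block, s, e, params)
        out.append(
            CNE(
                interval=GenomicInterval(
                    block.ref_sequence_id, int(refcols[0]), int(refcols[-1]) + 1, "+"
                ),
                conserved_column_count=int(conserved[s : e + 1].sum()),
                supporting_species=supporting,
                fish_support=fish,
                tetrapod_support=tetra,
            )
        )
    return out


def scan(
    blocks: list[AlignmentBlock] | AlignmentBlock,
    masks: list[MaskTrack] | MaskTrack | None,
    params: ScanParams | None = None,
) -> list[CNE]:
    """Full pipeline: mask -> seed -> extend -> merge -> fish-presence filter.

    Elements with no fish-class row aligned over at least
    ``fish_presence_min_cover`` of their columns are dropped (set the threshold
    to 0 to disable the filter). Output is sorted by (sequence, start, end).
    """
    params = params or ScanParams()
    if isinstance(blocks, AlignmentBlock):
        blocks = [blocks]
    if params.fish_presence_min_cover > 0:
        for b in blocks:
            if not any(c == "fish" for c in b.species_class.values()):
                raise ValidationError(
                    "no fish-class species in block; tag species_class or disable "
                    "the fish-presence filter (fish_presence_min_cover=0)"
                )
    cnes: list[CNE] = []
    for block in blocks:
        for sub in mask_block(block, masks):
            cnes.extend(_scan_subblock(sub, params))
    if params.fish_presence_min_cover > 0:
        cnes = [c for c in cnes if c.fish_support]
    cnes.sort(key=lambda c: (c.interval.sequence_id, c.interval.start, c.interval.end))
    return cnes
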