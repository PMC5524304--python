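"""Shared coordinate/interval types and readers/writers for MAF, BED and tagged newick.

All coordinates are 0-based half-open internally. MAF is already 0-based so
values pass through; BED likewise. Strands are '+', '-' or '.' (unstranded).

Branch ω-class tags ride on newick node labels as a ``#tag`` suffix
(``((A#a,B#a)#a,(C#b,D#b)#b,E);``): the tag names the ω class of the branch
*above* that node. Untagged branches default to class ``r`` (rest/background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import IntegrityError, ParseError, ValidationError

STRANDS = ("+", "-", ".")
SPECIES_CLASSES = ("fish", "tetrapod", "reference", "other")
OMEGA_CLASSES = ("r", "p", "a", "b")

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.sequence_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.sequence_id != other.sequence_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals per sequence (strand dropped)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.sequence_id, x.start, x.end)):
        if out and out[-1].sequence_id == iv.sequence_id and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(replace(iv, strand="."))
    return out


@dataclass
class MaskTrack:
    """Normalised (sorted, merged) set of intervals to exclude from scanning."""

    intervals: list[GenomicInterval]
    kind: str = "exon"

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)


@dataclass
class AlignmentBlock:
    """Reference-anchored multi-species alignment slice.

    ``rows`` maps species name -> gapped sequence over A,C,G,T,N,-; the
    reference row anchors every column to a coordinate on ``ref_sequence_id``
    starting at ``ref_start`` (0-based). ``species_class`` tags each species as
    fish / tetrapod / reference / other for the downstream retention rules.
    """

    reference_species: str
    rows: dict[str, str]
    ref_sequence_id: str
    ref_start: int
    species_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.rows:
            raise IntegrityError("alignment block has no rows")
        if self.reference_species not in self.rows:
            raise IntegrityError(
                f"reference species {self.reference_species!r} missing from rows"
            )
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise IntegrityError(f"ragged alignment rows (lengths {sorted(lengths)})")
        self.rows = {sp: seq.upper() for sp, seq in self.rows.items()}
        for sp in self.rows:
            self.species_class.setdefault(
                sp, "reference" if sp == self.reference_species else "other"
            )
        for sp, cls in self.species_class.items():
            if cls not in SPECIES_CLASSES:
                raise ValidationError(f"unknown species class {cls!r} for {sp!r}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.reference_species])

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def matrix(self) -> np.ndarray:
        """Rows as a (n_species, n_columns) byte matrix, reference row first."""
        order = [self.reference_species] + [
            sp for sp in self.rows if sp != self.reference_species
        ]
        return np.array([np.frombuffer(self.rows[sp].encode(), np.uint8) for sp in order])

    def ref_coordinates(self) -> np.ndarray:
        """Per-column reference position; -1 for reference-gap columns."""
        ref = np.frombuffer(self.rows[self.reference_species].encode(), np.uint8)
        nongap = ref != ord("-")
        coords = np.where(nongap, self.ref_start + np.cumsum(nongap) - 1, -1)
        return coords.astype(np.int64)

    def slice_columns(self, start: int, stop: int) -> "AlignmentBlock":
        """Sub-block of columns [start, stop); reference start re-anchored."""
        coords = self.ref_coordinates()[start:stop]
        present = coords[coords >= 0]
        new_start = int(present[0]) if present.size else self.ref_start
        return AlignmentBlock(
            reference_species=self.reference_species,
            rows={sp: seq[start:stop] for sp, seq in self.rows.items()},
            ref_sequence_id=self.ref_sequence_id,
            ref_start=new_start,
            species_class=dict(self.species_class),
        )


@dataclass
class LabeledTree:
    """Rooted tree whose every branch carries an ω-class tag in OMEGA_CLASSES.

    The tag of a branch is stored on its child node as ``omega_class``.
    """

    tree: dendropy.Tree

    def __post_init__(self):
        seen = set()
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else leaf.label
            if name in seen:
                raise ValidationError(f"duplicate leaf name {name!r}")
            seen.add(name)
        for nd in self.tree:
            cls = getattr(nd, "omega_class", None)
            if cls is None:
                nd.omega_class = "r"
            elif cls not in OMEGA_CLASSES:
                raise ValidationError(f"unknown branch class tag {cls!r}")
            if nd.edge.length is not None and nd.edge.length < 0:
                raise ValidationError("negative branch length")

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def branch_classes(self) -> dict[str, str]:
        """Leaf-name -> class for terminal branches (convenience for reporting)."""
        return {lf.taxon.label: lf.omega_class for lf in self.tree.leaf_node_iter()}

    def clone(self) -> "LabeledTree":
        t = self.tree.clone(depth=1)
        for src, dst in zip(self.tree, t):
            dst.omega_class = src.omega_class
        return LabeledTree(t)


# ---------------------------------------------------------------------------
# MAF


def read_maf(
    path,
    species_class: Mapping[str, str] | None = None,
) -> list[AlignmentBlock]:
    """Read a MAF file into AlignmentBlocks (reference = first 's' row per block).

    MAF 's' lines give species as ``species.sequence``; the part before the
    first dot names the species, the remainder the sequence. ``species_class``
    optionally maps species -> fish/tetrapod/other (the reference species is
    always tagged 'reference').
    """
    try:
        msas = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise ParseError(f"malformed MAF file {path}: {exc}") from exc
    blocks = []
    for msa in msas:
        if len(msa) == 0:
            continue
        rows, classes = {}, {}
        ref = msa[0]
        ref_species, _, ref_seqid = ref.id.partition(".")
        for i, rec in enumerate(msa):
            sp = rec.id.partition(".")[0]
            rows[sp] = str(rec.seq)
            if i == 0:
                classes[sp] = "reference"
            elif species_class and sp in species_class:
                classes[sp] = species_class[sp]
        try:
            block = AlignmentBlock(
                reference_species=ref_species,
                rows=rows,
                ref_sequence_id=ref_seqid or ref.id,
                ref_start=int(ref.annotations.get("start", 0)),
                species_class=classes,
            )
        except IntegrityError as exc:
            raise IntegrityError(f"{path}: {exc}") from exc
        ungapped = sum(c != "-" for c in rows[ref_species])
        declared = ref.annotations.get("size")
        if declared is not None and declared != ungapped:
            raise IntegrityError(
                f"{path}: reference row declares size {declared} but has "
                f"{ungapped} non-gap columns"
            )
        blocks.append(block)
    return blocks


def write_maf(blocks: Sequence[AlignmentBlock], path) -> None:
    msas = []
    for b in blocks:
        recs = []
        order = [b.reference_species] + [s for s in b.rows if s != b.reference_species]
        for sp in order:
            seq = b.rows[sp]
            size = sum(c != "-" for c in seq)
            start = b.ref_start if sp == b.reference_species else 0
            seqid = b.ref_sequence_id if sp == b.reference_species else sp
            rec = SeqRecord(Seq(seq), id=f"{sp}.{seqid}")
            rec.annotations.update(
                {"start": start, "size": size, "strand": 1, "srcSize": start + size}
            )
            recs.append(rec)
        msas.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")


# ---------------------------------------------------------------------------
# BED


def read_bed(path, kind: str = "exon") -> MaskTrack:
    """Read a 3+ column BED (0-based half-open) into a normalised MaskTrack."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in STRANDS else "."
            intervals.append(GenomicInterval(parts[0], start, end, strand))
    return MaskTrack(intervals=intervals, kind=kind)


def write_bed(features, path) -> None:
    """Write CNEs (or intervals) as BED6; score column = percent identity/conservation."""
    with open(path, "w") as fh:
        for i, feat in enumerate(features):
            iv = getattr(feat, "interval", feat)
            score = getattr(feat, "score_percent", 0.0)
            name = getattr(feat, "name", f"element_{i + 1}")
            strand = iv.strand if iv.strand in ("+", "-") else "+"
            fh.write(
                f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{name}\t{score:.1f}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Tagged newick


def _split_tag(label: str | None) -> tuple[str | None, str | None]:
    if label is None or "#" not in label:
        return label, None
    name, _, tag = label.partition("#")
    return (name or None), (tag or None)


def read_labeled_tree(source: str, *, is_path: bool = False) -> LabeledTree:
    """Parse newick with ``#tag`` branch-class suffixes into a LabeledTree."""
    kwargs = {"path": str(source)} if is_path else {"data": source}
    try:
        tree = dendropy.Tree.get(
            schema="newick", suppress_internal_node_taxa=True, **kwargs
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"malformed newick: {exc}") from exc
    for nd in tree:
        if nd.taxon is not None:
            name, tag = _split_tag(nd.taxon.label)
            nd.taxon.label = name
        else:
            name, tag = _split_tag(nd.label)
            nd.label = name
        if tag is not None and tag not in OMEGA_CLASSES:
            raise ValidationError(f"unknown branch class tag {tag!r}")
        nd.omega_class = tag if tag is not None else "r"
    return LabeledTree(tree)


def write_labeled_tree(lt: LabeledTree) -> str:
    """Serialise a LabeledTree back to the ``#tag`` newick dialect."""
    t = lt.tree
    saved = [(nd, nd.taxon.label if nd.taxon else nd.label) for nd in t]
    try:
        for nd, label in saved:
            tag = "" if nd.omega_class == "r" else f"#{nd.omega_class}"
            if nd.taxon is not None:
                nd.taxon.label = f"{label}{tag}"
            elif tag:
                nd.label = f"{label or ''}{tag}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()
    finally:
        for nd, label in saved:
            if nd.taxon is not None:
                nd.taxon.label = label
            else:
                nd.label = label
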