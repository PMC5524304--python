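"""Synthetic inputs with controlled ground truth for every pipeline stage.

Real inputs to these analyses are genome-scale alignments and wet-lab
measurements; the generators here emulate their statistical structure at desk
scale so each stage can be exercised and checked against planted truth:

* multi-species alignment blocks with high-identity elements planted on a
  divergent background (for the conservation scanner);
* paralog-region pairs where each ancestral element is retained near paralog
  a / b with configurable per-side probabilities (for the pairwise search and
  the partition statistics);
* copy-number landscapes and qPCR Cq tables with additive Gaussian noise.

Background identity defaults to 0.60 — at the pairwise retention threshold, so
background alignments do not pass filters by construction — and planted
elements default to 0.98 identity, above every threshold. Mismatches are
uniform over the three alternative bases; planted elements carry no indels,
keeping truth intervals exact. All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AlignmentBlock, GenomicInterval
from .landscape_summary import LandscapeMatrix

_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, length)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


@dataclass
class PlantedAlignmentSpec:
    """Recipe for an alignment block with planted conserved elements."""

    n_fish: int = 5
    n_tetrapod: int = 5
    length: int = 5000
    background_match_prob: float = 0.60
    cne_match_prob: float = 0.98
    cne_lengths: list[int] = field(default_factory=lambda: [25, 40, 60])
    cne_positions: list[int] | None = None  # starts; None -> evenly spread
    gap_prob: float = 0.02
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for p in (self.background_match_prob, self.cne_match_prob, self.gap_prob):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must be in [0, 1]")
        if self.n_fish + self.n_tetrapod < 1:
            raise ValidationError("need at least one non-reference species")


def _place_elements(spec: PlantedAlignmentSpec) -> list[tuple[int, int]]:
    if spec.cne_positions is not None:
        starts = list(spec.cne_positions)
    else:
        k = len(spec.cne_lengths)
        step = spec.length // (k + 1)
        starts = [step * (i + 1) for i in range(k)]
    spans = []
    for s, ln in zip(starts, spec.cne_lengths):
        e = s + ln
        if not (0 <= s < e <= spec.length):
            raise ValidationError(f"element [{s},{e}) outside sequence of length {spec.length}")
        spans.append((s, e))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValidationError("planted elements overlap")
    for ms, me in spec.mask_intervals:
        for s, e in spans:
            if s < me and ms < e:
                raise ValidationError(
                    f"planted element [{s},{e}) collides with mask [{ms},{me})"
                )
    return spans


def make_planted_alignment(
    spec: PlantedAlignmentSpec, sequence_id: str = "ref_region"
) -> tuple[AlignmentBlock, list[GenomicInterval]]:
    """Alignment block plus the true planted intervals (reference coordinates)."""
    rng = np.random.default_rng(spec.seed)
    spans = _place_elements(spec)
    ref = _random_seq(rng, spec.length)
    in_cne = np.zeros(spec.length, bool)
    for s, e in spans:
        in_cne[s:e] = True
    match_p = np.where(in_cne, spec.cne_match_prob, spec.background_match_prob)
    rows = {"reference": _to_str(ref)}
    classes = {"reference": "reference"}
    names = [f"fish_{i + 1}" for i in range(spec.n_fish)] + [
        f"tetrapod_{i + 1}" for i in range(spec.n_tetrapod)
    ]
    for name in names:
        mism = rng.random(spec.length) >= match_p
        shift = rng.integers(1, 4, spec.length)
        seq = np.where(mism, (ref + shift) % 4, ref)
        chars = np.array(list(_to_str(seq)))
        gaps = (rng.random(spec.length) < spec.gap_prob) & ~in_cne
        chars[gaps] = "-"
        rows[name] = "".join(chars)
        classes[name] = "fish" if name.startswith("fish") else "tetrapod"
    block = AlignmentBlock(
        reference_species="reference",
        rows=rows,
        ref_sequence_id=sequence_id,
        ref_start=0,
        species_class=classes,
    )
    truth = [GenomicInterval(sequence_id, s, e, "+") for s, e in spans]
    return block, truth


@dataclass
class ParalogRetentionSpec:
    """Recipe for an ancestral region plus per-species paralog a/b regions."""

    n_cnes: int = 10
    p_keep_a: float = 0.3
    p_keep_b: float = 0.8
    n_species: int = 4
    p_tetrapod_shared: float = 0.25
    cne_length: int = 100
    spacer_length: int = 250
    retained_identity: float = 0.90
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_keep_a, self.p_keep_b, self.p_tetrapod_shared,
                  self.retained_identity):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must be in [0, 1]")
        if self.n_cnes < 1 or self.n_species < 1:
            raise ValidationError("need n_cnes >= 1 and n_species >= 1")


@dataclass
class ParalogDataset:
    query_sequence: str
    query_id: str
    cne_intervals: list[GenomicInterval]
    tetrapod_shared: np.ndarray  # bool per CNE
    retained: dict[tuple[str, str], np.ndarray]  # (species, paralog) -> bool per CNE
    sequences: dict[tuple[str, str], str]  # (species, paralog) -> region sequence
    species: list[str]


def _mutate(rng, codes: np.ndarray, identity: float) -> np.ndarray:
    mism = rng.random(codes.size) >= identity
    shift = rng.integers(1, 4, codes.size)
    return np.where(mism, (codes + shift) % 4, codes)


def make_paralog_dataset(spec: ParalogRetentionSpec) -> ParalogDataset:
    """Ancestral query region + paralog a/b regions per species, with truth.

    Each ancestral element is independently retained near paralog a with
    probability ``p_keep_a`` and near paralog b with ``p_keep_b``, per species.
    Retained copies are re-emitted at ``retained_identity`` inside an unrelated
    random background, so the pairwise search can rediscover the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    species = [f"species_{i + 1}" for i in range(spec.n_species)]
    cnes = [_random_seq(rng, spec.cne_length) for _ in range(spec.n_cnes)]
    parts = [_random_seq(rng, spec.spacer_length)]
    intervals = []
    pos = spec.spacer_length
    for c in cnes:
        intervals.append(GenomicInterval("ancestral_region", pos, pos + spec.cne_length, "+"))
        parts.append(c)
        pos += spec.cne_length
        parts.append(_random_seq(rng, spec.spacer_length))
        pos += spec.spacer_length
    query = _to_str(np.concatenate(parts))
    tetra = rng.random(spec.n_cnes) < spec.p_tetrapod_shared
    retained = {}
    sequences = {}
    for sp in species:
        for par, pkeep in (("a", spec.p_keep_a), ("b", spec.p_keep_b)):
            keep = rng.random(spec.n_cnes) < pkeep
            parts = [_random_seq(rng, spec.spacer_length)]
            for ci, c in enumerate(cnes):
                if keep[ci]:
                    parts.append(_mutate(rng, c, spec.retained_identity))
                parts.append(_random_seq(rng, spec.spacer_length))
            retained[(sp, par)] = keep
            sequences[(sp, par)] = _to_str(np.concatenate(parts))
    return ParalogDataset(
        query_sequence=query,
        query_id="ancestral_region",
        cne_intervals=intervals,
        tetrapod_shared=tetra,
        retained=retained,
        sequences=sequences,
        species=species,
    )


def truth_partition_table(dataset: ParalogDataset):
    """The ground-truth PartitionTable implied by a ParalogDataset."""
    from .paralog_partition import PartitionTable

    keys = sorted(dataset.retained)
    ids = [f"cne_{i + 1}" for i in range(len(dataset.cne_intervals))]
    cols = pd.MultiIndex.from_tuples(keys, names=["species", "paralog"])
    data = np.column_stack([dataset.retained[k] for k in keys])
    return PartitionTable(
        gene="synthetic",
        table=pd.DataFrame(data, index=ids, columns=cols),
        tetrapod_shared=pd.Series(dataset.tetrapod_shared, index=ids),
    )


def make_landscape(
    n_genes: int,
    duplication_profile,
    seed: int,
    *,
    n_teleosts: int = 6,
    n_salmonids: int = 2,
    p_duplicated_all: float = 0.3,
) -> LandscapeMatrix:
    """Random copy-number landscape.

    ``duplication_profile`` is either 'all-singleton' or a list of origin tags
    (one per gene, from WGD_duplicate/SSD_duplicate/singleton). Duplicate
    genes keep both copies in all teleosts with probability
    ``p_duplicated_all``, otherwise in a random non-empty subset.
    """
    rng = np.random.default_rng(seed)
    if duplication_profile == "all-singleton":
        origins = ["singleton"] * n_genes
    else:
        origins = list(duplication_profile)
        if len(origins) != n_genes:
            raise ValidationError("duplication_profile length must equal n_genes")
    genes = [f"gene_{i + 1}" for i in range(n_genes)]
    teleosts = [f"teleost_{i + 1}" for i in range(n_teleosts)]
    salmonids = [f"salmonid_{i + 1}" for i in range(n_salmonids)]
    cn = pd.DataFrame(1, index=genes, columns=teleosts + salmonids)
    for g, origin in zip(genes, origins):
        if origin == "singleton":
            continue
        if rng.random() < p_duplicated_all:
            cn.loc[g, teleosts] = 2
        else:
            k = int(rng.integers(1, max(2, n_teleosts)))
            chosen = rng.choice(teleosts, size=k, replace=False)
            cn.loc[g, chosen] = 2
        cn.loc[g, salmonids] = rng.integers(2, 5, n_salmonids)
    lineage = {sp: "teleost" for sp in teleosts}
    lineage |= {sp: "salmonid_teleost" for sp in salmonids}
    origin = dict(zip(genes, origins))
    return LandscapeMatrix(copy_number=cn, lineage=lineage, origin=origin)


def make_cq_table(
    design: pd.DataFrame,
    noise_sd: float,
    seed: int,
    *,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Replicate Cq table from a design of true mean Cq values.

    ``design`` has columns sample, gene, cq (the noiseless mean); each row is
    expanded into ``n_replicates`` measurements with additive Gaussian noise.
    Detection-limit clipping is *not* applied here — that is the quantifier's
    job downstream.
    """
    missing = {"sample", "gene", "cq"} - set(design.columns)
    if missing:
        raise ValidationError(f"design missing columns {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in design.iterrows():
        for _ in range(n_replicates):
            rows.append(
                {
                    "sample": r["sample"],
                    "gene": r["gene"],
                    "cq": float(r["cq"]) + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
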