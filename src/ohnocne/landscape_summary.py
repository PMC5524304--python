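"""Duplicate-retention statistics over a genes x species copy-number landscape.

The landscape records, for each ancestral gene and each genome, how many
copies survive today, together with the duplication origin of each gene
(whole-genome duplication, small-scale duplication, or singleton). The
summary answers the retention questions that matter after a WGD: what
fraction of genes kept a duplicate in at least one species, in all species,
only in particular lineages, and how strongly salmonids (which underwent a
second, more recent WGD) retain duplicates.

Percentages are carried as exact floats; rendering to one decimal supports
both round-half-up and truncation styles, because published per-cent figures
are frequently formatted inconsistently between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

LINEAGES = ("teleost", "salmonid_teleost", "outgroup")
ORIGINS = ("WGD_duplicate", "SSD_duplicate", "singleton")


def format_percent(x: float | None, style: str = "round") -> float | None:
    """Render a percentage to one decimal; style 'round' (half-up) or 'truncate'."""
    if x is None:
        return None
    if style == "truncate":
        return math.floor(x * 10) / 10
    if style == "round":
        return math.floor(x * 10 + 0.5) / 10
    raise ValidationError("style must be 'round' or 'truncate'")


@dataclass
class LandscapeMatrix:
    """Copy-number matrix (genes x species) with lineage and origin annotations."""

    copy_number: pd.DataFrame  # int, genes x species
    lineage: dict[str, str]  # species -> teleost / salmonid_teleost / outgroup
    origin: dict[str, str]  # gene -> WGD_duplicate / SSD_duplicate / singleton

    def __post_init__(self):
        if (self.copy_number.values < 0).any():
            raise ValidationError("copy numbers must be non-negative")
        for sp in self.copy_number.columns:
            if self.lineage.get(sp) not in LINEAGES:
                raise ValidationError(f"species {sp!r} missing/invalid lineage tag")
        for g in self.copy_number.index:
            if self.origin.get(g) not in ORIGINS:
                raise ValidationError(f"gene {g!r} missing/invalid origin tag")
        if not self.species_of("teleost"):
            raise ValidationError("landscape needs >= 1 non-salmonid teleost species")

    def species_of(self, lineage: str) -> list[str]:
        return [sp for sp in self.copy_number.columns if self.lineage[sp] == lineage]


@dataclass
class RetentionReport:
    n_genes: int
    n_duplicated_any: int
    n_duplicated_all: int
    n_lineage_specific: int
    n_wgd_duplicates: int

    @property
    def pct_duplicated_any(self) -> float:
        return 100.0 * self.n_duplicated_any / self.n_genes

    @property
    def pct_duplicated_all(self) -> float | None:
        if self.n_duplicated_any == 0:
            return None
        return 100.0 * self.n_duplicated_all / self.n_duplicated_any

    @property
    def pct_lineage_specific(self) -> float | None:
        if self.n_duplicated_any == 0:
            return None
        return 100.0 * self.n_lineage_specific / self.n_duplicated_any

    @property
    def wgd_retention_pct(self) -> float:
        return 100.0 * self.n_wgd_duplicates / self.n_genes

    def as_dict(self, style: str = "round") -> dict:
        return {
            "n_genes": self.n_genes,
            "n_duplicated_any": self.n_duplicated_any,
            "pct_duplicated_any": format_percent(self.pct_duplicated_any, style),
            "n_duplicated_all": self.n_duplicated_all,
            "pct_duplicated_all": format_percent(self.pct_duplicated_all, style),
            "n_lineage_specific": self.n_lineage_specific,
            "pct_lineage_specific": format_percent(self.pct_lineage_specific, style),
            "n_wgd_duplicates": self.n_wgd_duplicates,
            "wgd_retention_pct": format_percent(self.wgd_retention_pct, style),
        }


def summarize_landscape(matrix: LandscapeMatrix) -> RetentionReport:
    """Retention report over non-salmonid teleosts.

    Salmonids are excluded from the any/all denominators because their
    lineage-specific WGD would conflate two duplication rounds; see
    :func:`salmonid_retention` for their separate rate.
    """
    teleosts = matrix.species_of("teleost")
    cn = matrix.copy_number[teleosts]
    dup = cn >= 2
    dup_any = dup.any(axis=1)
    dup_all = dup.all(axis=1)
    n_any = int(dup_any.sum())
    n_all = int((dup_any & dup_all).sum())
    n_wgd = sum(matrix.origin[g] == "WGD_duplicate" for g in matrix.copy_number.index)
    return RetentionReport(
        n_genes=len(matrix.copy_number),
        n_duplicated_any=n_any,
        n_duplicated_all=n_all,
        n_lineage_specific=n_any - n_all,
        n_wgd_duplicates=n_wgd,
    )


def salmonid_retention(matrix: LandscapeMatrix) -> dict:
    """Per-salmonid (and pooled) percent of assayed genes retained in >= 2 copies.

    A gene counts as assayed in a salmonid when at least one copy is present.
    """
    salmonids = matrix.species_of("salmonid_teleost")
    if not salmonids:
        raise ValidationError("no salmonid species in landscape")
    per_species = {}
    pooled_num = pooled_den = 0
    for sp in salmonids:
        col = matrix.copy_number[sp]
        assayed = col >= 1
        dup = col >= 2
        den = int(assayed.sum())
        num = int((assayed & dup).sum())
        per_species[sp] = 100.0 * num / den if den else None
        pooled_num += num
        pooled_den += den
    return {
        "per_species": per_species,
        "pooled": 100.0 * pooled_num / pooled_den if pooled_den else None,
    }


def read_landscape_tsv(path) -> LandscapeMatrix:
    """Read a landscape TSV: columns gene, origin, then one column per species
    named ``species:lineage`` holding integer copy numbers."""
    df = pd.read_csv(path, sep="\t")
    origin = dict(zip(df["gene"], df["origin"]))
    sp_cols = [c for c in df.columns if c not in ("gene", "origin")]
    lineage = {}
    rename = {}
    for c in sp_cols:
        sp, _, lin = c.partition(":")
        lineage[sp] = lin or "teleost"
        rename[c] = sp
    cn = df.set_index("gene")[sp_cols].rename(columns=rename).astype(int)
    return LandscapeMatrix(copy_number=cn, lineage=lineage, origin=origin)


def write_landscape_tsv(matrix: LandscapeMatrix, path) -> None:
    df = matrix.copy_number.copy()
    df.columns = [f"{sp}:{matrix.lineage[sp]}" for sp in df.columns]
    df.insert(0, "origin", [matrix.origin[g] for g in df.index])
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Reference fixture: the 19-gene sox family landscape in teleost genomes,
# assembled from published in-text gene lists (which genes are WGD ohnolog
# pairs, which stayed single-copy, which were lost in which lineages). Copy
# numbers not pinned down by those lists (mainly which lineages retain each
# lineage-specific duplicate, and salmonid counts) are representative choices.

TELEOSTS = (
    "zebrafish", "cavefish", "cod", "tilapia", "medaka",
    "platyfish", "tetraodon", "fugu", "stickleback",
)
SALMONIDS = ("salmon", "trout")
OUTGROUPS = ("spotted_gar", "coelacanth", "human", "mouse", "elephant_shark")

_WGD_GENES = ("sox1", "sox4", "sox6", "sox8", "sox9", "sox10", "sox11",
              "sox14", "sox19", "sox21")
_SINGLETONS = ("sox2", "sox3", "sox5", "sox7", "sox13", "sox18")
# sox17's duplicate (sox32) arose by small-scale duplication and is present in
# every teleost genome; sox12 and sox30 are singletons with lineage losses.
_ACANTHOPTERYGII = ("cod", "tilapia", "medaka", "platyfish", "tetraodon",
                    "fugu", "stickleback")
_SOX30_LOST = ("cavefish", "zebrafish", "medaka", "tetraodon", "fugu", "stickleback")

# Species retaining both WGD copies, for the eight genes duplicated only in
# particular lineages (sox4 and sox9 are duplicated everywhere).
_LINEAGE_RETAINERS = {
    "sox1": ("zebrafish", "cavefish", "medaka", "stickleback"),
    "sox6": ("zebrafish", "cavefish", "tilapia"),
    "sox8": ("zebrafish", "medaka", "platyfish"),
    "sox10": ("zebrafish", "tilapia", "medaka", "stickleback"),
    "sox11": ("zebrafish", "cavefish", "cod", "tilapia", "medaka"),
    "sox14": ("zebrafish", "tilapia"),
    "sox19": ("zebrafish", "cavefish"),
    "sox21": ("zebrafish", "medaka", "fugu"),
}


def sox_landscape() -> LandscapeMatrix:
    """The 19-gene sox copy-number landscape across 16 vertebrate genomes."""
    genes = list(_WGD_GENES) + ["sox17"] + list(_SINGLETONS) + ["sox12", "sox30"]
    species = list(TELEOSTS) + list(SALMONIDS) + list(OUTGROUPS)
    cn = pd.DataFrame(1, index=genes, columns=species)
    for sp in TELEOSTS:
        cn.loc["sox4", sp] = 2
        cn.loc["sox9", sp] = 2
        cn.loc["sox17", sp] = 2
    for gene, retainers in _LINEAGE_RETAINERS.items():
        for sp in retainers:
            cn.loc[gene, sp] = 2
    cn.loc["sox10", "cavefish"] = 0
    for sp in _ACANTHOPTERYGII:
        cn.loc["sox12", sp] = 0
    for sp in _SOX30_LOST:
        cn.loc["sox30", sp] = 0
    for sp in SALMONIDS:
        cn.loc[:, sp] = 2
        cn.loc[["sox7", "sox18", "sox30"], sp] = 1
    cn.loc["sox19", "elephant_shark"] = 0
    lineage = {sp: "teleost" for sp in TELEOSTS}
    lineage |= {sp: "salmonid_teleost" for sp in SALMONIDS}
    lineage |= {sp: "outgroup" for sp in OUTGROUPS}
    origin = {g: "WGD_duplicate" for g in _WGD_GENES}
    origin["sox17"] = "SSD_duplicate"
    for g in list(_SINGLETONS) + ["sox12", "sox30"]:
        origin[g] = "singleton"
    return LandscapeMatrix(copy_number=cn, lineage=lineage, origin=origin)
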