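"""Config-driven orchestration: scan -> pairwise -> partition -> statistics -> reports.

A single YAML (or dict) config names the inputs and parameters of each stage;
stages run in dependency order, any stage can be skipped by omitting its
section or restricting ``stages``. Each run writes a manifest recording
parameters, seed, package version and input/output checksums, so identical
config + inputs give identical outputs. On stage failure, files the stage had
already written are renamed with a ``.partial`` suffix and the failure names
the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .cne_pairwise import PairwiseParams, find_hits, hits_to_table
from .cne_scan import ScanParams, scan
from .errors import OhnocneError, ValidationError
from .expression_ddct import calls_to_table, quantify, read_cq_table
from .io_formats import read_bed, read_maf, write_bed
from .landscape_summary import read_landscape_tsv, salmonid_retention, summarize_landscape
from .paralog_partition import (
    build_partition,
    count_asymmetry_test,
    partition_to_tsv,
    summarize,
)

logger = logging.getLogger(__name__)

STAGES = ("scan", "pairwise", "partition", "landscape", "ddct", "codon")


class StageError(OhnocneError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> list[Path]:
    """Check referenced input files exist before any compute; returns the inputs."""
    inputs = []
    for stage in STAGES:
        section = config.get(stage)
        if not section:
            continue
        for key in ("maf", "mask", "query_fasta", "matrix", "cq_table",
                    "alignment_fasta", "tree_newick"):
            if key in section:
                p = Path(section[key])
                if not p.exists():
                    raise ValidationError(f"{stage}.{key}: missing input file {p}")
                inputs.append(p)
        for sub in section.get("subjects", []):
            p = Path(sub["fasta"])
            if not p.exists():
                raise ValidationError(f"pairwise subject file missing: {p}")
            inputs.append(p)
    return inputs


def _read_fasta_one(path: str) -> str:
    from Bio import SeqIO

    recs = list(SeqIO.parse(path, "fasta"))
    if len(recs) != 1:
        raise ValidationError(f"{path}: expected exactly one FASTA record")
    return str(recs[0].seq)


def run(config, only_stages: list[str] | None = None) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config = load_config(config)
    inputs = validate_config(config)
    outdir = Path(config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    active = [s for s in (only_stages or config.get("stages", STAGES)) if s in config]
    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": active,
        "parameters": {s: config.get(s) for s in active},
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {},
    }
    results: dict = {}
    for stage in active:
        written: list[Path] = []
        try:
            _run_stage(stage, config[stage], outdir, results, written)
        except Exception as exc:
            for p in written:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise StageError(stage, exc) from exc
        for p in written:
            manifest["outputs"][str(p)] = _sha256(p)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage, section, outdir: Path, results: dict, written: list[Path]):
    if stage == "scan":
        params = ScanParams(**section.get("params", {}))
        blocks = read_maf(section["maf"], species_class=section.get("species_class"))
        masks = read_bed(section["mask"]) if section.get("mask") else None
        cnes = scan(blocks, masks, params)
        results["cnes"] = cnes
        bed = outdir / "cnes.bed"
        write_bed(cnes, bed)
        written.append(bed)
        tsv = outdir / "cnes_support.tsv"
        with open(tsv, "w") as fh:
            fh.write("sequence\tstart\tend\tconserved_columns\tfish\ttetrapod\tspecies\n")
            for c in cnes:
                fh.write(
                    f"{c.interval.sequence_id}\t{c.interval.start}\t{c.interval.end}\t"
                    f"{c.conserved_column_count}\t{c.fish_support}\t{c.tetrapod_support}\t"
                    f"{','.join(sorted(c.supporting_species))}\n"
                )
        written.append(tsv)
    elif stage == "pairwise":
        params = PairwiseParams(**section.get("params", {}))
        query = _read_fasta_one(section["query_fasta"])
        if section.get("mask"):
            track = read_bed(section["mask"])
            q = list(query)
            for iv in track.intervals:
                for k in range(iv.start, min(iv.end, len(q))):
                    q[k] = "N"
            query = "".join(q)
        hits_by_key = {}
        for sub in section["subjects"]:
            subject = _read_fasta_one(sub["fasta"])
            hits_by_key[(sub["species"], sub["paralog"])] = find_hits(
                query, subject, params,
                query_id=section.get("query_id", "query"),
                subject_id=f"{sub['species']}.{sub['paralog']}",
            )
        results["hits"] = hits_by_key
        all_hits = [h for hs in hits_by_key.values() for h in hs]
        path = outdir / "pairwise_hits.tsv"
        hits_to_table(all_hits).to_csv(path, sep="\t", index=False)
        written.append(path)
    elif stage == "partition":
        if "cnes" not in results or "hits" not in results:
            raise ValidationError("partition stage needs scan and pairwise results")
        table = build_partition(
            results["cnes"], results["hits"],
            gene=section.get("gene", "gene"),
            min_overlap_fraction=section.get("min_overlap_fraction", 0.5),
        )
        results["partition"] = table
        tsv = outdir / "partition.tsv"
        partition_to_tsv(table, tsv)
        written.append(tsv)
        summary = summarize(table, section.get("aggregation", "any_species"))
        counts_a = [int(table.table.xs("a", axis=1, level="paralog").get(sp, 0).sum())
                    for sp in table.species]
        counts_b = [int(table.table.xs("b", axis=1, level="paralog").get(sp, 0).sum())
                    for sp in table.species]
        payload = {"summary": summary.as_dict()}
        if len(counts_a) >= 2:
            t = count_asymmetry_test(counts_a, counts_b, paired=section.get("paired", True))
            payload["asymmetry_test"] = {
                "t": t.statistic, "df": t.df, "p": t.p_value, "paired": t.paired,
            }
        path = outdir / "partition_summary.json"
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)
    elif stage == "landscape":
        matrix = read_landscape_tsv(section["matrix"])
        report = summarize_landscape(matrix)
        payload = report.as_dict(style=section.get("percent_style", "round"))
        if matrix.species_of("salmonid_teleost"):
            payload["salmonid_retention"] = salmonid_retention(matrix)
        path = outdir / "landscape_report.json"
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)
    elif stage == "ddct":
        table = read_cq_table(section["cq_table"])
        calls = quantify(
            table,
            section["reference"],
            section["calibrator"],
            detection_limit=section.get("detection_limit", 34.0),
            low_cutoff=section.get("low_cutoff", 0.10),
        )
        path = outdir / "expression_calls.tsv"
        calls_to_table(calls).to_csv(path, sep="\t", index=False)
        written.append(path)
    elif stage == "codon":
        from .codon_evolution import CodonAlignment, ModelSpec, fit, lrt

        aln = CodonAlignment.from_fasta(section["alignment_fasta"])
        tree = Path(section["tree_newick"]).read_text()
        models = section.get("models", ["A", "B"])
        fits = {}
        for m in models:
            fits[m] = fit(
                aln, tree, ModelSpec(m, section.get("codon_frequencies", "F3x4")),
                seed=int(section.get("seed", 0)),
                n_restarts=int(section.get("n_restarts", 3)),
            )
        payload = {m: f.as_dict() for m, f in fits.items()}
        order = [m for m in ("A", "B", "C") if m in fits]
        for null, alt in zip(order, order[1:]):
            r = lrt(fits[null], fits[alt])
            payload[f"lrt_{null}_vs_{alt}"] = {
                "statistic": r.statistic, "df": r.df, "p": r.p_value,
            }
        path = outdir / "codon_models.json"
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)
    else:
        raise ValidationError(f"unknown stage {stage!r}")
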