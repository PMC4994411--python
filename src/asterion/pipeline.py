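"""End-to-end orchestration: simulate -> classify -> enrich -> correlate ->
conserve -> introns, with one master seed and a reproducible JSON report.

Each stage derives its own seed from the master seed and the stage name,
so enabling or reordering stages never perturbs another stage's draws.
The report deliberately contains no timestamps: two runs with one seed
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from . import classify as _classify
from . import conservation as _conservation
from . import evidence as _evidence
from . import expression as _expression
from . import stats as _stats
from .annotation_io import (
    read_annotation,
    read_bed,
    read_hit_table,
    write_annotation,
    write_hit_table,
)
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_conservation_hits,
    simulate_cne_hits,
    simulate_evidence_hits,
    simulate_expression,
    simulate_synteny_blocks,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("classify", "enrich", "correlate", "conserve", "introns")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a pipeline run.

    Threshold defaults are the study's printed settings: e-value < 0.001,
    1000 resamples, 20 length bins, 100 bp minimum CNE length.
    """

    gff: str
    outdir: str
    seed: int = 0
    blastx: Optional[str] = None
    expression: Optional[str] = None
    manifest: Optional[str] = None
    blocks_bed: Optional[str] = None
    evalue_max: float = 0.001
    reps: int = 1000
    n_bins: int = 20
    min_cne_len: int = 100
    null_pair_reps: int = 10
    stages: tuple[str, ...] = ALL_STAGES

    def to_dict(self) -> dict:
        return {
            "gff": self.gff,
            "outdir": self.outdir,
            "seed": self.seed,
            "blastx": self.blastx,
            "expression": self.expression,
            "manifest": self.manifest,
            "blocks_bed": self.blocks_bed,
            "evalue_max": self.evalue_max,
            "reps": self.reps,
            "n_bins": self.n_bins,
            "min_cne_len": self.min_cne_len,
            "null_pair_reps": self.null_pair_reps,
            "stages": list(self.stages),
        }


def write_bundle(cfg: SimulationConfig, outdir: str) -> dict:
    """Simulate every pipeline input into *outdir*; returns the file map.

    Writes annotation.gff3, expression.tsv, blastx.tsv, per-(genome, pair)
    conservation hit tables plus manifest.yaml, synteny blocks.bed,
    cne_hits.tsv and truth.json.
    """
    os.makedirs(outdir, exist_ok=True)
    aset, truth = simulate_annotation(cfg)
    gff = os.path.join(outdir, "annotation.gff3")
    write_annotation(aset, gff, dialect="gff3")

    expr = simulate_expression(cfg, truth, aset)
    expr_path = os.path.join(outdir, "expression.tsv")
    expr.to_tsv(expr_path)

    hits = simulate_evidence_hits(cfg, truth, aset)
    blastx = os.path.join(outdir, "blastx.tsv")
    write_hit_table(hits, blastx, frames=True)

    tables = simulate_conservation_hits(cfg, truth)
    cons_dir = os.path.join(outdir, "conservation")
    os.makedirs(cons_dir, exist_ok=True)
    manifest: dict = {"pairs": [], "genomes": [], "tables": {}}
    assert truth.conservation is not None
    manifest["pairs"] = list(truth.conservation.index)
    manifest["genomes"] = list(truth.conservation.columns)
    for (p, g), (host_hits, ast_hits) in sorted(tables.items()):
        safe = p.replace("|", "_")
        hp = os.path.join(cons_dir, f"{g}.{safe}.host.tsv")
        ap = os.path.join(cons_dir, f"{g}.{safe}.ast.tsv")
        write_hit_table(host_hits, hp)
        write_hit_table(ast_hits, ap)
        manifest["tables"].setdefault(p, {})[g] = {"host": hp, "ast": ap}
    manifest_path = os.path.join(outdir, "manifest.yaml")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    blocks = simulate_synteny_blocks(cfg)
    blocks_path = os.path.join(outdir, "blocks.bed")
    with open(blocks_path, "w", encoding="utf-8") as fh:
        fh.write("# contig\tstart\tend\tname\tscore\tstrand\n")
        pos = 0
        for i, b in enumerate(blocks):
            fh.write(f"chrB1\t{pos}\t{pos + int(b)}\tblock{i}\t0\t.\n")
            pos += int(b) + 100

    cne_hits = simulate_cne_hits(seed=cfg.seed)
    cne_path = os.path.join(outdir, "cne_hits.tsv")
    write_hit_table(cne_hits, cne_path)

    truth_path = os.path.join(outdir, "truth.json")
    truth.to_json(truth_path)
    return {
        "gff": gff,
        "expression": expr_path,
        "blastx": blastx,
        "manifest": manifest_path,
        "blocks_bed": blocks_path,
        "cne_hits": cne_path,
        "truth": truth_path,
    }


def read_manifest(path: str):
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    tables = {}
    for p, per_genome in manifest["tables"].items():
        for g, files in per_genome.items():
            tables[(p, g)] = (
                read_hit_table(files["host"]),
                read_hit_table(files["ast"]),
            )
    return manifest["pairs"], manifest["genomes"], tables


def run_all(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and write report.json.

    Returns the report dict.  A stage whose inputs are not configured is
    skipped with a log message rather than failing the run.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    with open(os.path.join(cfg.outdir, "resolved_config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)

    report: dict = {"seed": cfg.seed, "stages": {}}
    aset = read_annotation(cfg.gff, dialect="gff3")
    pairs = _classify.classify_annotation(aset)
    summary = _classify.summarize(pairs)

    if "classify" in cfg.stages:
        frame = _classify.pairs_to_frame(pairs)
        frame.to_csv(
            os.path.join(cfg.outdir, "antisense_pairs.tsv"), sep="\t", index=False
        )
        report["stages"]["classify"] = summary.to_dict()

    intronic = [p for p in pairs if p.cls is _classify.AntisenseClass.INTRONIC]

    if "enrich" in cfg.stages and cfg.blastx:
        hits = read_hit_table(cfg.blastx, format="outfmt6_frames")
        index = _evidence.EvidenceIndex.build(
            aset, hits, evalue_max=cfg.evalue_max
        )
        asts = sorted({p.ast for p in intronic})
        universe = sorted(index.flags)
        n_bins = min(cfg.n_bins, len(asts))
        if n_bins < cfg.n_bins:
            log.info(
                "enrich: only %d ASTs, reducing length bins to %d",
                len(asts), n_bins,
            )
        res = _evidence.resampling_test(
            asts,
            universe,
            index,
            reps=cfg.reps,
            seed=stage_seed(cfg.seed, "enrich"),
            n_bins=n_bins,
        )
        np.savetxt(
            os.path.join(cfg.outdir, "enrichment_null_counts.tsv"),
            res.null_counts,
            fmt="%d",
        )
        report["stages"]["enrich"] = res.to_dict()

    if "correlate" in cfg.stages and cfg.expression:
        expr = _expression.ExpressionMatrix.from_tsv(cfg.expression)
        gene_pairs = sorted({(p.host_gene, p.ast_gene) for p in intronic})
        rhos, n_dropped = _expression.pair_correlations(gene_pairs, expr)
        if rhos:
            null = _expression.random_pair_null(
                expr,
                n_pairs=len(rhos),
                reps=cfg.null_pair_reps,
                seed=stage_seed(cfg.seed, "correlate"),
                exclude={frozenset(p) for p in gene_pairs},
            )
            comp = _expression.compare_to_null(rhos, null, n_dropped)
            report["stages"]["correlate"] = comp.to_dict()
        else:
            log.info("correlate: no evaluable pairs")

    if "conserve" in cfg.stages and cfg.manifest:
        pair_ids, genomes, tables = read_manifest(cfg.manifest)
        matrix = _conservation.build_matrix(
            pair_ids, genomes, tables, evalue_max=cfg.evalue_max
        )
        mf = matrix.to_frame()
        mf.to_csv(os.path.join(cfg.outdir, "conservation_matrix.tsv"), sep="\t")
        report["stages"]["conserve"] = {
            "n_pairs": len(pair_ids),
            "n_genomes": len(genomes),
            "n_conserved_cells": int(mf.fillna(0).to_numpy().sum()),
            "per_pair": {p: matrix.conserved_count(p) for p in pair_ids},
        }

    if "introns" in cfg.stages:
        hosts = {p.host_gene for p in intronic}
        table = _stats.largest_intron_per_gene(aset, host_genes=hosts)
        table.to_csv(
            os.path.join(cfg.outdir, "largest_introns.tsv"), sep="\t", index=False
        )
        if hosts and (~table["is_host"]).any():
            res = _stats.intron_length_comparison(table)
            report["stages"]["introns"] = res.to_dict()

        if cfg.blocks_bed and intronic:
            blocks = [len(iv) for iv in read_bed(cfg.blocks_bed)]
            spans = [
                len(aset[p.host].span()) for p in intronic
            ]
            res = _stats.span_size_comparison(spans, blocks)
            report["stages"]["spansize"] = res.to_dict()

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
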