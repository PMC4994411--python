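"""Synthetic study data with known ground truth.

Every pipeline input can be generated here: a stranded multi-exon genome
annotation with planted antisense configurations of all five classes, an
expression matrix whose antisense gene pairs have a controlled Spearman
correlation (Gaussian copula), a BLASTX-like evidence table whose
hit probability is logistic in transcript length with a configurable
AST enrichment ratio, and per-genome homology hit tables realising a
planted conservation truth matrix.

Design notes
------------
Gene models are laid out in disjoint genomic "slots" separated by fixed
gaps, so the only opposite-strand overlaps in a simulated annotation are
the planted ones.  Exon and intron lengths are log-normal (heavy right
tail, as in real annotations); host genes draw the intron carrying the
planted AST from a long-intron model, so the host/non-host largest-intron
contrast of real genomes is reproduced.  All generators are pure functions
of the configuration seed: rerunning writes byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptModel
from .annotation_io import HitRecord
from .expression import ExpressionMatrix
from .intervals import MINUS, PLUS, GenomicInterval

#: spacing between gene slots; nothing planted ever crosses a gap
SLOT_GAP = 500
#: margin between a planted intronic AST and its host intron boundaries
AST_MARGIN = 50


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generators.

    Defaults mirror the analysed study system: a few hundred background
    genes, the five antisense classes dominated by intronic ASTs, 30
    developmental expression samples, zero target correlation for
    antisense pairs (host and AST independently regulated), a 30 %
    baseline protein-evidence rate with a two-fold AST enrichment, and a
    20-genome conservation screen.
    """

    seed: int = 0
    n_genes: int = 200
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "intronic": 20,
            "nested": 10,
            "exonic": 8,
            "utr3": 6,
            "utr5": 4,
        }
    )
    # length models, log scale
    exon_log_mu: float = np.log(200.0)
    exon_log_sigma: float = 0.6
    intron_log_mu: float = np.log(80.0)
    intron_log_sigma: float = 0.8
    host_intron_log_mu: float = np.log(1000.0)
    host_intron_log_sigma: float = 1.0
    # expression
    n_samples: int = 30
    rho_target: float = 0.0
    rho_targets: Optional[dict[tuple[str, str], float]] = None
    expr_log_mu: float = np.log(50.0)
    expr_log_sigma: float = 1.0
    # protein evidence
    evidence_base_rate: float = 0.3
    evidence_enrichment_ratio: float = 2.0
    evidence_length_slope: float = 1.0
    decoy_fraction: float = 0.1
    # conservation screen
    n_genomes: int = 20
    hit_dropout: float = 0.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one artifact stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedPair:
    cls: str
    host_transcript: str
    ast_transcript: str
    host_gene: str
    ast_gene: str


@dataclass
class TruthBundle:
    """Ground truth emitted alongside the synthetic files."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    host_genes: set[str] = field(default_factory=set)
    ast_transcripts: set[str] = field(default_factory=set)
    rho_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    evidence_probs: dict[str, float] = field(default_factory=dict)
    evidence_flags: dict[str, bool] = field(default_factory=dict)
    conservation: Optional[pd.DataFrame] = None  # pairs x genomes bool
    nonconserved_modes: dict[tuple[str, str], str] = field(default_factory=dict)

    def gene_pairs(self, cls: str = "intronic") -> list[tuple[str, str]]:
        return sorted(
            {
                (p.host_gene, p.ast_gene)
                for p in self.planted_pairs
                if p.cls == cls
            }
        )

    def to_json(self, path: str) -> None:
        doc = {
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "host_genes": sorted(self.host_genes),
            "ast_transcripts": sorted(self.ast_transcripts),
            "rho_targets": {
                f"{h}|{a}": r for (h, a), r in self.rho_targets.items()
            },
            "evidence_flags": {
                t: bool(f) for t, f in sorted(self.evidence_flags.items())
            },
            "conservation": (
                None
                if self.conservation is None
                else {
                    "pairs": list(self.conservation.index),
                    "genomes": list(self.conservation.columns),
                    "cells": self.conservation.astype(int).values.tolist(),
                }
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation


def _lognormal_int(rng: np.random.Generator, mu: float, sigma: float, lo: int = 30) -> int:
    return max(lo, int(round(float(rng.lognormal(mu, sigma)))))


def _background_gene(
    cfg: SimulationConfig, rng: np.random.Generator, gid: str, contig: str, start: int
) -> TranscriptModel:
    n_exons = int(rng.integers(1, 6))
    strand = PLUS if rng.random() < 0.5 else MINUS
    exons = []
    pos = start
    for i in range(n_exons):
        elen = _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma)
        exons.append(GenomicInterval(contig, pos, pos + elen, strand))
        pos += elen
        if i < n_exons - 1:
            pos += _lognormal_int(rng, cfg.intron_log_mu, cfg.intron_log_sigma, lo=40)
    return TranscriptModel(f"{gid}.t1", gid, contig, strand, exons)


def _plant_intronic(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    idx: int,
    contig: str,
    start: int,
) -> tuple[list[TranscriptModel], PlantedPair]:
    hg, ag = f"hostI{idx:03d}", f"astI{idx:03d}"
    host_strand = PLUS if rng.random() < 0.5 else MINUS
    ast_strand = MINUS if host_strand == PLUS else PLUS
    # AST: 1-2 exons
    n_ast_ex = int(rng.integers(1, 3))
    ast_lens = [
        _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma)
        for _ in range(n_ast_ex)
    ]
    ast_introns = [
        _lognormal_int(rng, cfg.intron_log_mu, cfg.intron_log_sigma, lo=40)
        for _ in range(n_ast_ex - 1)
    ]
    ast_span = sum(ast_lens) + sum(ast_introns)
    intron_len = max(
        _lognormal_int(rng, cfg.host_intron_log_mu, cfg.host_intron_log_sigma),
        ast_span + 2 * AST_MARGIN,
    )
    e1 = _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma)
    e2 = _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma)
    host_exons = [
        GenomicInterval(contig, start, start + e1, host_strand),
        GenomicInterval(
            contig, start + e1 + intron_len, start + e1 + intron_len + e2, host_strand
        ),
    ]
    slack = intron_len - ast_span - 2 * AST_MARGIN
    offset = start + e1 + AST_MARGIN + int(rng.integers(0, slack + 1))
    ast_exons = []
    pos = offset
    for i, elen in enumerate(ast_lens):
        ast_exons.append(GenomicInterval(contig, pos, pos + elen, ast_strand))
        pos += elen
        if i < n_ast_ex - 1:
            pos += ast_introns[i]
    host = TranscriptModel(f"{hg}.t1", hg, contig, host_strand, host_exons)
    ast = TranscriptModel(f"{ag}.t1", ag, contig, ast_strand, ast_exons)
    return [host, ast], PlantedPair(
        "intronic", host.transcript_id, ast.transcript_id, hg, ag
    )


def _plant_nested(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    idx: int,
    contig: str,
    start: int,
) -> tuple[list[TranscriptModel], PlantedPair]:
    hg, ag = f"hostN{idx:03d}", f"astN{idx:03d}"
    host_strand = PLUS if rng.random() < 0.5 else MINUS
    ast_strand = MINUS if host_strand == PLUS else PLUS
    a1 = _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma)
    intron_len = max(
        _lognormal_int(rng, cfg.host_intron_log_mu, cfg.host_intron_log_sigma),
        a1 + 2 * AST_MARGIN,
    )
    e1 = _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma)
    e2 = max(120, _lognormal_int(rng, cfg.exon_log_mu, cfg.exon_log_sigma))
    host_exons = [
        GenomicInterval(contig, start, start + e1, host_strand),
        GenomicInterval(
            contig, start + e1 + intron_len, start + e1 + intron_len + e2, host_strand
        ),
    ]
    # first AST exon inside the host intron, second one straddling the end
    # of the host's far exon (so the AST is not fully embedded and the
    # reverse ordering embeds nothing)
    ast_ex1 = GenomicInterval(
        contig, start + e1 + AST_MARGIN, start + e1 + AST_MARGIN + a1, ast_strand
    )
    far_end = start + e1 + intron_len + e2
    ast_ex2 = GenomicInterval(contig, far_end - 60, far_end + 140, ast_strand)
    host = TranscriptModel(f"{hg}.t1", hg, contig, host_strand, host_exons)
    ast = TranscriptModel(f"{ag}.t1", ag, contig, ast_strand, [ast_ex1, ast_ex2])
    return [host, ast], PlantedPair(
        "nested", host.transcript_id, ast.transcript_id, hg, ag
    )


def _plant_symmetric(
    cls: str, idx: int, contig: str, start: int
) -> tuple[list[TranscriptModel], PlantedPair]:
    """Exonic / utr3 / utr5 plants: two single-exon CDS-bearing models."""
    tag = {"exonic": "E", "utr3": "U3", "utr5": "U5"}[cls]
    ga, gb = f"g{tag}a{idx:03d}", f"g{tag}b{idx:03d}"
    s = start
    if cls == "exonic":
        # CDS-CDS overlap in the middle
        left = TranscriptModel(
            f"{ga}.t1", ga, contig, PLUS,
            [GenomicInterval(contig, s, s + 400, PLUS)],
            cds=[GenomicInterval(contig, s + 50, s + 350, PLUS)],
        )
        right = TranscriptModel(
            f"{gb}.t1", gb, contig, MINUS,
            [GenomicInterval(contig, s + 300, s + 700, MINUS)],
            cds=[GenomicInterval(contig, s + 320, s + 650, MINUS)],
        )
    elif cls == "utr3":
        # tail-to-tail: + gene's right end meets - gene's left end
        left = TranscriptModel(
            f"{ga}.t1", ga, contig, PLUS,
            [GenomicInterval(contig, s, s + 300, PLUS)],
            cds=[GenomicInterval(contig, s, s + 200, PLUS)],
        )
        right = TranscriptModel(
            f"{gb}.t1", gb, contig, MINUS,
            [GenomicInterval(contig, s + 250, s + 550, MINUS)],
            cds=[GenomicInterval(contig, s + 350, s + 500, MINUS)],
        )
    else:  # utr5, head-to-head: - gene left, + gene right
        left = TranscriptModel(
            f"{ga}.t1", ga, contig, MINUS,
            [GenomicInterval(contig, s, s + 300, MINUS)],
            cds=[GenomicInterval(contig, s + 50, s + 200, MINUS)],
        )
        right = TranscriptModel(
            f"{gb}.t1", gb, contig, PLUS,
            [GenomicInterval(contig, s + 250, s + 550, PLUS)],
            cds=[GenomicInterval(contig, s + 300, s + 500, PLUS)],
        )
    a, b = sorted((left, right), key=lambda t: t.transcript_id)
    return [left, right], PlantedPair(
        cls, a.transcript_id, b.transcript_id, a.gene_id, b.gene_id
    )


def simulate_annotation(cfg: SimulationConfig) -> tuple[AnnotationSet, TruthBundle]:
    """Annotation with planted antisense configurations plus background
    genes, all in disjoint slots of one synthetic contig."""
    rng = cfg.rng(1)
    contig = "chrS1"
    truth = TruthBundle()
    aset = AnnotationSet()
    cursor = SLOT_GAP

    for cls in ("intronic", "nested", "exonic", "utr3", "utr5"):
        for i in range(cfg.planted.get(cls, 0)):
            if cls == "intronic":
                models, pair = _plant_intronic(cfg, rng, i, contig, cursor)
            elif cls == "nested":
                models, pair = _plant_nested(cfg, rng, i, contig, cursor)
            else:
                models, pair = _plant_symmetric(cls, i, contig, cursor)
            for m in models:
                aset.add(m)
            truth.planted_pairs.append(pair)
            if cls == "intronic":
                truth.host_genes.add(pair.host_gene)
                truth.ast_transcripts.add(pair.ast_transcript)
            cursor = max(m.span().end for m in models) + SLOT_GAP

    for i in range(cfg.n_genes):
        g = _background_gene(cfg, rng, f"bg{i:05d}", contig, cursor)
        aset.add(g)
        cursor = g.span().end + SLOT_GAP

    for host, ast in truth.gene_pairs("intronic"):
        truth.rho_targets[(host, ast)] = (
            cfg.rho_targets.get((host, ast), cfg.rho_target)
            if cfg.rho_targets
            else cfg.rho_target
        )
    return aset, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimulationConfig, truth: TruthBundle, annotation: AnnotationSet
) -> ExpressionMatrix:
    """Gene-by-sample matrix; antisense pairs follow a Gaussian copula at
    their target Spearman correlation, all other genes are independent.

    The copula parameter is ``r = 2 sin(pi * rho_S / 6)``, the exact
    inverse of the Spearman rho of a bivariate Gaussian; log-normal
    marginals preserve ranks.
    """
    rng = cfg.rng(2)
    genes = sorted(annotation.genes())
    n = cfg.n_samples
    z = pd.DataFrame(
        rng.standard_normal((len(genes), n)), index=genes
    )
    for (host, ast), rho_s in sorted(truth.rho_targets.items()):
        if abs(rho_s) >= 1:
            raise ValueError(f"|rho| must be < 1, got {rho_s}")
        if host not in z.index or ast not in z.index:
            continue
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        zh = rng.standard_normal(n)
        za = r * zh + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
        z.loc[host] = zh
        z.loc[ast] = za
    values = np.exp(cfg.expr_log_mu + cfg.expr_log_sigma * z)
    values.columns = [f"sample{j:02d}" for j in range(n)]
    return ExpressionMatrix(values.round(4))


# ---------------------------------------------------------------------------
# protein evidence


def evidence_hit_probability(
    cfg: SimulationConfig, length: int, is_ast: bool
) -> float:
    """Logistic-in-log-length hit probability, scaled by the enrichment
    ratio for ASTs (capped at 1)."""
    if cfg.evidence_base_rate <= 0:
        return 0.0
    x = cfg.evidence_length_slope * (np.log(max(length, 1)) - cfg.exon_log_mu)
    base = 1.0 / (1.0 + np.exp(-x) * (1.0 - cfg.evidence_base_rate) / cfg.evidence_base_rate)
    # at length == exp(exon_log_mu) this is exactly the base rate
    p = base * (cfg.evidence_enrichment_ratio if is_ast else 1.0)
    return float(min(p, 1.0))


def simulate_evidence_hits(
    cfg: SimulationConfig, truth: TruthBundle, annotation: AnnotationSet
) -> list[HitRecord]:
    """BLASTX-like hits: one forward-frame hit per flagged transcript,
    plus reverse-frame decoys on a configurable fraction of transcripts
    (removed by the orientation filter)."""
    rng = cfg.rng(3)
    hits: list[HitRecord] = []
    for t in sorted(annotation, key=lambda t: t.transcript_id):
        length = t.exonic_length()
        is_ast = t.transcript_id in truth.ast_transcripts
        p = evidence_hit_probability(cfg, length, is_ast)
        truth.evidence_probs[t.transcript_id] = p
        flagged = bool(rng.random() < p)
        truth.evidence_flags[t.transcript_id] = flagged
        if flagged:
            hits.append(
                HitRecord(
                    query_id=t.transcript_id,
                    subject_id=f"prot_{t.transcript_id}",
                    percent_identity=float(rng.uniform(40, 100)),
                    align_length=max(30, length // 3),
                    query_start=1,
                    query_end=length,
                    subject_start=1,
                    subject_end=max(10, length // 3),
                    evalue=1e-20,
                    bitscore=100.0,
                    query_frame=1,
                    subject_frame=1,
                )
            )
        if rng.random() < cfg.decoy_fraction:
            hits.append(
                HitRecord(
                    query_id=t.transcript_id,
                    subject_id=f"decoy_{t.transcript_id}",
                    percent_identity=float(rng.uniform(30, 60)),
                    align_length=50,
                    query_start=length,
                    query_end=1,
                    subject_start=1,
                    subject_end=50,
                    evalue=1e-6,
                    bitscore=40.0,
                    query_frame=-1,
                    subject_frame=1,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# conservation screen


def default_conservation_truth(
    cfg: SimulationConfig, pair_ids: list[str]
) -> pd.DataFrame:
    """Planted truth matrix: one pair conserved in every genome, the rest
    in a lineage-specific prefix of genomes (most in none or few)."""
    rng = cfg.rng(4)
    genomes = [f"genome{g:02d}" for g in range(cfg.n_genomes)]
    cells = np.zeros((len(pair_ids), cfg.n_genomes), dtype=bool)
    for i in range(len(pair_ids)):
        if i == 0:
            cells[i, :] = True
        else:
            breadth = int(rng.integers(0, max(1, cfg.n_genomes // 3) + 1))
            cells[i, :breadth] = True
    return pd.DataFrame(cells, index=pair_ids, columns=genomes)


def simulate_conservation_hits(
    cfg: SimulationConfig,
    truth: TruthBundle,
    conservation: Optional[pd.DataFrame] = None,
) -> dict[tuple[str, str], tuple[list[HitRecord], list[HitRecord]]]:
    """Per-(pair, genome) host and AST hit tables realising the truth
    matrix.

    Conserved cells get two host hits spanning a region and one AST
    witness hit strictly inside on the opposite strand; non-conserved
    cells get either no AST hits, AST hits outside the span, or AST hits
    on the same strand (mode recorded in the truth bundle).  ``hit_dropout``
    drops each AST witness of a conserved cell with that probability, so
    recall under dropout d is 1 - d per single-witness cell.
    """
    rng = cfg.rng(5)
    if conservation is None:
        pair_ids = [f"{h}|{a}" for h, a in truth.gene_pairs("intronic")]
        if not pair_ids:
            pair_ids = ["pair0"]
        conservation = default_conservation_truth(cfg, pair_ids)
    truth.conservation = conservation

    tables: dict[tuple[str, str], tuple[list[HitRecord], list[HitRecord]]] = {}
    for p in conservation.index:
        for g in conservation.columns:
            contig = f"{g}_ctg_{p}"
            lo = int(rng.integers(1000, 5000))
            span = int(rng.integers(3000, 8000))
            fwd = rng.random() < 0.5
            # host: two hits pinning the span ends (printed 1-based closed)
            if fwd:
                h1 = (lo + 1, lo + 300)
                h2 = (lo + span - 300, lo + span)
            else:
                h1 = (lo + 300, lo + 1)
                h2 = (lo + span, lo + span - 300)
            host_hits = [
                HitRecord(
                    query_id=f"{p}_host",
                    subject_id=contig,
                    percent_identity=80.0,
                    align_length=100,
                    query_start=1,
                    query_end=100,
                    subject_start=a,
                    subject_end=b,
                    evalue=1e-10,
                    bitscore=200.0,
                )
                for a, b in (h1, h2)
            ]
            ast_hits: list[HitRecord] = []
            conserved = bool(conservation.loc[p, g])
            if conserved:
                w_lo = lo + 500 + int(rng.integers(0, span - 1500))
                w = (w_lo + 200, w_lo + 1) if fwd else (w_lo + 1, w_lo + 200)
                if not (cfg.hit_dropout and rng.random() < cfg.hit_dropout):
                    ast_hits.append(
                        HitRecord(
                            query_id=f"{p}_ast",
                            subject_id=contig,
                            percent_identity=75.0,
                            align_length=60,
                            query_start=1,
                            query_end=60,
                            subject_start=w[0],
                            subject_end=w[1],
                            evalue=1e-8,
                            bitscore=120.0,
                        )
                    )
            else:
                mode = ["no_ast", "ast_outside", "ast_same_strand"][
                    int(rng.integers(0, 3))
                ]
                truth.nonconserved_modes[(p, g)] = mode
                if mode == "ast_outside":
                    o_lo = lo + span + 1000
                    w = (o_lo + 200, o_lo + 1) if fwd else (o_lo + 1, o_lo + 200)
                    ast_hits.append(
                        HitRecord(
                            query_id=f"{p}_ast",
                            subject_id=contig,
                            percent_identity=75.0,
                            align_length=60,
                            query_start=1,
                            query_end=60,
                            subject_start=w[0],
                            subject_end=w[1],
                            evalue=1e-8,
                            bitscore=120.0,
                        )
                    )
                elif mode == "ast_same_strand":
                    w_lo = lo + 500
                    w = (w_lo + 1, w_lo + 200) if fwd else (w_lo + 200, w_lo + 1)
                    ast_hits.append(
                        HitRecord(
                            query_id=f"{p}_ast",
                            subject_id=contig,
                            percent_identity=75.0,
                            align_length=60,
                            query_start=1,
                            query_end=60,
                            subject_start=w[0],
                            subject_end=w[1],
                            evalue=1e-8,
                            bitscore=120.0,
                        )
                    )
            tables[(p, g)] = (host_hits, ast_hits)
    return tables


# ---------------------------------------------------------------------------
# auxiliary inputs


def simulate_synteny_blocks(
    cfg: SimulationConfig, n_blocks: int = 500, shift: float = 1.0
) -> np.ndarray:
    """Genomic extents (bp) of background conserved synteny blocks,
    log-normal; *shift* scales the median.

    The default median (800 bp) sits below typical host-gene spans, so the
    simulated study reproduces the direction of the real comparison:
    antisense gene pairs span larger regions than ordinary blocks.
    """
    rng = cfg.rng(6)
    return np.maximum(
        200, (shift * rng.lognormal(np.log(800.0), 0.9, size=n_blocks)).astype(int)
    )


def simulate_cne_hits(
    n_queries: int = 28, n_subjects: int = 27, seed: int = 0
) -> list[HitRecord]:
    """BLASTN-like table with a planted number of distinct query and
    subject identifiers among passing hits (queries in excess of subjects
    share the last subject)."""
    rng = np.random.default_rng(seed)
    hits = []
    for i in range(n_queries):
        sub = min(i, n_subjects - 1)
        lo = int(rng.integers(100, 10_000))
        hits.append(
            HitRecord(
                query_id=f"cne_query{i:03d}",
                subject_id=f"cne_subject{sub:03d}",
                percent_identity=float(rng.uniform(70, 95)),
                align_length=int(rng.integers(100, 400)),
                query_start=1,
                query_end=150,
                subject_start=lo,
                subject_end=lo + 149,
                evalue=1e-5,
                bitscore=90.0,
            )
        )
    return hits
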