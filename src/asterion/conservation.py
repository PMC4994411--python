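"""Cross-genome conservation of antisense gene pairs, called by span
containment of homology hits, plus conserved non-coding element (CNE)
candidate filtering.

A gene pair is called conserved in a target genome when the extent spanned
by the host protein's TBLASTN hits on one contig and strand contains at
least one hit of the antisense protein on the opposite strand of the same
contig.  Hits are filtered at e-value < 0.001 (strict, as in the screen's
protocol).  CNE candidates are the >= 100 bp stretches of a genome left
after masking coding and repetitive sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation_io import HitRecord
from .intervals import (
    GenomicInterval,
    complement_intervals,
    opposite_strand,
)

log = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 0.001
DEFAULT_MIN_CNE_LEN = 100


@dataclass(frozen=True)
class SpanCall:
    """Conservation verdict for one (pair, genome) cell."""

    genome_id: str
    pair_id: str
    conserved: bool
    host_detected: bool = False
    supporting_contig: Optional[str] = None
    host_span: Optional[GenomicInterval] = None
    ast_hit: Optional[GenomicInterval] = None


@dataclass
class ConservationMatrix:
    """Pairs x genomes boolean matrix, each cell backed by one SpanCall."""

    calls: dict[tuple[str, str], SpanCall]
    pair_ids: list[str]
    genome_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        data = {
            g: [
                int(self.calls[(p, g)].conserved) if (p, g) in self.calls else pd.NA
                for p in self.pair_ids
            ]
            for g in self.genome_ids
        }
        return pd.DataFrame(data, index=self.pair_ids)

    def conserved_count(self, pair_id: str) -> int:
        return sum(
            1
            for g in self.genome_ids
            if (pair_id, g) in self.calls and self.calls[(pair_id, g)].conserved
        )


def hit_spans(
    hits: Sequence[HitRecord], evalue_max: float = DEFAULT_EVALUE_MAX
) -> dict[tuple[str, str], GenomicInterval]:
    """Leftmost-to-rightmost extent of passing hits per (contig, strand).

    Only hits with e-value strictly below *evalue_max* contribute; hits on
    opposite strands of one contig never merge.
    """
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    for h in hits:
        if h.evalue >= evalue_max:
            continue
        iv = h.subject_interval
        key = (iv.contig, iv.strand)
        if key in spans:
            lo, hi = spans[key]
            spans[key] = (min(lo, iv.start), max(hi, iv.end))
        else:
            spans[key] = (iv.start, iv.end)
    return {
        (c, s): GenomicInterval(c, lo, hi, s)
        for (c, s), (lo, hi) in spans.items()
    }


def call_pair(
    host_hits: Sequence[HitRecord],
    ast_hits: Sequence[HitRecord],
    genome_id: str = "",
    pair_id: str = "",
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> SpanCall:
    """Span-containment conservation call for one pair in one genome.

    Conserved iff some contig/strand holds a host hit span whose extent
    fully contains >= 1 passing antisense hit on the opposite strand.  The
    lexicographically first satisfying contig is recorded.  A genome
    without host hits is not conserved; ``host_detected`` separates the
    two situations.
    """
    h_spans = hit_spans(host_hits, evalue_max)
    if not h_spans:
        return SpanCall(genome_id, pair_id, conserved=False, host_detected=False)
    ast_ivs = [
        h.subject_interval for h in ast_hits if h.evalue < evalue_max
    ]
    witnesses = []
    for (contig, strand), span in h_spans.items():
        for iv in ast_ivs:
            if (
                iv.contig == contig
                and iv.strand == opposite_strand(strand)
                and span.contains(iv)
            ):
                witnesses.append((contig, span, iv))
    if witnesses:
        contig, span, iv = min(witnesses, key=lambda w: w[0])
        return SpanCall(
            genome_id,
            pair_id,
            conserved=True,
            host_detected=True,
            supporting_contig=contig,
            host_span=span,
            ast_hit=iv,
        )
    return SpanCall(genome_id, pair_id, conserved=False, host_detected=True)


def build_matrix(
    pair_ids: Sequence[str],
    genome_ids: Sequence[str],
    hit_tables: Mapping[tuple[str, str], tuple[Sequence[HitRecord], Sequence[HitRecord]]],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> ConservationMatrix:
    """Conservation matrix over all (pair, genome) cells.

    *hit_tables* maps ``(pair_id, genome_id)`` to the pair's
    ``(host_hits, ast_hits)`` in that genome.  A missing entry leaves the
    cell absent (warned), not false.
    """
    calls: dict[tuple[str, str], SpanCall] = {}
    for p in pair_ids:
        for g in genome_ids:
            if (p, g) not in hit_tables:
                log.warning("no hit tables for pair %s in genome %s", p, g)
                continue
            host_hits, ast_hits = hit_tables[(p, g)]
            calls[(p, g)] = call_pair(
                host_hits, ast_hits, genome_id=g, pair_id=p, evalue_max=evalue_max
            )
    return ConservationMatrix(
        calls=calls, pair_ids=list(pair_ids), genome_ids=list(genome_ids)
    )


def cne_regions(
    contig_lengths: Mapping[str, int],
    coding_mask: Iterable[GenomicInterval],
    repeat_mask: Iterable[GenomicInterval],
    min_len: int = DEFAULT_MIN_CNE_LEN,
) -> list[GenomicInterval]:
    """Unmasked genomic stretches of at least *min_len* bp.

    The per-contig complement of the union of coding and repeat masks,
    filtered to length >= *min_len* (100 bp by default).  Masks must lie
    within contig bounds.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for iv in list(coding_mask) + list(repeat_mask):
        if iv.contig not in contig_lengths:
            raise ValueError(f"mask interval on unknown contig {iv.contig}")
        if iv.end > contig_lengths[iv.contig]:
            raise ValueError(
                f"mask interval [{iv.start},{iv.end}) exceeds length of "
                f"contig {iv.contig}"
            )
        by_contig[iv.contig].append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for contig in sorted(contig_lengths):
        for s, e in complement_intervals(
            by_contig[contig], 0, contig_lengths[contig]
        ):
            if e - s >= min_len:
                out.append(GenomicInterval(contig, s, e))
    return out


def count_cne(
    hits: Sequence[HitRecord], evalue_max: float = DEFAULT_EVALUE_MAX
) -> tuple[int, int]:
    """(#distinct query sequences with a passing hit, #distinct subject
    sequences hit) among BLASTN hits below the e-value threshold."""
    queries = {h.query_id for h in hits if h.evalue < evalue_max}
    subjects = {h.subject_id for h in hits if h.evalue < evalue_max}
    return len(queries), len(subjects)
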