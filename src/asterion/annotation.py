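"""Transcript models and annotation sets.

A :class:`TranscriptModel` is a stranded, multi-exon gene model; introns are
derived as the gaps between consecutive exons.  An :class:`AnnotationSet`
holds transcripts plus a per-contig, per-strand spatial index over their
genomic spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

from .intervals import (
    PLUS,
    MINUS,
    GenomicInterval,
    merge_intervals,
)

log = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript with optional CDS.

    Exons are stored sorted by start and pairwise non-overlapping; exons
    that touch or overlap on input are merged with a warning (corrupt
    assembler output).  All exons and CDS parts must share the
    transcript's contig and strand.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    cds: Optional[list[GenomicInterval]] = None

    def __post_init__(self) -> None:
        if self.strand not in (PLUS, MINUS):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        for ex in self.exons:
            if ex.contig != self.contig:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on contig "
                    f"{ex.contig}, transcript on {self.contig}"
                )
        merged = merge_intervals((e.start, e.end) for e in self.exons)
        if len(merged) != len(self.exons):
            log.warning(
                "transcript %s: merged %d overlapping/touching exons into %d",
                self.transcript_id,
                len(self.exons),
                len(merged),
            )
        self.exons = [
            GenomicInterval(self.contig, s, e, self.strand) for s, e in merged
        ]
        if self.cds is not None:
            cds_merged = merge_intervals((c.start, c.end) for c in self.cds)
            for s, e in cds_merged:
                if not any(
                    ex.start <= s and e <= ex.end for ex in self.exons
                ):
                    raise ValueError(
                        f"transcript {self.transcript_id}: CDS [{s},{e}) "
                        "not contained in exons"
                    )
            self.cds = [
                GenomicInterval(self.contig, s, e, self.strand)
                for s, e in cds_merged
            ]

    def span(self) -> GenomicInterval:
        """Genomic extent ``[first exon start, last exon end)``."""
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons; empty for single-exon models."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.contig, a.end, b.start, self.strand))
        return out

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def terminal_exon_5p(self) -> GenomicInterval:
        """First exon in transcription direction (leftmost for +)."""
        return self.exons[0] if self.strand == PLUS else self.exons[-1]

    def terminal_exon_3p(self) -> GenomicInterval:
        """Last exon in transcription direction (rightmost for +)."""
        return self.exons[-1] if self.strand == PLUS else self.exons[0]

    def utr_intervals(self) -> Optional[tuple[list[tuple[int, int]], list[tuple[int, int]]]]:
        """(5'UTR, 3'UTR) exonic intervals relative to the CDS.

        Returns None when the transcript has no CDS.  UTRs are the exonic
        bases upstream of the CDS start / downstream of the CDS end in
        transcription direction.
        """
        if not self.cds:
            return None
        cds_lo = self.cds[0].start
        cds_hi = self.cds[-1].end
        left = []
        right = []
        for ex in self.exons:
            if ex.start < cds_lo:
                left.append((ex.start, min(ex.end, cds_lo)))
            if ex.end > cds_hi:
                right.append((max(ex.start, cds_hi), ex.end))
        if self.strand == PLUS:
            return left, right
        return right, left


def derive_introns(t: TranscriptModel) -> list[GenomicInterval]:
    """Introns of *t*: the gaps between consecutive sorted exons."""
    return t.introns()


class AnnotationSet:
    """A collection of transcripts with a per-contig/strand span index."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self.transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        sp = t.span()
        key = (t.contig, t.strand)
        self._trees.setdefault(key, IntervalTree()).addi(
            sp.start, sp.end, t.transcript_id
        )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def genes(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def contigs(self) -> set[str]:
        return {t.contig for t in self}

    def query(
        self, contig: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps ``[start, end)`` on *contig*.

        When *strand* is given, only that strand's index is searched.
        """
        strands = (strand,) if strand else (PLUS, MINUS)
        hits = []
        for s in strands:
            tree = self._trees.get((contig, s))
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                hits.append(self.transcripts[iv.data])
        return hits
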