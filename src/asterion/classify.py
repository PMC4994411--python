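"""Classification of opposite-strand transcript overlaps.

Two overlapping transcripts on opposite strands are assigned to one of five
configurations:

``intronic``
    the antisense transcript (AST) lies fully inside a single intron of its
    host;
``nested``
    at least one AST exon lies fully inside a host intron, but the AST as a
    whole does not;
``exonic``
    the coding parts of the two transcripts overlap;
``utr3`` / ``utr5``
    the transcripts overlap only at their 3'-terminal (tail-to-tail) or
    5'-terminal (head-to-head) ends, without shared coding parts.

``intronic`` and ``nested`` are directional (evaluated for both orderings of
the pair); the remaining classes are symmetric and assigned at most once per
unordered pair.  Precedence is intronic > nested > exonic > utr3 > utr5:
intron embedding silences the symmetric classes, and UTR classes require
that the coding parts do not overlap.  When a transcript carries no CDS
annotation (typical for assembler output), its exons stand in for coding
parts and the UTR classes are decided purely from terminal-exon geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .annotation import AnnotationSet, TranscriptModel
from .intervals import MINUS, PLUS, GenomicInterval, intersect_intervals


class AntisenseClass(str, Enum):
    INTRONIC = "intronic"
    NESTED = "nested"
    EXONIC = "exonic"
    UTR3 = "utr3"
    UTR5 = "utr5"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Directional classes: host/AST roles are meaningful.
DIRECTIONAL = (AntisenseClass.INTRONIC, AntisenseClass.NESTED)


@dataclass(frozen=True)
class AntisensePair:
    """One classified overlap.

    For the directional classes ``host``/``ast`` carry biological roles;
    for the symmetric classes the two transcripts are stored in lexicographic
    order and the roles are purely positional.
    """

    host: str
    ast: str
    host_gene: str
    ast_gene: str
    cls: AntisenseClass
    contig: str
    host_intron_index: Optional[int] = None
    host_intron_length: Optional[int] = None


@dataclass
class ClassificationSummary:
    """Per-class counts plus gene-level deduplication for the intronic class."""

    counts: dict[AntisenseClass, int]
    n_pairs: int
    n_unique_asts: int
    n_unique_hosts: int
    n_gene_level_pairs: int

    def to_dict(self) -> dict:
        return {
            "counts": {c.value: n for c, n in self.counts.items()},
            "n_pairs": self.n_pairs,
            "n_unique_asts": self.n_unique_asts,
            "n_unique_hosts": self.n_unique_hosts,
            "n_gene_level_pairs": self.n_gene_level_pairs,
        }


def find_opposite_overlaps(
    a: AnnotationSet,
) -> list[tuple[TranscriptModel, TranscriptModel]]:
    """All unordered transcript pairs on opposite strands of one contig
    whose genomic spans share at least 1 bp."""
    pairs = []
    seen: set[frozenset[str]] = set()
    for t in a:
        if t.strand != PLUS:
            continue
        sp = t.span()
        for other in a.query(t.contig, sp.start, sp.end, strand=MINUS):
            key = frozenset((t.transcript_id, other.transcript_id))
            if key not in seen:
                seen.add(key)
                pairs.append((t, other))
    return pairs


def _intronic_index(host: TranscriptModel, ast: TranscriptModel) -> Optional[int]:
    """Index of the host intron fully containing the AST span, if any."""
    sp = ast.span()
    for i, intron in enumerate(host.introns()):
        if intron.contains(sp):
            return i
    return None


def _is_nested(host: TranscriptModel, ast: TranscriptModel) -> bool:
    """True if >= 1 AST exon lies fully inside some host intron."""
    introns = host.introns()
    return any(
        intron.contains(ex) for ex in ast.exons for intron in introns
    )


def _exon_overlap(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[int, int]]:
    return intersect_intervals(
        [(e.start, e.end) for e in t1.exons],
        [(e.start, e.end) for e in t2.exons],
    )


def _touches(region: list[tuple[int, int]], ivs: list[tuple[int, int]]) -> bool:
    return bool(intersect_intervals(region, ivs))


def _terminal_context(
    t: TranscriptModel, overlap: list[tuple[int, int]]
) -> tuple[bool, bool]:
    """(overlap touches t's 5' end, overlap touches t's 3' end).

    With a CDS the ends are the 5'/3' UTR exonic intervals; without one the
    5'/3'-terminal exons (in transcription direction) stand in.
    """
    utrs = t.utr_intervals()
    if utrs is not None:
        utr5, utr3 = utrs
        return _touches(overlap, utr5), _touches(overlap, utr3)
    e5 = t.terminal_exon_5p()
    e3 = t.terminal_exon_3p()
    return (
        _touches(overlap, [(e5.start, e5.end)]),
        _touches(overlap, [(e3.start, e3.end)]),
    )


def classify_pair(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[AntisensePair]:
    """Classify one opposite-strand overlapping transcript pair.

    Returns 0, 1 or 2 records: the directional classes are evaluated for
    both orderings, the symmetric classes once per unordered pair.  A pair
    whose spans do not overlap yields no record.
    """
    if t1.contig != t2.contig or t1.strand == t2.strand:
        return []
    if not t1.span().overlaps(t2.span()):
        return []

    records: list[AntisensePair] = []
    intronic_seen = 0
    for host, ast in ((t1, t2), (t2, t1)):
        idx = _intronic_index(host, ast)
        if idx is not None:
            intronic_seen += 1
            records.append(
                AntisensePair(
                    host=host.transcript_id,
                    ast=ast.transcript_id,
                    host_gene=host.gene_id,
                    ast_gene=ast.gene_id,
                    cls=AntisenseClass.INTRONIC,
                    contig=host.contig,
                    host_intron_index=idx,
                    host_intron_length=len(host.introns()[idx]),
                )
            )
        elif _is_nested(host, ast):
            records.append(
                AntisensePair(
                    host=host.transcript_id,
                    ast=ast.transcript_id,
                    host_gene=host.gene_id,
                    ast_gene=ast.gene_id,
                    cls=AntisenseClass.NESTED,
                    contig=host.contig,
                )
            )
    if intronic_seen == 2:
        raise AssertionError(
            "mutual intron embedding is geometrically impossible: "
            f"{t1.transcript_id} / {t2.transcript_id}"
        )
    if records:
        return records

    # symmetric classes, once per unordered pair, transcripts in lexicographic
    # order (no biological host for these configurations)
    a, b = sorted((t1, t2), key=lambda t: t.transcript_id)
    overlap = _exon_overlap(a, b)
    cls = AntisenseClass.EXONIC
    if a.cds and b.cds:
        cds_hit = _touches(
            [(c.start, c.end) for c in a.cds],
            [(c.start, c.end) for c in b.cds],
        )
    else:
        cds_hit = False
    if not cds_hit and overlap:
        a5, a3 = _terminal_context(a, overlap)
        b5, b3 = _terminal_context(b, overlap)
        if a3 and b3:
            cls = AntisenseClass.UTR3
        elif a5 and b5:
            cls = AntisenseClass.UTR5
    return [
        AntisensePair(
            host=a.transcript_id,
            ast=b.transcript_id,
            host_gene=a.gene_id,
            ast_gene=b.gene_id,
            cls=cls,
            contig=a.contig,
        )
    ]


def classify_annotation(a: AnnotationSet) -> list[AntisensePair]:
    """Find and classify every opposite-strand overlap in *a*."""
    out: list[AntisensePair] = []
    for t1, t2 in find_opposite_overlaps(a):
        out.extend(classify_pair(t1, t2))
    return out


def summarize(pairs: Iterable[AntisensePair]) -> ClassificationSummary:
    """Count classified pairs per class and deduplicate intronic pairs at
    gene level (unique ASTs, unique host genes, unique gene pairs)."""
    pairs = list(pairs)
    counts = {c: 0 for c in AntisenseClass}
    asts: set[str] = set()
    hosts: set[str] = set()
    gene_pairs: set[tuple[str, str]] = set()
    for p in pairs:
        counts[p.cls] += 1
        if p.cls is AntisenseClass.INTRONIC:
            asts.add(p.ast)
            hosts.add(p.host_gene)
            gene_pairs.add((p.host_gene, p.ast_gene))
    return ClassificationSummary(
        counts=counts,
        n_pairs=len(pairs),
        n_unique_asts=len(asts),
        n_unique_hosts=len(hosts),
        n_gene_level_pairs=len(gene_pairs),
    )


def pairs_to_frame(pairs: Iterable[AntisensePair]) -> pd.DataFrame:
    """Tabular view of classified pairs (one row each), ready for TSV."""
    rows = [
        {
            "host_transcript": p.host,
            "ast_transcript": p.ast,
            "host_gene": p.host_gene,
            "ast_gene": p.ast_gene,
            "class": p.cls.value,
            "host_intron_index": p.host_intron_index,
            "host_intron_length": p.host_intron_length,
            "contig": p.contig,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "host_transcript",
            "ast_transcript",
            "host_gene",
            "ast_gene",
            "class",
            "host_intron_index",
            "host_intron_length",
            "contig",
        ],
    )
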