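"""Reading and writing genome annotations, BLAST tabular hit files and BED.

Internal coordinates are 0-based half-open; GFF3/GTF and BLAST tabular
files are 1-based closed on disk and are converted at the boundary.
GFF3/GTF parsing is delegated to :mod:`gffutils` (in-memory database);
writing is symmetric so that read -> write -> read is the identity on the
in-memory model.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Optional

import gffutils

from .annotation import AnnotationSet, TranscriptModel
from .intervals import MINUS, PLUS, GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationParseError",
    "HitRecord",
    "read_annotation",
    "write_annotation",
    "read_hit_table",
    "write_hit_table",
    "read_bed",
    "write_bed",
]


class AnnotationParseError(ValueError):
    """Structured parse failure; message names the offending line/feature."""


# ---------------------------------------------------------------------------
# GFF3 / GTF


def _has_feature_lines(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_annotation(path: str, dialect: str = "gff3") -> AnnotationSet:
    """Read a GFF3 or GTF annotation into an :class:`AnnotationSet`.

    File coordinates (1-based closed) are converted to internal 0-based
    half-open.  Exons are grouped per transcript and sorted; CDS features
    are attached when present.  Unstranded transcripts, and transcripts
    whose exons disagree on contig or strand, are rejected with a warning.

    Parameters
    ----------
    path : str
        Path to the annotation file.
    dialect : {'gff3', 'gtf'}
        File dialect; controls how exon->transcript linkage is resolved
        (``Parent`` attributes for GFF3, ``transcript_id``/``gene_id``
        attributes for GTF).
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not _has_feature_lines(path):
        return AnnotationSet()

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript_id -> (gene_id, contig, strand)
    meta: dict[str, tuple[str, str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}

    if dialect == "gff3":
        for feat in db.all_features():
            if feat.featuretype in _TRANSCRIPT_TYPES:
                tid = feat.id
                gid = feat.attributes.get("Parent", [tid])[0]
                meta[tid] = (gid, feat.seqid, feat.strand)
        for feat in db.all_features(featuretype=("exon", "CDS")):
            parents = feat.attributes.get("Parent")
            if not parents:
                raise AnnotationParseError(
                    f"{feat.featuretype} without Parent attribute: {feat}"
                )
            for tid in parents:
                if tid not in meta:
                    raise AnnotationParseError(
                        f"{feat.featuretype} refers to unknown transcript "
                        f"{tid!r}: {feat}"
                    )
                target = exons if feat.featuretype == "exon" else cds
                target.setdefault(tid, []).append(
                    (feat.start - 1, feat.end, feat.seqid, feat.strand)
                )
    else:  # gtf
        for feat in db.all_features():
            tids = feat.attributes.get("transcript_id")
            if feat.featuretype in ("gene",):
                continue
            if not tids:
                raise AnnotationParseError(
                    f"{feat.featuretype} without transcript_id: {feat}"
                )
            tid = tids[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            if tid not in meta:
                meta[tid] = (gid, feat.seqid, feat.strand)
            if feat.featuretype == "exon":
                exons.setdefault(tid, []).append(
                    (feat.start - 1, feat.end, feat.seqid, feat.strand)
                )
            elif feat.featuretype == "CDS":
                cds.setdefault(tid, []).append(
                    (feat.start - 1, feat.end, feat.seqid, feat.strand)
                )

    aset = AnnotationSet()
    for tid, (gid, contig, strand) in meta.items():
        ex = exons.get(tid)
        if not ex:
            continue  # transcript feature without exon children
        if strand not in (PLUS, MINUS):
            log.warning("rejecting unstranded transcript %s", tid)
            continue
        if any(c != contig or s != strand for _, _, c, s in ex):
            log.warning(
                "rejecting transcript %s: exon on different contig/strand", tid
            )
            continue
        exon_ivs = [
            GenomicInterval(contig, s, e, strand)
            for s, e, _, _ in sorted(ex)
        ]
        cds_ivs = None
        if tid in cds:
            cds_ivs = [
                GenomicInterval(contig, s, e, strand)
                for s, e, _, _ in sorted(cds[tid])
            ]
        aset.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                contig=contig,
                strand=strand,
                exons=exon_ivs,
                cds=cds_ivs,
            )
        )
    return aset


def write_annotation(aset: AnnotationSet, path: str, dialect: str = "gff3") -> None:
    """Write an :class:`AnnotationSet` as GFF3 or GTF (1-based closed)."""
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines: list[str] = []
    if dialect == "gff3":
        lines.append("##gff-version 3")
    genes = aset.genes()
    all_tids = set(aset.transcripts)
    for gid in sorted(genes):
        ts = sorted(genes[gid], key=lambda t: t.transcript_id)
        # a gene line whose ID collides with a transcript ID (gene_id ==
        # transcript_id, as in assembler output) would make the file invalid
        if dialect == "gff3" and gid not in all_tids:
            gstart = min(t.span().start for t in ts)
            gend = max(t.span().end for t in ts)
            t0 = ts[0]
            lines.append(
                f"{t0.contig}\tasterion\tgene\t{gstart + 1}\t{gend}\t.\t"
                f"{t0.strand}\t.\tID={gid}"
            )
        for t in ts:
            sp = t.span()
            if dialect == "gff3":
                lines.append(
                    f"{t.contig}\tasterion\tmRNA\t{sp.start + 1}\t{sp.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}"
                )
                attr = f"Parent={t.transcript_id}"
            else:
                attr = (
                    f'gene_id "{t.gene_id}"; '
                    f'transcript_id "{t.transcript_id}";'
                )
                lines.append(
                    f"{t.contig}\tasterion\ttranscript\t{sp.start + 1}\t"
                    f"{sp.end}\t.\t{t.strand}\t.\t{attr}"
                )
            for ex in t.exons:
                lines.append(
                    f"{t.contig}\tasterion\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attr}"
                )
            for c in t.cds or ():
                lines.append(
                    f"{t.contig}\tasterion\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t0\t{attr}"
                )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular


@dataclass(frozen=True)
class HitRecord:
    """One row of BLAST tabular output (outfmt 6), coordinates as printed.

    ``subject_interval`` exposes the normalized 0-based half-open subject
    span with the strand inferred from start/end inversion; a negative
    ``query_frame`` marks a hit on the reverse strand of the query.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float = 0.0
    query_frame: Optional[int] = None
    subject_frame: Optional[int] = None

    @property
    def subject_strand(self) -> str:
        return MINUS if self.subject_start > self.subject_end else PLUS

    @property
    def subject_interval(self) -> GenomicInterval:
        lo = min(self.subject_start, self.subject_end)
        hi = max(self.subject_start, self.subject_end)
        return GenomicInterval(self.subject_id, lo - 1, hi, self.subject_strand)

    @property
    def query_reverse(self) -> bool:
        return self.query_frame is not None and self.query_frame < 0


def read_hit_table(path: str, format: str = "outfmt6") -> list[HitRecord]:
    """Parse a BLAST tabular file.

    ``format='outfmt6'`` expects the standard 12 columns; ``'outfmt6_frames'``
    expects two extra columns (query frame, subject frame), i.e. the
    ``-outfmt '6 std qframe sframe'`` dialect.
    """
    if format not in ("outfmt6", "outfmt6_frames"):
        raise ValueError(f"unknown hit-table format {format!r}")
    want_frames = format == "outfmt6_frames"
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            ncol = 14 if want_frames else 12
            if len(cols) < ncol:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected {ncol} columns, got {len(cols)}"
                )
            try:
                rec = HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    align_length=int(cols[3]),
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_start=int(cols[8]),
                    subject_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    query_frame=int(cols[12]) if want_frames else None,
                    subject_frame=int(cols[13]) if want_frames else None,
                )
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-numeric field ({exc})"
                ) from None
            hits.append(rec)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str, frames: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            row = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.align_length),
                "0",
                "0",
                str(h.query_start),
                str(h.query_end),
                str(h.subject_start),
                str(h.subject_end),
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
            ]
            if frames:
                row += [str(h.query_frame or 1), str(h.subject_frame or 1)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open, as on disk)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED needs >= 3 columns"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-numeric BED coordinates"
                ) from None
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# contig\tstart\tend\tname\tscore\tstrand\n")
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\tregion{i}\t0\t{iv.strand}\n"
            )
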