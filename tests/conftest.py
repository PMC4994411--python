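from __future__ import annotations

import numpy as np
import pytest

from asterion.annotation import AnnotationSet, TranscriptModel
from asterion.intervals import MINUS, PLUS, GenomicInterval


def make_t(
    tid: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]] | None = None,
    gene: str | None = None,
    contig: str = "chr1",
) -> TranscriptModel:
    """Shorthand transcript constructor for tests."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid.split(".")[0],
        contig=contig,
        strand=strand,
        exons=[GenomicInterval(contig, s, e, strand) for s, e in exons],
        cds=(
            [GenomicInterval(contig, s, e, strand) for s, e in cds]
            if cds
            else None
        ),
    )


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    contig: str = "chr1",
    contig_len: int = 6000,
    with_cds_prob: float = 0.4,
) -> TranscriptModel:
    """A random small gene model, possibly with a CDS, anywhere on the
    contig (overlaps between calls are intended)."""
    strand = PLUS if rng.random() < 0.5 else MINUS
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, max(1, contig_len - 2500)))
    exons = []
    for i in range(n_exons):
        elen = int(rng.integers(20, 200))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(30, 400))
    cds = None
    if rng.random() < with_cds_prob:
        lo = exons[0][0] + int(rng.integers(0, 40))
        hi = exons[-1][1] - int(rng.integers(0, 40))
        pieces = []
        for s, e in exons:
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                pieces.append((cs, ce))
        cds = pieces or None
    return make_t(tid, strand, exons, cds=cds, contig=contig)


def random_annotation(
    rng: np.random.Generator, n_genes: int, contig_len: int = 6000
) -> AnnotationSet:
    return AnnotationSet(
        random_transcript(rng, f"t{i:03d}", contig_len=contig_len)
        for i in range(n_genes)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20161112)
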