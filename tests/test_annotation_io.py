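import logging

import numpy as np
import pytest

from asterion.annotation import AnnotationSet, derive_introns
from asterion.annotation_io import (
    AnnotationParseError,
    read_annotation,
    read_bed,
    read_hit_table,
    write_annotation,
    write_bed,
)
from asterion.intervals import (
    GenomicInterval,
    complement_intervals,
    merge_intervals,
)

from conftest import make_t, random_annotation


GFF3_TWO_EXON = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=g1.t1
chr1\tsrc\texon\t301\t400\t.\t+\t.\tParent=g1.t1
"""


def test_gff3_coordinate_conversion(tmp_path):
    """1-based closed exon lines 101-200 / 301-400 become 0-based half-open
    [100,200) / [300,400) with one intron [200,300)."""
    p = tmp_path / "a.gff3"
    p.write_text(GFF3_TWO_EXON)
    aset = read_annotation(str(p), dialect="gff3")
    t = aset["g1.t1"]
    assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
    assert [(i.start, i.end) for i in derive_introns(t)] == [(200, 300)]
    assert t.gene_id == "g1"
    assert (t.span().start, t.span().end) == (100, 400)


@pytest.mark.parametrize("dialect", ["gff3", "gtf"])
def test_round_trip_identity(tmp_path, rng, dialect):
    """read -> write -> read is the identity on the in-memory model, and
    the GFF3 and GTF encodings of one model read back identically."""
    aset = random_annotation(rng, 12)
    path = tmp_path / f"out.{dialect}"
    write_annotation(aset, str(path), dialect=dialect)
    back = read_annotation(str(path), dialect=dialect)
    assert set(back.transcripts) == set(aset.transcripts)
    for tid, t in aset.transcripts.items():
        b = back[tid]
        assert b.gene_id == t.gene_id
        assert b.strand == t.strand
        assert [(e.start, e.end) for e in b.exons] == [
            (e.start, e.end) for e in t.exons
        ]
        if t.cds:
            assert [(c.start, c.end) for c in b.cds] == [
                (c.start, c.end) for c in t.cds
            ]


def test_empty_file_gives_empty_set(tmp_path):
    p = tmp_path / "empty.gff3"
    p.write_text("##gff-version 3\n")
    assert len(read_annotation(str(p))) == 0


def test_unknown_parent_raises(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text(
        "chr1\ts\tmRNA\t1\t100\t.\t+\t.\tID=t1\n"
        "chr1\ts\texon\t1\t100\t.\t+\t.\tParent=ghost\n"
    )
    with pytest.raises(AnnotationParseError, match="ghost"):
        read_annotation(str(p))


def test_unstranded_transcript_rejected(tmp_path, caplog):
    p = tmp_path / "u.gff3"
    p.write_text(
        "chr1\ts\tmRNA\t1\t100\t.\t.\t.\tID=t1\n"
        "chr1\ts\texon\t1\t100\t.\t.\t.\tParent=t1\n"
    )
    with caplog.at_level(logging.WARNING):
        aset = read_annotation(str(p))
    assert len(aset) == 0
    assert "unstranded" in caplog.text


@pytest.mark.parametrize(
    "exons,expected",
    [
        ([(0, 100), (500, 600)], [(100, 500)]),
        ([(0, 100)], []),
        ([(0, 10), (20, 30), (40, 50)], [(10, 20), (30, 40)]),
    ],
)
def test_derive_introns(exons, expected):
    t = make_t("t1", "+", exons)
    assert [(i.start, i.end) for i in derive_introns(t)] == expected


def test_overlapping_exons_merged(caplog):
    with caplog.at_level(logging.WARNING):
        t = make_t("t1", "+", [(0, 100), (50, 150), (200, 300)])
    assert [(e.start, e.end) for e in t.exons] == [(0, 150), (200, 300)]
    assert "merged" in caplog.text


def test_exon_intron_lengths_tile_span(rng):
    """sum(exons) + sum(introns) == span length for every transcript."""
    for t in random_annotation(rng, 30):
        total = sum(len(e) for e in t.exons) + sum(
            len(i) for i in t.introns()
        )
        assert total == len(t.span())


def test_spatial_index_matches_bruteforce(rng):
    aset = random_annotation(rng, 40)
    for _ in range(50):
        lo = int(rng.integers(0, 5500))
        hi = lo + int(rng.integers(1, 800))
        got = {t.transcript_id for t in aset.query("chr1", lo, hi)}
        expect = {
            t.transcript_id
            for t in aset
            if t.span().start < hi and lo < t.span().end
        }
        assert got == expect


# --- BLAST tabular ---------------------------------------------------------


def _row(**kw):
    d = dict(
        q="q1", s="s1", pid="90.0", ln="100", mm="0", go="0",
        qs="1", qe="100", ss="1", se="100", ev="1e-10", bs="200",
    )
    d.update(kw)
    return "\t".join(
        [d["q"], d["s"], d["pid"], d["ln"], d["mm"], d["go"],
         d["qs"], d["qe"], d["ss"], d["se"], d["ev"], d["bs"]]
    )


def test_subject_strand_inversion(tmp_path):
    """sstart > send marks a minus-strand subject hit, normalized to
    [999,1200) on '-'."""
    p = tmp_path / "h.tsv"
    p.write_text(_row(ss="1200", se="1000") + "\n")
    (h,) = read_hit_table(str(p))
    iv = h.subject_interval
    assert (iv.start, iv.end, iv.strand) == (999, 1200, "-")
    assert h.subject_strand == "-"


def test_query_frame_orientation(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(
        _row() + "\t-2\t1\n" + _row() + "\t3\t1\n"
    )
    hits = read_hit_table(str(p), format="outfmt6_frames")
    assert [h.query_frame for h in hits] == [-2, 3]
    assert hits[0].query_reverse and not hits[1].query_reverse


def test_standard_12_columns_have_no_frame(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(_row() + "\n")
    (h,) = read_hit_table(str(p), format="outfmt6")
    assert h.query_frame is None


def test_non_numeric_field_names_line(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(_row() + "\n" + _row(ev="oops") + "\n")
    with pytest.raises(AnnotationParseError, match=":2"):
        read_hit_table(str(p))


def test_bed_round_trip(tmp_path):
    ivs = [
        GenomicInterval("c1", 0, 100, "+"),
        GenomicInterval("c2", 50, 1000, "-"),
    ]
    p = tmp_path / "x.bed"
    write_bed(ivs, str(p))
    assert read_bed(str(p)) == ivs


# --- interval algebra ------------------------------------------------------


def test_merge_and_complement_tile_window(rng):
    for _ in range(100):
        n = int(rng.integers(0, 8))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 900))
            ivs.append((s, s + int(rng.integers(1, 150))))
        merged = merge_intervals(ivs)
        comp = complement_intervals(ivs, 0, 1000)
        pieces = sorted(
            [(max(0, s), min(1000, e)) for s, e in merged if s < 1000 and e > 0]
            + comp
        )
        assert sum(e - s for s, e in pieces) == 1000
        for (_, e1), (s2, _) in zip(pieces, pieces[1:]):
            assert e1 == s2


from hypothesis import given, settings, strategies as st

interval_lists = st.lists(
    st.tuples(st.integers(0, 950), st.integers(1, 200)).map(
        lambda p: (p[0], p[0] + p[1])
    ),
    max_size=12,
)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(interval_lists)
def test_merge_is_idempotent_and_disjoint(ivs):
    merged = merge_intervals(ivs)
    assert merge_intervals(merged) == merged
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        assert e1 < s2  # strictly disjoint and sorted


@settings(derandomize=True, max_examples=150, deadline=None)
@given(interval_lists)
def test_complement_is_involutive(ivs):
    comp = complement_intervals(ivs, 0, 1200)
    back = complement_intervals(comp, 0, 1200)
    clipped = merge_intervals(
        (max(0, s), min(1200, e)) for s, e in ivs if s < 1200 and e > 0
    )
    assert back == clipped
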