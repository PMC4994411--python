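"""Independent brute-force oracles used to cross-check the package.

Everything here is computed by a different route than the implementation:
per-base boolean masks instead of interval arithmetic, explicit rank /
enumeration instead of closed forms, and exhaustive triple scans instead
of indexed lookups.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from asterion.annotation import TranscriptModel
from asterion.intervals import MINUS, PLUS


# ---------------------------------------------------------------------------
# per-base antisense classifier


def _masks(t: TranscriptModel, lo: int, hi: int):
    n = hi - lo
    exon = np.zeros(n, dtype=bool)
    for e in t.exons:
        exon[max(0, e.start - lo) : max(0, e.end - lo)] = True
    span = np.zeros(n, dtype=bool)
    sp = t.span()
    span[max(0, sp.start - lo) : max(0, sp.end - lo)] = True
    intron = span & ~exon
    return exon, span, intron


def _utr3_mask(t: TranscriptModel, lo: int, hi: int) -> np.ndarray:
    """Bases of the transcript's 3' context: 3'UTR if a CDS exists, else
    the 3'-terminal exon."""
    n = hi - lo
    out = np.zeros(n, dtype=bool)
    exon, _, _ = _masks(t, lo, hi)
    if t.cds:
        cds_lo, cds_hi = t.cds[0].start, t.cds[-1].end
        idx = np.arange(lo, hi)
        if t.strand == PLUS:
            out = exon & (idx >= cds_hi)
        else:
            out = exon & (idx < cds_lo)
    else:
        e = t.exons[-1] if t.strand == PLUS else t.exons[0]
        out[max(0, e.start - lo) : max(0, e.end - lo)] = True
        out &= exon
    return out


def _utr5_mask(t: TranscriptModel, lo: int, hi: int) -> np.ndarray:
    n = hi - lo
    out = np.zeros(n, dtype=bool)
    exon, _, _ = _masks(t, lo, hi)
    if t.cds:
        cds_lo, cds_hi = t.cds[0].start, t.cds[-1].end
        idx = np.arange(lo, hi)
        if t.strand == PLUS:
            out = exon & (idx < cds_lo)
        else:
            out = exon & (idx >= cds_hi)
    else:
        e = t.exons[0] if t.strand == PLUS else t.exons[-1]
        out[max(0, e.start - lo) : max(0, e.end - lo)] = True
        out &= exon
    return out


def classify_pair_bruteforce(t1: TranscriptModel, t2: TranscriptModel):
    """Per-base reimplementation of the five-class taxonomy.

    Returns a list of (host_id, ast_id, class_label) triples following the
    same precedence semantics as the package: directional intron embedding
    first (both orderings), then one symmetric class per unordered pair.
    """
    if t1.contig != t2.contig or t1.strand == t2.strand:
        return []
    s1, s2 = t1.span(), t2.span()
    if not (s1.start < s2.end and s2.start < s1.end):
        return []
    lo = min(s1.start, s2.start)
    hi = max(s1.end, s2.end)

    results = []
    for host, ast in ((t1, t2), (t2, t1)):
        _, _, h_intron = _masks(host, lo, hi)
        a_exon, a_span, _ = _masks(ast, lo, hi)
        if np.all(h_intron[a_span]):
            results.append((host.transcript_id, ast.transcript_id, "intronic"))
            continue
        nested = False
        for e in ast.exons:
            seg = h_intron[max(0, e.start - lo) : max(0, e.end - lo)]
            if len(seg) == len(e) and np.all(seg):
                nested = True
                break
        if nested:
            results.append((host.transcript_id, ast.transcript_id, "nested"))
    if results:
        return results

    a, b = sorted((t1, t2), key=lambda t: t.transcript_id)
    a_exon, _, _ = _masks(a, lo, hi)
    b_exon, _, _ = _masks(b, lo, hi)
    overlap = a_exon & b_exon
    label = "exonic"
    cds_hit = False
    if a.cds and b.cds:
        a_cds = np.zeros(hi - lo, dtype=bool)
        for c in a.cds:
            a_cds[max(0, c.start - lo) : max(0, c.end - lo)] = True
        b_cds = np.zeros(hi - lo, dtype=bool)
        for c in b.cds:
            b_cds[max(0, c.start - lo) : max(0, c.end - lo)] = True
        cds_hit = bool(np.any(a_cds & b_cds))
    if not cds_hit and overlap.any():
        if np.any(overlap & _utr3_mask(a, lo, hi)) and np.any(
            overlap & _utr3_mask(b, lo, hi)
        ):
            label = "utr3"
        elif np.any(overlap & _utr5_mask(a, lo, hi)) and np.any(
            overlap & _utr5_mask(b, lo, hi)
        ):
            label = "utr5"
    return [(a.transcript_id, b.transcript_id, label)]


# ---------------------------------------------------------------------------
# rank statistics


def spearman_bruteforce(x, y) -> float:
    """Midrank assignment by sorting, then the Pearson formula by hand."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def ranksum_exact_bruteforce(a, b, alternative="a_less") -> float:
    """Exact one-sided p by enumerating every assignment of the pooled
    values to the first sample (tie-free inputs)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    idx = range(len(pooled))
    u_obs = sum(1 for x in a for y in b if x > y)
    count = 0
    total = 0
    for comb in itertools.combinations(idx, n1):
        sel = set(comb)
        u = sum(
            1
            for i in comb
            for j in idx
            if j not in sel and pooled[i] > pooled[j]
        )
        total += 1
        if alternative == "a_less" and u <= u_obs:
            count += 1
        elif alternative == "a_greater" and u >= u_obs:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# conservation span call


def call_pair_bruteforce(host_hits, ast_hits, evalue_max=0.001) -> bool:
    """Enumerate every (contig, strand, AST hit) triple explicitly."""
    from collections import defaultdict

    spans = defaultdict(list)
    for h in host_hits:
        if h.evalue < evalue_max:
            iv = h.subject_interval
            spans[(iv.contig, iv.strand)].append((iv.start, iv.end))
    for (contig, strand), ivs in spans.items():
        lo = min(s for s, _ in ivs)
        hi = max(e for _, e in ivs)
        for h in ast_hits:
            if h.evalue >= evalue_max:
                continue
            iv = h.subject_interval
            if (
                iv.contig == contig
                and iv.strand != strand
                and lo <= iv.start
                and iv.end <= hi
            ):
                return True
    return False


# ---------------------------------------------------------------------------
# mask complement


def cne_regions_bruteforce(contig_len, masks, min_len=100):
    """Per-base complement of the mask union, then run-length scan."""
    covered = np.zeros(contig_len, dtype=bool)
    for s, e in masks:
        covered[s:e] = True
    out = []
    start = None
    for i in range(contig_len + 1):
        free = i < contig_len and not covered[i]
        if free and start is None:
            start = i
        elif not free and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    return out
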