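"""Length-matched resampling test for protein evidence in antisense
transcripts.

The question: do antisense transcripts (ASTs) show more or less homology to
known proteins than random transcripts of the same lengths?  Transcript
length strongly predicts having a BLASTX hit, so the null is built by
stratified resampling: AST lengths are cut into 20 equal-frequency bins and
each null replicate draws, per bin, a bin-size-matched sample (without
replacement) from all transcripts in that length range, recording how many
carry evidence.  The observed flagged-AST count is then ranked against the
resampled null with the (r+1)/(n+1) empirical p-value.

Because the statistic is a count of flagged transcripts and the bin pools
partition the universe, the per-bin count under without-replacement
sampling is exactly hypergeometric; null counts are drawn as sums of
independent hypergeometric variates, which is distributionally identical to
materialising the index samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import AnnotationSet
from .annotation_io import HitRecord
from .stats import empirical_p

DEFAULT_N_BINS = 20
DEFAULT_EVALUE_MAX = 0.001


class BinPoolError(ValueError):
    """A length bin's sampling pool is smaller than the required sample."""


@dataclass
class EvidenceIndex:
    """Per-transcript protein-evidence flag plus transcript length."""

    flags: dict[str, bool]
    lengths: dict[str, int]

    @classmethod
    def build(
        cls,
        annotation: AnnotationSet,
        hits: Iterable[HitRecord],
        evalue_max: float = DEFAULT_EVALUE_MAX,
        require_forward: bool = True,
    ) -> "EvidenceIndex":
        """Flag every transcript with >= 1 qualifying hit.

        A hit qualifies if its e-value is strictly below *evalue_max* and, when
        *require_forward* is set, it lies on the forward strand of the
        query (positive frame); reverse-frame hits are artifacts of the
        opposite strand and are discarded for stranded data.
        Transcript length is the summed exon length.
        """
        lengths = {
            t.transcript_id: t.exonic_length() for t in annotation
        }
        flags = {tid: False for tid in lengths}
        hits = list(hits)
        if require_forward:
            hits = orientation_filter(hits)
        for h in hits:
            if h.evalue < evalue_max and h.query_id in flags:
                flags[h.query_id] = True
        return cls(flags=flags, lengths=lengths)


@dataclass
class EnrichmentResult:
    """Observed flagged-AST count against its length-matched null."""

    observed: int
    null_counts: np.ndarray
    empirical_p_high: float
    empirical_p_low: float
    n_bins: int
    reps: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "empirical_p_high": self.empirical_p_high,
            "empirical_p_low": self.empirical_p_low,
            "n_bins": self.n_bins,
            "reps": self.reps,
            "seed": self.seed,
        }


def orientation_filter(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """Keep only hits on the forward strand of the query (frame > 0).

    Requires the frames dialect; raises if any record lacks frame
    information.
    """
    out = []
    for h in hits:
        if h.query_frame is None:
            raise ValueError(
                "hit table lacks query frames; re-read with "
                "format='outfmt6_frames' (-outfmt '6 std qframe sframe')"
            )
        if h.query_frame > 0:
            out.append(h)
    return out


def length_bins(
    ast_lengths: Sequence[int], n_bins: int = DEFAULT_N_BINS
) -> np.ndarray:
    """Interior bin edges at the 1/n, 2/n, ... (n-1)/n quantiles of AST
    lengths (20 equal-frequency sets by default).

    Duplicate edges from tied lengths collapse, merging the affected bins;
    every AST falls in exactly one bin via ``searchsorted(edges, L,
    side='left')`` (each edge closes its own bin, so distinct lengths
    1..100 yield 20 bins of 5).
    """
    lengths = np.asarray(ast_lengths)
    if len(lengths) < n_bins:
        raise ValueError(
            f"{len(lengths)} ASTs cannot fill {n_bins} length bins; "
            "reduce n_bins"
        )
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(lengths, qs, method="lower")
    return np.unique(edges)


def resampling_test(
    asts: Sequence[str],
    universe: Sequence[str],
    evidence: EvidenceIndex,
    reps: int = 1000,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> EnrichmentResult:
    """Length-matched resampling test of protein evidence in ASTs.

    Parameters
    ----------
    asts, universe : sequence of str
        Transcript ids; ``asts`` must be a subset of ``universe`` and the
        evidence index must cover the universe.
    reps : int
        Number of null resamples (the study default is 1000).
    seed : int
        Seed for the null draws; identical seeds give identical
        ``null_counts``.
    """
    asts = list(asts)
    universe = list(universe)
    ast_set = set(asts)
    if not ast_set <= set(universe):
        raise ValueError("asts must be a subset of the universe")
    missing = [t for t in universe if t not in evidence.flags]
    if missing:
        raise ValueError(f"evidence index missing {len(missing)} transcripts")

    ast_lengths = np.array([evidence.lengths[t] for t in asts])
    uni_lengths = np.array([evidence.lengths[t] for t in universe])
    uni_flags = np.array([evidence.flags[t] for t in universe], dtype=bool)
    observed = int(sum(evidence.flags[t] for t in asts))

    edges = length_bins(ast_lengths, n_bins=n_bins)
    ast_bin = np.searchsorted(edges, ast_lengths, side="left")
    uni_bin = np.searchsorted(edges, uni_lengths, side="left")

    rng = np.random.default_rng(seed)
    null_counts = np.zeros(reps, dtype=int)
    for b in range(len(edges) + 1):
        k = int(np.sum(ast_bin == b))
        if k == 0:
            continue
        in_pool = uni_bin == b
        m = int(np.sum(in_pool))
        if m < k:
            raise BinPoolError(
                f"length bin {b}: pool of {m} transcripts cannot supply "
                f"{k} samples"
            )
        ngood = int(np.sum(uni_flags[in_pool]))
        null_counts += rng.hypergeometric(ngood, m - ngood, k, size=reps)

    return EnrichmentResult(
        observed=observed,
        null_counts=null_counts,
        empirical_p_high=empirical_p(null_counts, observed, "high"),
        empirical_p_low=empirical_p(null_counts, observed, "low"),
        n_bins=n_bins,
        reps=reps,
        seed=seed,
    )
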