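"""Rank-based statistics: Wilcoxon/Mann-Whitney rank-sum comparisons and
empirical p-values from resampled null distributions.

The rank-sum test uses exact enumeration of the U distribution for small
tie-free samples (total n <= 16) and a tie-corrected normal approximation
with continuity correction otherwise.  The exact branch enumerates the
number of arrangements for each U via the standard recurrence
``f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import AnnotationSet

EXACT_MAX_N = 16


def empirical_p(null: Sequence[float], observed: float, tail: str = "high") -> float:
    """(1 + #{null at least as extreme}) / (reps + 1).

    ``tail='high'`` counts null values >= observed, ``'low'`` counts <=.
    The +1 correction keeps the estimate strictly positive.
    """
    null = np.asarray(null)
    if tail == "high":
        r = int(np.sum(null >= observed))
    elif tail == "low":
        r = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + r) / (len(null) + 1)


@dataclass(frozen=True)
class RankSumResult:
    statistic_U: float
    z: float
    p_two_sided: float
    p_one_sided: float
    n1: int
    n2: int
    alternative: str
    method: str

    def to_dict(self) -> dict:
        return {
            "U": self.statistic_U,
            "z": self.z,
            "p_two_sided": self.p_two_sided,
            "p_one_sided": self.p_one_sided,
            "n1": self.n1,
            "n2": self.n2,
            "alternative": self.alternative,
            "method": self.method,
        }


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value, U = 0..m*n."""
    if m == 0 or n == 0:
        return (1,)
    a = _u_counts(m - 1, n)  # last element from sample 2: U gains n... shift
    b = _u_counts(m, n - 1)
    out = [0] * (m * n + 1)
    for u, c in enumerate(a):
        out[u + n] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _exact_pvalues(u1: float, n1: int, n2: int) -> tuple[float, float]:
    """(P(U1 >= u1), P(U1 <= u1)) under the tie-free null."""
    counts = np.array(_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    u = int(round(u1))
    p_hi = counts[u:].sum() / total
    p_lo = counts[: u + 1].sum() / total
    return p_hi, p_lo


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
) -> RankSumResult:
    """Mann-Whitney U test of two independent samples.

    ``alternative='a_greater'`` tests the one-sided hypothesis that values
    in *a* are stochastically larger than in *b*; ``'a_less'`` the reverse.
    Midranks handle ties; the normal approximation uses the tie-corrected
    variance and a 0.5 continuity correction.
    """
    if alternative not in ("two_sided", "a_greater", "a_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires non-empty samples")

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    sd = np.sqrt(var) if var > 0 else np.nan
    z = (u1 - mu) / sd if var > 0 else 0.0

    if not has_ties and n <= EXACT_MAX_N:
        method = "exact"
        p_hi, p_lo = _exact_pvalues(u1, n1, n2)
    else:
        method = "normal"
        if var > 0:
            p_hi = float(sps.norm.sf((u1 - mu - 0.5) / sd))
            p_lo = float(sps.norm.cdf((u1 - mu + 0.5) / sd))
        else:  # all values identical
            p_hi = p_lo = 1.0

    if alternative == "a_greater":
        p_one = p_hi
    elif alternative == "a_less":
        p_one = p_lo
    else:
        p_one = min(p_hi, p_lo)
    p_two = min(1.0, 2.0 * min(p_hi, p_lo))

    return RankSumResult(
        statistic_U=float(u1),
        z=float(z),
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        n1=n1,
        n2=n2,
        alternative=alternative,
        method=method,
    )


def largest_intron_per_gene(
    a: AnnotationSet, host_genes: Optional[set[str]] = None
) -> pd.DataFrame:
    """Per gene, the maximum intron length over all isoforms.

    Single-exon genes get 0.  ``host_genes`` marks which genes carry an
    intronic antisense transcript (classifier output); absent, every gene
    is flagged non-host.

    Returns a DataFrame with columns ``gene_id``, ``is_host``,
    ``largest_intron``.
    """
    host_genes = host_genes or set()
    rows = []
    for gid, transcripts in sorted(a.genes().items()):
        largest = 0
        for t in transcripts:
            for intron in t.introns():
                largest = max(largest, len(intron))
        rows.append(
            {
                "gene_id": gid,
                "is_host": gid in host_genes,
                "largest_intron": largest,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "is_host", "largest_intron"])


def intron_length_comparison(
    table: pd.DataFrame, include_intronless: bool = False
) -> RankSumResult:
    """One-sided rank-sum test that host genes have larger largest introns.

    Genes whose transcripts are all single-exon (largest intron 0) are
    excluded by default: a zero-length "largest intron" is not a length.
    """
    if not include_intronless:
        table = table[table["largest_intron"] > 0]
    hosts = table.loc[table["is_host"], "largest_intron"].to_numpy()
    non = table.loc[~table["is_host"], "largest_intron"].to_numpy()
    return rank_sum_test(hosts, non, alternative="a_greater")


def span_size_comparison(
    pair_spans: Sequence[float], block_sizes: Sequence[float]
) -> RankSumResult:
    """One-sided test that antisense-pair genomic spans exceed conserved
    synteny block sizes."""
    return rank_sum_test(pair_spans, block_sizes, alternative="a_greater")
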