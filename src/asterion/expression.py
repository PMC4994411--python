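"""Expression correlation of antisense gene pairs against a random-pair
null.

If an antisense transcript regulated its host (or vice versa), host/AST
expression across developmental samples should be correlated or
anticorrelated.  This module computes Spearman's rho for each antisense
gene pair and compares the distribution to rhos of randomly drawn gene
pairs from the same matrix; a two-sample Kolmogorov-Smirnov test plus
quantile tables quantify whether pair correlations leave the random range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values (non-negative, as provided)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.data.shape[1] < 3:
            raise ValueError(">= 3 samples required for correlation")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def filter_min_mean(self, min_mean: float) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[self.data.mean(axis=1) >= min_mean])

    def aggregate_to_genes(self, gene_map: dict[str, str]) -> "ExpressionMatrix":
        """Sum transcript-level rows into gene-level rows."""
        groups = self.data.groupby(
            self.data.index.map(lambda t: gene_map.get(t, t))
        ).sum()
        return ExpressionMatrix(groups)


@dataclass
class CorrelationComparison:
    pair_rhos: np.ndarray
    null_rhos: np.ndarray
    n_dropped: int
    ks_statistic: float
    ks_p: float
    pair_quantiles: dict[str, float]
    null_quantiles: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_pairs": len(self.pair_rhos),
            "n_null": len(self.null_rhos),
            "n_dropped": self.n_dropped,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "pair_quantiles": self.pair_quantiles,
            "null_quantiles": self.null_quantiles,
        }


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation (midrank ties): Pearson correlation of
    average ranks.  Returns NaN when either vector is constant (the
    correlation is undefined; callers drop the pair)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def pair_correlations(
    pairs: Iterable[tuple[str, str]], expr: ExpressionMatrix
) -> tuple[list[float], int]:
    """Spearman rho per antisense gene pair.

    Pairs with a gene absent from the matrix are skipped with a log
    message; pairs with constant expression are dropped and counted in the
    returned ``n_dropped``.
    """
    rhos: list[float] = []
    n_dropped = 0
    values = expr.data
    for host, ast in pairs:
        if host not in values.index or ast not in values.index:
            log.info("skipping pair (%s, %s): gene missing from matrix", host, ast)
            continue
        rho = spearman_rho(values.loc[host].to_numpy(), values.loc[ast].to_numpy())
        if np.isnan(rho):
            n_dropped += 1
        else:
            rhos.append(rho)
    return rhos, n_dropped


def _ranked_centered(expr: ExpressionMatrix) -> np.ndarray:
    ranks = sps.rankdata(expr.data.to_numpy(), axis=1)
    return ranks - ranks.mean(axis=1, keepdims=True)


def random_pair_null(
    expr: ExpressionMatrix,
    n_pairs: int,
    reps: int = 1,
    seed: int = 0,
    exclude: Optional[set[frozenset[str]]] = None,
) -> np.ndarray:
    """Spearman rhos of ``reps * n_pairs`` uniformly drawn distinct gene
    pairs (excluding *exclude*), reproducible from *seed*.

    Constant-expression genes yield undefined rhos and are redrawn.
    """
    genes = expr.genes
    if len(genes) < 2:
        raise ValueError(">= 2 genes required")
    exclude = exclude or set()
    rng = np.random.default_rng(seed)
    rc = _ranked_centered(expr)
    ss = np.sqrt((rc**2).sum(axis=1))

    want = n_pairs * reps
    out = np.empty(want)
    filled = 0
    while filled < want:
        i = rng.integers(0, len(genes), size=want)
        j = rng.integers(0, len(genes), size=want)
        for a, b in zip(i, j):
            if filled >= want:
                break
            if a == b or frozenset((genes[a], genes[b])) in exclude:
                continue
            denom = ss[a] * ss[b]
            if denom == 0:
                continue
            out[filled] = float(rc[a] @ rc[b] / denom)
            filled += 1
    return out


def compare_to_null(
    pair_rhos: Sequence[float], null_rhos: Sequence[float], n_dropped: int = 0
) -> CorrelationComparison:
    """Two-sample KS comparison of pair rhos against the random-pair null,
    with 5/25/50/75/95% quantiles of both distributions."""
    pair_rhos = np.asarray(pair_rhos, dtype=float)
    null_rhos = np.asarray(null_rhos, dtype=float)
    if len(pair_rhos) == 0 or len(null_rhos) == 0:
        raise ValueError("both rho sets must be non-empty")
    ks = sps.ks_2samp(pair_rhos, null_rhos)
    qs = [5, 25, 50, 75, 95]
    return CorrelationComparison(
        pair_rhos=pair_rhos,
        null_rhos=null_rhos,
        n_dropped=n_dropped,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        pair_quantiles={f"q{q}": float(np.percentile(pair_rhos, q)) for q in qs},
        null_quantiles={f"q{q}": float(np.percentile(null_rhos, q)) for q in qs},
    )
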