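"""Rank-rank hypergeometric overlap and F_ST-expression correlation.

RRHO compares two ranked lists over a common gene universe without fixing
a significance cutoff: for every pair of rank thresholds (i, j) on a step
grid it counts the overlap of the top-i genes of one list with the top-j
genes of the other and scores it with hypergeometric tail probabilities
(population N, i successes, j draws). Cells are signed -log10 of the
smaller tail: positive for over-enrichment, negative for depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RRHOMap", "rrho", "set_overlap_test", "fst_expression_correlation", "default_step"]


@dataclass
class RRHOMap:
    thresholds1: np.ndarray
    thresholds2: np.ndarray
    values: np.ndarray  # signed -log10 P, shape (len(t1), len(t2))
    overlaps: np.ndarray
    step: int


def default_step(n: int) -> int:
    """Grid granularity: about 100 cells per axis, at least 1."""
    return max(1, n // 100)


def _thresholds(n: int, step: int) -> np.ndarray:
    k = -(-n // step)  # ceil
    return np.minimum(np.arange(1, k + 1) * step, n)


def rrho(list1: Sequence, list2: Sequence, step: int | None = None) -> RRHOMap:
    """Rank-rank hypergeometric overlap map of two ranked gene lists.

    Both lists must be permutations of the same universe of size N >= 2.
    For thresholds (i, j), overlap k = |top-i(list1) & top-j(list2)|;
    over-enrichment P = P(X >= k), depletion P = P(X <= k) for
    hypergeometric X with population N, i successes, j draws.
    """
    l1 = list(list1)
    l2 = list(list2)
    if set(l1) != set(l2) or len(set(l1)) != len(l1):
        raise ValueError("lists must be permutations of one universe")
    n = len(l1)
    if n < 2:
        raise ValueError("universe must have at least 2 genes")
    if step is None:
        step = default_step(n)
    if not (1 <= step <= n):
        raise ValueError("step must lie in [1, N]")
    rank2 = {g: i for i, g in enumerate(l2)}
    # rank in list2 of each element of list1, in list1 order
    r2_of_l1 = np.array([rank2[g] for g in l1])
    t1 = _thresholds(n, step)
    t2 = _thresholds(n, step)
    values = np.zeros((t1.size, t2.size))
    overlaps = np.zeros((t1.size, t2.size), dtype=np.int64)
    for a, i in enumerate(t1):
        in_top_i = np.sort(r2_of_l1[:i])  # list2-ranks of list1's top i
        # overlap with top-j of list2 = count of these ranks < j
        ks = np.searchsorted(in_top_i, t2, side="left")
        overlaps[a] = ks
        # canonical (K, n) order: the tail is symmetric in successes/draws and
        # this keeps the map exactly equal to its transposed counterpart
        kk = np.maximum(i, t2)
        nn = np.minimum(i, t2)
        p_over = stats.hypergeom.sf(ks - 1, n, kk, nn)
        p_under = stats.hypergeom.cdf(ks, n, kk, nn)
        over = p_over <= p_under
        with np.errstate(divide="ignore"):
            values[a] = np.where(
                over,
                -np.log10(np.maximum(p_over, 1e-320)),
                np.log10(np.maximum(p_under, 1e-320)),
            )
    return RRHOMap(t1, t2, values, overlaps, step)


def set_overlap_test(set_a: Set, set_b: Set, universe: Set) -> Tuple[int, float]:
    """Exact hypergeometric over-enrichment test of two gene sets.

    Returns ``(k, P(X >= k))`` with population |universe|, |set_a|
    successes and |set_b| draws.
    """
    if not (set(set_a) <= set(universe) and set(set_b) <= set(universe)):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    k = len(set(set_a) & set(set_b))
    p = float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))
    return k, p


def fst_expression_correlation(
    window_fst: pd.DataFrame,
    expr: pd.DataFrame,
    window: int = 10_000,
) -> Tuple[float, float, int]:
    """Pearson correlation between window F_ST and expression divergence.

    ``window_fst`` carries ``chrom, win_start, win_end, fst``; ``expr``
    carries ``chrom, start, abs_lfc`` per transcript (gene 5' start
    position). Each transcript is assigned the window containing its
    start; transcripts without a finite window value are dropped. Returns
    ``(rho, p, n)``; requires at least 3 paired observations.
    """
    fmap = {}
    for _, row in window_fst.iterrows():
        if np.isfinite(row["fst"]):
            fmap[(row["chrom"], int((row["win_start"] - 1) // window))] = row["fst"]
    xs, ys = [], []
    for _, row in expr.iterrows():
        key = (row["chrom"], int((row["start"] - 1) // window))
        if key in fmap and np.isfinite(row["abs_lfc"]):
            xs.append(fmap[key])
            ys.append(row["abs_lfc"])
    if len(xs) < 3:
        raise ValueError("need at least 3 paired observations")
    r, p = stats.pearsonr(np.asarray(xs, float), np.asarray(ys, float))
    return float(r), float(p), len(xs)
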