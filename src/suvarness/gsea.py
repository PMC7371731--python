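"""Preranked gene-set enrichment: running sum, NES, leading edge.

The enrichment score is the weighted Kolmogorov–Smirnov-like running-sum
statistic: walking down the ranked list, set members ("hits") increment
the sum by |metric|^w normalized over all hits, non-members decrement it
by 1/(N - N_hits). The ES is the running-sum value of largest absolute
excursion; the leading edge contains the set members between the top of
the list and the ES peak (for positive ES), or between the peak and the
bottom (for negative ES).

Significance uses a gene-permutation null — the set's gene labels are
re-drawn uniformly, preserving set size — which applies to any preranked
input regardless of group sizes. NES divides the observed ES by the mean
|ES| of same-sign null scores; the permutation p-value is one-sided with
a +1 pseudo-count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io import GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaResult",
    "rank_genes",
    "enrichment_score",
    "permutation_test",
    "nes_matrix",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a ranking metric, descending, ties broken by ID."""

    gene_ids: tuple[str, ...]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        metric = np.asarray(self.metric_values, dtype=float)
        object.__setattr__(self, "metric_values", metric)
        if len(self.gene_ids) != metric.size:
            raise ValueError("one metric value per gene required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        if metric.size and not np.isfinite(metric).all():
            raise ValueError("ranking metric must be finite")
        if np.any(np.diff(metric) > 0):
            raise ValueError("metric must be non-increasing down the list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaResult:
    gene_set: str
    es: float
    running_sum: np.ndarray
    peak_position: int
    leading_edge: GeneSet
    nes: float | None = None
    p_perm: float | None = None
    hit_positions: tuple[int, ...] = field(default_factory=tuple)


def rank_genes(de: pd.DataFrame, metric: str = "t_stat") -> RankedList:
    """Order a differential-expression table into a descending ranked list.

    Ties in the metric are broken lexicographically by gene ID so the
    ranking — and everything downstream — is bit-reproducible.
    """
    if metric not in de.columns:
        raise ValueError(f"metric column {metric!r} not in DE table")
    if de.index.duplicated().any():
        raise ValueError("duplicate genes in DE table")
    frame = de[[metric]].copy()
    frame["_gene"] = frame.index.astype(str)
    frame = frame.sort_values(by=[metric, "_gene"], ascending=[False, True], kind="mergesort")
    return RankedList(
        gene_ids=tuple(frame["_gene"]),
        metric_values=frame[metric].to_numpy(),
    )


def _hit_weights(metric: np.ndarray, hits: np.ndarray, weight_exponent: float) -> np.ndarray:
    w = np.abs(metric[hits]) ** weight_exponent
    total = 0.0  # sequential sum: keeps results bit-identical to a scalar walk
    for x in w:
        total += float(x)
    if total == 0:  # all-zero metric at the hits: fall back to equal steps
        return np.full(hits.size, 1.0 / hits.size)
    return w / total


def _es_core(
    n: int, hits_sorted: np.ndarray, increments: np.ndarray
) -> tuple[float, int]:
    """ES and peak position without materializing the full running sum.

    The running sum is piecewise linear between hits, so its extrema occur
    either right after a hit increment or just before the next hit (after
    the intervening miss decrements); both candidate sets are evaluated.
    """
    miss = 1.0 / (n - hits_sorted.size)
    cum_inc = np.cumsum(increments)
    # value right after hit j at position p_j: cum_inc[j] - miss * (p_j + 1 - (j+1))
    ranks = np.arange(1, hits_sorted.size + 1)
    after_hit = cum_inc - miss * (hits_sorted + 1 - ranks)
    # value just before hit j (all misses since previous hit applied)
    before_hit = after_hit - increments
    lowest_after = float(after_hit[-1] - miss * (n - hits_sorted[-1] - 1)) if hits_sorted[-1] < n - 1 else None
    candidates = [(abs(v), hits_sorted[j], v) for j, v in enumerate(after_hit)]
    candidates += [
        (abs(v), hits_sorted[j] - 1, v)
        for j, v in enumerate(before_hit)
        if hits_sorted[j] > 0
    ]
    if lowest_after is not None:
        candidates.append((abs(lowest_after), n - 1, lowest_after))
    best = max(candidates, key=lambda t: (t[0], -t[1]))
    return float(best[2]), int(best[1])


def enrichment_score(
    ranked: RankedList,
    gs: GeneSet,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """Weighted running-sum enrichment of ``gs`` in the ranked list.

    Requires 1 <= |set ∩ list| < N (a set covering every ranked gene has no
    misses and the statistic is undefined). The returned result carries the
    full running-sum profile, ES, peak position and leading-edge gene set.
    """
    n = len(ranked)
    member_mask = np.fromiter(
        (g in gs.members for g in ranked.gene_ids), dtype=bool, count=n
    )
    hits = np.flatnonzero(member_mask)
    if hits.size == 0:
        raise ValueError(f"gene set {gs.name!r} has no overlap with the ranked list")
    if hits.size == n:
        raise ValueError(f"gene set {gs.name!r} covers the whole ranked list")
    increments = _hit_weights(ranked.metric_values, hits, weight_exponent)
    miss = 1.0 / (n - hits.size)
    steps = np.full(n, -miss)
    steps[hits] = increments
    # strict left-to-right accumulation (not pairwise summation) so the
    # profile is reproducible bit for bit across platforms
    running = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc += steps[i]
        running[i] = acc
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        edge_positions = hits[hits <= peak]
    else:
        edge_positions = hits[hits >= peak]
    leading = GeneSet(
        name=f"{gs.name}_leading_edge",
        members=frozenset(ranked.gene_ids[i] for i in edge_positions),
        description=f"leading edge of {gs.name}",
    )
    return GseaResult(
        gene_set=gs.name,
        es=es,
        running_sum=running,
        peak_position=peak,
        leading_edge=leading,
        hit_positions=tuple(int(i) for i in hits),
    )


def permutation_test(
    ranked: RankedList,
    gs: GeneSet,
    n_perm: int = 1000,
    seed: int = 1,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """Gene-permutation NES and p-value for one set.

    Null scores come from uniformly re-drawn gene sets of the same size.
    nes = es / mean(|es_null|) over null scores sharing the observed sign;
    p = (1 + #{same-sign |es_null| >= |es|}) / (n_same_sign + 1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    result = enrichment_score(ranked, gs, weight_exponent)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    size = len(result.hit_positions)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=size, replace=False))
        inc = _hit_weights(ranked.metric_values, pos, weight_exponent)
        null_es[i], _ = _es_core(n, pos, inc)
    same_sign = null_es[np.sign(null_es) == np.sign(result.es)] if result.es != 0 else null_es
    if same_sign.size == 0:
        log.warning("no same-sign null scores for %s; p floored", gs.name)
        result.nes = float("nan")
        result.p_perm = 1.0 / (n_perm + 1)
        return result
    result.nes = float(result.es / np.mean(np.abs(same_sign)))
    exceed = int(np.sum(np.abs(same_sign) >= abs(result.es)))
    result.p_perm = (1 + exceed) / (same_sign.size + 1)
    return result


def nes_matrix(
    comparisons: Sequence[tuple[RankedList, str]],
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int = 1,
    weight_exponent: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """NES of every gene set in every comparison, clustered for display.

    Rows (gene sets) are ordered by complete-linkage hierarchical
    clustering of their NES profiles under Euclidean distance; a set with
    no overlap in some comparison gets a missing NES, excluded from the
    distances. Returns (sets x comparisons NES frame, clustered row order).
    """
    if len(comparisons) < 1 or len(gene_sets) < 2:
        raise ValueError("need >=1 comparison and >=2 gene sets")
    values = np.full((len(gene_sets), len(comparisons)), np.nan)
    for j, (ranked, _label) in enumerate(comparisons):
        for i, gs in enumerate(gene_sets):
            try:
                res = permutation_test(
                    ranked, gs, n_perm=n_perm, seed=seed, weight_exponent=weight_exponent
                )
            except ValueError:
                log.warning("set %s has no overlap in comparison %d", gs.name, j)
                continue
            values[i, j] = res.nes
    frame = pd.DataFrame(
        values,
        index=[gs.name for gs in gene_sets],
        columns=[label for _, label in comparisons],
    )
    order = _cluster_rows(values)
    ordered_names = [frame.index[i] for i in order]
    return frame, ordered_names


def _cluster_rows(values: np.ndarray) -> list[int]:
    n = values.shape[0]
    if n <= 2:
        return list(range(n))
    dist = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.isfinite(values[i]) & np.isfinite(values[j])
            if shared.any():
                dist[k] = float(np.sqrt(np.sum((values[i][shared] - values[j][shared]) ** 2)))
            else:
                dist[k] = np.nanmax(np.abs(values)) * values.shape[1] + 1.0
            k += 1
    Z = linkage(dist, method="complete")
    return [int(i) for i in leaves_list(Z)]
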