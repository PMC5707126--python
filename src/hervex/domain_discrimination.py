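"""Domain-level discrimination of specimens.

Catalog counts are binned by domain type and normalized by HQ reads,
log2-transformed with a pseudocount and mean-centered along the domain
axis, then specimens are agglomeratively clustered on 1 - Pearson
correlation with average linkage. The root split of the dendrogram is
tested for group separation with the two-tailed Fisher exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import TestResult, fisher_exact_2x2

__all__ = [
    "DomainProfile",
    "ClusterSplit",
    "domain_hit_rates",
    "log2_center",
    "cluster_specimens",
    "split_and_test",
]


@dataclass
class DomainProfile:
    specimens: list[str]
    domain_types: list[str]
    values: np.ndarray  # domains x specimens, log2, row-centered

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.domain_types), len(self.specimens)):
            raise ValueError("matrix shape does not match labels")
        if np.abs(self.values.mean(axis=1)).max() > 1e-9:
            raise ValueError("rows must be mean-centered")


@dataclass
class ClusterSplit:
    merges: list[tuple[int, int, float]]  # (node_a, node_b, height)
    left_members: list[str]
    right_members: list[str]
    contingency: list[list[int]]
    fisher: TestResult
    tested_groups: tuple[str, str] = ("demyelination", "control")


def domain_hit_rates(counts: Mapping[str, Mapping[str, int]],
                     entry_domains: Mapping[str, str],
                     hq_counts: Mapping[str, int]) -> pd.DataFrame:
    """Domain-type x specimen matrix: summed entry counts over HQ reads."""
    domains = sorted(set(entry_domains.values()))
    specimens = list(counts)
    mat = np.zeros((len(domains), len(specimens)))
    dindex = {d: i for i, d in enumerate(domains)}
    for j, spec in enumerate(specimens):
        hq = hq_counts[spec]
        for code, c in counts[spec].items():
            if code not in entry_domains:
                raise KeyError(f"entry {code!r} has no domain mapping")
            mat[dindex[entry_domains[code]], j] += c / hq
    return pd.DataFrame(mat, index=domains, columns=specimens)


def log2_center(rates: pd.DataFrame, pseudocount: float | None = None,
                hq_counts: Mapping[str, int] | None = None) -> DomainProfile:
    """log2(rate + pseudocount), then mean-center each domain row.

    The default pseudocount is half a hit at the median HQ depth,
    0.5 / median(hq), keeping zero rates finite.
    """
    if pseudocount is None:
        if hq_counts is None:
            raise ValueError("supply a pseudocount or hq_counts to derive one")
        pseudocount = 0.5 / float(np.median(list(hq_counts.values())))
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = np.log2(rates.to_numpy(dtype=float) + pseudocount)
    values = values - values.mean(axis=1, keepdims=True)
    return DomainProfile(list(rates.columns), list(rates.index), values)


def _pearson_distance(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - r between columns; zero-variance columns get r = 0."""
    n = values.shape[1]
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("zero-variance specimen profile; correlations set to 0",
                      stacklevel=2)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if degenerate[i] or degenerate[j]:
                d = 1.0
            else:
                r = float(np.corrcoef(values[:, i], values[:, j])[0, 1])
                d = 1.0 - r
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_specimens(profile: DomainProfile) -> list[tuple[int, int, float]]:
    """Average-linkage agglomeration on 1 - Pearson distance.

    Returns the merge history as (node_a, node_b, height) with leaves
    numbered 0..n-1 and internal nodes n, n+1, ... in merge order. Ties are
    broken by the smallest (a, b) pair for determinism.
    """
    n = len(profile.specimens)
    if n < 2 or len(profile.domain_types) < 2:
        raise ValueError("need >= 2 specimens and >= 2 domain types")
    dist = _pearson_distance(profile.values)

    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # node -> leaves
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, h))
        leaves_a, leaves_b = active.pop(a), active.pop(b)
        new_leaves = leaves_a + leaves_b
        for node, leaves in active.items():
            # average linkage over the underlying leaf distances
            pair = tuple(sorted((node, a)))
            pair_b = tuple(sorted((node, b)))
            da, db = d.pop(pair), d.pop(pair_b)
            d[(min(node, next_id), max(node, next_id))] = (
                da * len(leaves_a) + db * len(leaves_b)) / len(new_leaves)
        d.pop((a, b), None)
        active[next_id] = new_leaves
        next_id += 1
    return merges


def _node_leaves(merges: Sequence[tuple[int, int, float]], n: int,
                 node: int) -> list[int]:
    if node < n:
        return [node]
    a, b, _ = merges[node - n]
    return _node_leaves(merges, n, a) + _node_leaves(merges, n, b)


def split_and_test(merges: Sequence[tuple[int, int, float]],
                   specimens: Sequence[str], design: pd.DataFrame,
                   groups_to_test: tuple[str, str] = ("demyelination", "control")
                   ) -> ClusterSplit:
    """Cut the dendrogram at its final merge and Fisher-test the 2x2 table.

    The contingency table is restricted to the two groups under test; the
    "left" side is the one holding more members of the first tested group.
    """
    n = len(specimens)
    a, b, _ = merges[-1]
    side_a = [specimens[i] for i in _node_leaves(merges, n, a)]
    side_b = [specimens[i] for i in _node_leaves(merges, n, b)]
    groups = dict(zip(design["specimen_id"].astype(str), design["group"].astype(str)))
    g1, g2 = groups_to_test
    for g in groups_to_test:
        if not any(groups.get(s) == g for s in side_a + side_b):
            raise ValueError(f"group {g!r} absent from the dendrogram")

    def tally(side: Sequence[str]) -> tuple[int, int]:
        return (sum(groups.get(s) == g1 for s in side),
                sum(groups.get(s) == g2 for s in side))

    a1, a2 = tally(side_a)
    b1, b2 = tally(side_b)
    if a1 >= b1:
        left, right = side_a, side_b
        table = [[a1, b1], [a2, b2]]
    else:
        left, right = side_b, side_a
        table = [[b1, a1], [b2, a2]]
    fisher = fisher_exact_2x2(table)
    return ClusterSplit(list(merges), left, right, table, fisher, groups_to_test)
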