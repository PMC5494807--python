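"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every statistic by direct
enumeration or a literal walk, independent of the package's vectorised
implementations, so tests compare two routes to the same number.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stromaging as sg

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles

def running_sum_oracle(n: int, hit_positions, weights=None):
    """Literal top-to-bottom walk; hit_positions are 0-based ranks.

    Returns (es, trace).  Ties between the positive and negative
    extremum resolve to the negative one, matching the documented
    convention.
    """
    hits = set(int(h) for h in hit_positions)
    nh = len(hits)
    assert 0 < nh < n
    if weights is None:
        w = {h: 1.0 for h in hits}
    else:
        w = {h: float(weights[h]) for h in hits}
    total = sum(w.values())
    trace = []
    value = 0.0
    for i in range(n):
        if i in hits:
            value += w[i] / total
        else:
            value -= 1.0 / (n - nh)
        trace.append(value)
    hi, lo = max(trace), min(trace)
    es = hi if hi > -lo + 1e-9 else lo  # ties resolve to the negative side
    return es, np.array(trace)


def exhaustive_gene_label_p(n: int, n_hits: int, observed_positions, weights=None):
    """Two-sided gene-label permutation p by full enumeration."""
    es_obs, _ = running_sum_oracle(n, observed_positions, weights)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_hits):
        es, _ = running_sum_oracle(n, combo, weights)
        if abs(es) >= abs(es_obs) - 1e-12:
            count += 1
        total += 1
    return count / total, es_obs


def wilcoxon_enumeration_p(a, b):
    """Two-sided rank-sum p by enumerating all group assignments.

    p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|) under random assignment
    of the pooled values to the two groups (handles ties by mid-ranks).
    """
    a = list(a)
    b = list(b)
    pooled = np.array(a + b, dtype=float)
    n1 = len(a)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty_like(pooled)
    # mid-ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    center = n1 * (n - n1) / 2.0

    def u_stat(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_stat(range(n1))
    d_obs = abs(u_obs - center)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        if abs(u_stat(combo) - center) >= d_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def exact_ranksum_attainable_level(n1: int, n2: int, alpha: float) -> float:
    """P(exact two-sided rank-sum p < alpha) under the tie-free null.

    Builds the exact distribution of the rank sum W of group 1 by
    dynamic programming over which ranks the group occupies, converts to
    the Mann-Whitney U, and integrates the attainable p-values.
    """
    n = n1 + n2
    # ways[k][w]: number of k-subsets of ranks 1..r summing to w
    ways = [[0] * (n * n1 + 1) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            row_k, row_km1 = ways[k], ways[k - 1]
            for w in range(n * n1, r - 1, -1):
                row_k[w] += row_km1[w - r]
    total = math.comb(n, n1)
    w_min = n1 * (n1 + 1) // 2
    pmf = {w - w_min: ways[n1][w] / total for w in range(w_min, n1 * n + 1)
           if ways[n1][w]}
    center = n1 * n2 / 2.0
    level = 0.0
    for u, prob in pmf.items():
        d = abs(u - center)
        p = sum(q for v, q in pmf.items() if abs(v - center) >= d - 1e-9)
        if p < alpha:
            level += prob
    return level


def hypergeom_enumeration_p(k, n_study, n_external, universe):
    """Upper-tail overlap p by direct combinatorial summation."""
    total = math.comb(universe, n_external)
    acc = 0
    for i in range(k, min(n_study, n_external) + 1):
        acc += math.comb(n_study, i) * math.comb(universe - n_study, n_external - i)
    return acc / total


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def curated_sets():
    return sg.load_curated_sets()


@pytest.fixture(scope="session")
def de_fixture_records():
    return sg.load_de_table()


@pytest.fixture(scope="session")
def fixture_ranking():
    """The published 227-gene list ranked by signed fold change."""
    from stromaging.pipeline import replay_de_fixture

    return sg.rank_genes(replay_de_fixture())


@pytest.fixture()
def small_matrix():
    """3 genes x 4 samples with a hand-checkable fold-change pattern."""
    values = pd.DataFrame(
        {
            "s1": [3.0, 2.0, 5.0],
            "s2": [3.0, 2.0, 5.0],
            "s3": [2.0, 3.0, 5.0],
            "s4": [2.0, 3.0, 5.0],
        },
        index=["GUP", "GDOWN", "GFLAT"],
    )
    groups = pd.Series(
        ["young", "young", "old", "old"], index=["s1", "s2", "s3", "s4"]
    )
    return sg.ExpressionMatrix(values, groups)


def make_ranked(n: int, seed: int = 0) -> sg.RankedList:
    """A strictly decreasing synthetic ranking of n pseudo-genes."""
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    symbols = tuple(f"G{i:04d}" for i in range(n))
    return sg.RankedList(symbols, scores)
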