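"""Running-sum gene-set enrichment with a permutation null and FDR.

Genes are ranked by signed fold change, descending: the most up-in-young
gene first, the most up-in-old gene last.  Walking the ranking from top
to bottom, a running sum is incremented on every gene belonging to the
query set ("hit") and decremented on every other gene ("miss"):

* unweighted (classic Kolmogorov-Smirnov statistic, the default):
  hits add ``1 / n_hits``, misses subtract ``1 / (N - n_hits)``;
* weighted: hits add ``|score_i| / sum of hit |score|``, misses subtract
  ``1 / (N - n_hits)``.

The enrichment score (ES) is the signed maximum-magnitude deviation of
this walk and lies in [-1, 1].  A **positive** ES means the set is
concentrated among genes up-regulated in the *young* group (top of the
ranking); a **negative** ES means concentration among genes up-regulated
in the *old* group.  Significance comes from an empirical permutation
null — by default random gene sets of the same size drawn from the
ranked universe ("gene-label" scheme), optionally by re-deriving the
ranking under shuffled sample labels ("phenotype" scheme) — and q-values
are Benjamini-Hochberg adjusted across the tested sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("unweighted", "weighted")
SCHEMES = ("gene_label", "phenotype")


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a signed ranking metric, descending.

    Attributes
    ----------
    symbols : tuple of str
        Unique gene symbols, best (most up-in-young) first.
    scores : numpy.ndarray
        The per-gene metric (signed fold change), non-increasing.
    """

    symbols: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.symbols) != scores.size:
            raise ValueError("symbols and scores differ in length")
        if scores.size == 0:
            raise ValueError("empty ranking")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols in ranking")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")

    @property
    def N(self) -> int:
        return len(self.symbols)

    def positions(self, symbols: Iterable[str]) -> np.ndarray:
        """Sorted 0-based ranks of the given symbols that are present."""
        index = {s: i for i, s in enumerate(self.symbols)}
        pos = sorted(index[s] for s in symbols if s in index)
        return np.asarray(pos, dtype=np.int64)

    def reversed(self) -> "RankedList":
        return RankedList(tuple(reversed(self.symbols)), -self.scores[::-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"symbol": self.symbols, "score": self.scores})


def rank_genes(de) -> RankedList:
    """Rank genes by signed fold change, descending.

    Ties are broken lexicographically by symbol so the ranking is
    deterministic.  Accepts a fitted differential-expression results
    object or any DataFrame with a symbol index and a ``signed_fc``
    column.
    """
    table = de.table if hasattr(de, "table") else de
    if table.empty:
        raise ValueError("cannot rank an empty table")
    if table.index.has_duplicates:
        raise ValueError("duplicate symbols in DE table")
    symbols = table.index.to_numpy(dtype=object)
    scores = table["signed_fc"].to_numpy(dtype=float)
    order = np.lexsort((symbols, -scores))
    return RankedList(tuple(symbols[order]), scores[order])


def _resolve_members(gene_set, include_provisional: bool) -> frozenset[str]:
    if isinstance(gene_set, GeneSet):
        return gene_set.members(include_provisional)
    return frozenset(gene_set)


def _hit_weights(ranked: RankedList, weight_mode: str) -> np.ndarray | None:
    if weight_mode == "unweighted":
        return None
    if weight_mode == "weighted":
        return np.abs(ranked.scores)
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def _es_from_positions(
    pos: np.ndarray, N: int, weights: np.ndarray | None
) -> np.ndarray:
    """ES for each row of `pos` (sorted hit ranks, shape (m, n_hits)).

    The walk's local maxima occur immediately after hits and local minima
    immediately before hits, so only those 2*n_hits candidate deviations
    need inspecting.  Exact |max| = |min| ties resolve to the negative
    (bottom) extremum.
    """
    pos = np.atleast_2d(pos)
    m, nh = pos.shape
    if not 1 <= nh < N:
        raise ValueError(f"need 1 <= n_hits < N, got n_hits={nh}, N={N}")
    miss = 1.0 / (N - nh)
    j = np.arange(nh, dtype=float)
    if weights is None:
        cum = (j + 1.0) / nh
        step = np.full((1, nh), 1.0 / nh)
        top = cum[None, :] - (pos - j[None, :]) * miss
    else:
        w = weights[pos]
        cw = np.cumsum(w, axis=1)
        total = cw[:, -1:]
        if np.any(total <= 0):
            raise ValueError("weighted mode requires a positive total hit weight")
        cum = cw / total
        step = w / total
        top = cum - (pos - j[None, :]) * miss
    bottom = top - step
    max_top = top.max(axis=1)
    min_bottom = bottom.min(axis=1)
    # a 1e-9 guard keeps exact |max| == |min| ties stable across float
    # evaluation orders; ties resolve to the negative excursion
    return np.where(max_top > -min_bottom + 1e-9, max_top, min_bottom)


def enrichment_score(
    ranked: RankedList,
    gene_set,
    weight_mode: str = "unweighted",
    include_provisional: bool = False,
) -> tuple[float, np.ndarray]:
    """Enrichment score and full running-sum trace for one set.

    Returns
    -------
    es : float
        Signed maximum-magnitude deviation of the running sum, in
        [-1, 1].  Negative = enriched among genes up-regulated in old.
    running_sum : numpy.ndarray
        The deviation after each of the N ranking positions (ends at 0
        in unweighted mode).
    """
    members = _resolve_members(gene_set, include_provisional)
    pos = ranked.positions(members)
    nh = pos.size
    N = ranked.N
    if nh == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    if nh == N:
        raise ValueError("gene set covers the whole universe; ES undefined")
    weights = _hit_weights(ranked, weight_mode)
    hit_mask = np.zeros(N, dtype=bool)
    hit_mask[pos] = True
    steps = np.full(N, -1.0 / (N - nh))
    if weights is None:
        steps[hit_mask] = 1.0 / nh
    else:
        total = weights[pos].sum()
        if total <= 0:
            raise ValueError("weighted mode requires a positive total hit weight")
        steps[hit_mask] = weights[hit_mask] / total
    running = np.cumsum(steps)
    es = float(_es_from_positions(pos[None, :], N, weights)[0])
    return es, running


def _sample_positions(
    rng: np.random.Generator, n_perm: int, N: int, nh: int
) -> np.ndarray:
    """Draw `n_perm` sorted hit-position vectors without replacement."""
    out = np.empty((n_perm, nh), dtype=np.int64)
    # chunked argpartition over random keys keeps memory bounded
    chunk = max(1, min(n_perm, 4_000_000 // max(N, 1)))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        keys = rng.random((c, N))
        idx = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
        idx.sort(axis=1)
        out[done : done + c] = idx
        done += c
    return out


def permutation_test(
    ranked: RankedList,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "gene_label",
    weight_mode: str = "unweighted",
    include_provisional: bool = False,
    matrix=None,
    fc_mode: str = "ratio_of_means",
    exhaustive: bool = False,
) -> float:
    """Two-sided empirical p-value for a set's enrichment score.

    gene_label scheme (default)
        The ranking is held fixed and random sets of the same size are
        drawn from the universe.  With ``exhaustive=True`` all
        ``C(N, n_hits)`` placements are enumerated instead of sampled
        (only sensible for tiny problems); the sampled p uses the
        add-one correction ``(1 + #{|ES*| >= |ES|}) / (1 + n_perm)`` so
        it is never 0.
    phenotype scheme
        Sample group labels are shuffled, fold changes recomputed, the
        ranking rebuilt and the ES recomputed; requires `matrix`.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not exhaustive and seed is None:
        raise ValueError("an explicit seed is required for sampled permutations")
    members = _resolve_members(gene_set, include_provisional)
    es_obs, _ = enrichment_score(ranked, members, weight_mode, include_provisional=True)
    nh = ranked.positions(members).size
    N = ranked.N

    if scheme == "gene_label":
        weights = _hit_weights(ranked, weight_mode)
        if exhaustive:
            combos = np.array(
                list(itertools.combinations(range(N), nh)), dtype=np.int64
            )
            es_all = _es_from_positions(combos, N, weights)
            hits = int(np.sum(np.abs(es_all) >= abs(es_obs) - 1e-12))
            return hits / len(combos)
        rng = np.random.default_rng(seed)
        pos = _sample_positions(rng, n_perm, N, nh)
        es_perm = _es_from_positions(pos, N, weights)
    else:
        if matrix is None:
            raise ValueError("phenotype scheme requires the expression matrix")
        es_perm = _phenotype_null(
            matrix, members, n_perm, seed, weight_mode, fc_mode
        )
    exceed = int(np.sum(np.abs(es_perm) >= abs(es_obs) - 1e-12))
    return (1 + exceed) / (1 + len(es_perm))


def _phenotype_null(
    matrix, members, n_perm: int, seed: int | None, weight_mode: str, fc_mode: str
) -> np.ndarray:
    """ES null distribution under shuffled sample-group labels."""
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float)
    symbols = matrix.values.index.to_numpy(dtype=object)
    lin = np.exp2(values)
    n_young = int((matrix.groups == "young").sum())
    n_samples = values.shape[1]
    member_mask = np.isin(symbols, list(members))
    if not member_mask.any():
        raise ValueError("gene set has no overlap with the matrix genes")
    es = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_samples)
        iy, io = perm[:n_young], perm[n_young:]
        if fc_mode == "ratio_of_means":
            r = lin[:, iy].mean(axis=1) / lin[:, io].mean(axis=1)
        else:
            r = 2.0 ** (values[:, iy].mean(axis=1) - values[:, io].mean(axis=1))
        fc = np.where(r >= 1.0, r, -1.0 / r)
        order = np.lexsort((symbols, -fc))
        pos = np.flatnonzero(member_mask[order])
        weights = np.abs(fc[order]) if weight_mode == "weighted" else None
        es[i] = _es_from_positions(pos[None, :], len(symbols), weights)[0]
    return es


@dataclass
class EnrichmentRecord:
    """Per-set enrichment outcome."""

    set_name: str
    es: float
    n_hits: int
    p_perm: float
    q_fdr: float = field(default=float("nan"))
    running_sum: np.ndarray | None = field(default=None, repr=False)


def fdr_adjust(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Benjamini-Hochberg step-up over a batch of permutation p-values."""
    if not records:
        raise ValueError("no results to adjust")
    pvals = np.array([r.p_perm for r in records])
    q = multipletests(pvals, method="fdr_bh")[1]
    for rec, qv in zip(records, q):
        rec.q_fdr = float(qv)
    return list(records)


@dataclass
class EnrichmentResults:
    """Fitted gene-set enrichment over a batch of sets.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per tested set: ``es``, ``n_hits``, ``p_perm``,
        ``q_fdr``; indexed by set name, in the collection's order.
    records : list of EnrichmentRecord
        Per-set results with the running-sum traces.
    skipped : dict
        Sets not tested, mapped to the reason.
    """

    records: list[EnrichmentRecord]
    skipped: dict[str, str]
    n_perm: int
    seed: int
    weight_mode: str
    scheme: str
    alpha: float = 0.05

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "es": [r.es for r in self.records],
                "n_hits": [r.n_hits for r in self.records],
                "p_perm": [r.p_perm for r in self.records],
                "q_fdr": [r.q_fdr for r in self.records],
            },
            index=pd.Index([r.set_name for r in self.records], name="set_name"),
        )

    def __getitem__(self, set_name: str) -> EnrichmentRecord:
        for r in self.records:
            if r.set_name == set_name:
                return r
        raise KeyError(set_name)

    def running_sum_frame(self, set_name: str) -> pd.DataFrame:
        rec = self[set_name]
        return pd.DataFrame(
            {"rank": np.arange(1, len(rec.running_sum) + 1), "deviation": rec.running_sum}
        )

    def summary(self) -> str:
        lines = [
            "Gene-set enrichment (running-sum statistic, permutation null)",
            f"  weight mode : {self.weight_mode}",
            f"  null scheme : {self.scheme}, n_perm={self.n_perm}, seed={self.seed}",
            "",
            f"  {'set':<14}{'ES':>8}{'n_hits':>8}{'p_perm':>10}{'q_fdr':>10}  call",
        ]
        for r in self.records:
            call = "significant" if r.q_fdr < self.alpha else "-"
            direction = "up-in-old" if r.es < 0 else "up-in-young"
            lines.append(
                f"  {r.set_name:<14}{r.es:>8.3f}{r.n_hits:>8d}"
                f"{r.p_perm:>10.4g}{r.q_fdr:>10.4g}  {call} ({direction})"
            )
        for name, reason in self.skipped.items():
            lines.append(f"  {name:<14}skipped: {reason}")
        return "\n".join(lines)


class GeneSetEnrichment:
    """Model object: enrichment of curated sets over a fold-change ranking.

    Parameters
    ----------
    de : differential-expression results, DataFrame or RankedList
        The ranking substrate.  A results object / DataFrame is ranked
        by signed fold change (descending) first.
    sets : GeneSetCollection
        The sets to score; each is intersected with the ranked universe.
    weight_mode : {"unweighted", "weighted"}
        Hit increments (see module docstring).  Unweighted by default.
    scheme : {"gene_label", "phenotype"}
        Permutation null.  Phenotype requires `matrix`.
    n_perm : int
        Number of permutations (>= 100).
    seed : int
        Seed for the permutation null (mandatory, default 1).
    min_hits : int
        Sets overlapping the universe in fewer genes are skipped.
    include_provisional : bool
        Score provisional set members too.
    """

    def __init__(
        self,
        de,
        sets: GeneSetCollection,
        weight_mode: str = "unweighted",
        scheme: str = "gene_label",
        n_perm: int = 1000,
        seed: int = 1,
        min_hits: int = 3,
        include_provisional: bool = False,
        matrix=None,
        fc_mode: str = "ratio_of_means",
    ) -> None:
        self.ranked = de if isinstance(de, RankedList) else rank_genes(de)
        if weight_mode not in WEIGHT_MODES:
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        if scheme == "phenotype" and matrix is None:
            raise ValueError("phenotype scheme requires the expression matrix")
        self.sets = sets
        self.weight_mode = weight_mode
        self.scheme = scheme
        self.n_perm = int(n_perm)
        self.seed = int(seed)
        self.min_hits = int(min_hits)
        self.include_provisional = include_provisional
        self.matrix = matrix
        self.fc_mode = fc_mode

    def fit(self) -> EnrichmentResults:
        universe = set(self.ranked.symbols)
        records: list[EnrichmentRecord] = []
        skipped: dict[str, str] = {}
        # one independent child seed per set keeps the batch reproducible
        # regardless of which sets get skipped
        seeds = {
            s.name: int(np.random.default_rng([self.seed, k]).integers(2**31))
            for k, s in enumerate(self.sets)
        }
        for s in self.sets:
            members = s.members(self.include_provisional) & universe
            nh = len(members)
            if nh < max(self.min_hits, 1):
                reason = (
                    f"{nh} of {len(s)} members in universe "
                    f"(min_hits={self.min_hits})"
                )
                logger.warning("skipping set %s: %s", s.name, reason)
                skipped[s.name] = reason
                continue
            if nh == self.ranked.N:
                skipped[s.name] = "set covers the whole universe"
                continue
            es, running = enrichment_score(
                self.ranked, members, self.weight_mode, include_provisional=True
            )
            p = permutation_test(
                self.ranked,
                members,
                n_perm=self.n_perm,
                seed=seeds[s.name],
                scheme=self.scheme,
                weight_mode=self.weight_mode,
                include_provisional=True,
                matrix=self.matrix,
                fc_mode=self.fc_mode,
            )
            records.append(
                EnrichmentRecord(
                    set_name=s.name, es=es, n_hits=nh, p_perm=p, running_sum=running
                )
            )
        if not records:
            raise ValueError("no gene set overlaps the universe sufficiently")
        fdr_adjust(records)
        return EnrichmentResults(
            records=records,
            skipped=skipped,
            n_perm=self.n_perm,
            seed=self.seed,
            weight_mode=self.weight_mode,
            scheme=self.scheme,
        )


def run_gsea(
    de,
    sets: GeneSetCollection,
    **kwargs,
) -> EnrichmentResults:
    """Fit :class:`GeneSetEnrichment` (functional form)."""
    return GeneSetEnrichment(de, sets, **kwargs).fit()
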