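"""Direction-stratified cross-dataset overlap of DE gene lists.

The study's DE genes are intersected, separately for the up-in-old and
up-in-young directions, with DE lists derived from independent stromal
expression datasets.  Overlap significance is a one-sided (upper-tail)
hypergeometric test on a common gene universe — by default the
intersection of the datasets' measured symbols, the most conservative
well-defined choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

DIRECTIONS = ("up_in_old", "up_in_young")
MODES = ("union_of_external", "per_dataset")


@dataclass(frozen=True)
class DEGeneList:
    """Direction-labelled DE gene lists from one dataset."""

    dataset_id: str
    up_in_old: frozenset[str]
    up_in_young: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.up_in_old & self.up_in_young:
            both = sorted(self.up_in_old & self.up_in_young)
            raise ValueError(f"{self.dataset_id}: genes in both directions: {both}")
        listed = self.up_in_old | self.up_in_young
        if not listed <= self.universe:
            raise ValueError(
                f"{self.dataset_id}: DE genes outside the measured universe"
            )

    def direction(self, direction: str) -> frozenset[str]:
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        return getattr(self, direction)


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of one direction between study and external lists."""

    direction: str
    genes: tuple[str, ...]
    k: int
    hypergeom_p: float
    universe_size: int
    n_study: int
    n_external: int
    dataset_id: str = field(default="union")


def overlap_significance(
    k: int, n_study: int, n_external: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for an overlap of k genes
    between lists of sizes `n_study` and `n_external` drawn from a
    universe of `universe_size` genes."""
    if not 0 <= k <= min(n_study, n_external):
        raise ValueError("k must lie in [0, min(list sizes)]")
    if max(n_study, n_external) > universe_size:
        raise ValueError("list sizes cannot exceed the universe size")
    # X ~ Hypergeom(M=universe, K=n_study successes, n=n_external draws)
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_study, n_external))
    return min(p, 1.0)


def intersect_lists(
    study: DEGeneList,
    external: list[DEGeneList] | DEGeneList,
    mode: str = "union_of_external",
) -> dict:
    """Direction-stratified overlap of the study list with external lists.

    All lists are restricted to the common universe (intersection of the
    measured universes) before intersecting.  ``union_of_external`` pools
    the external lists into one comparator (one OverlapResult per
    direction); ``per_dataset`` returns one per (direction, dataset).

    Returns
    -------
    dict
        ``union_of_external``: direction -> OverlapResult.
        ``per_dataset``: direction -> list of OverlapResult.
    """
    if isinstance(external, DEGeneList):
        external = [external]
    if not external:
        raise ValueError("need at least one external list")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")

    def _one(direction: str, comparator: DEGeneList | list[DEGeneList]):
        ext_list = comparator if isinstance(comparator, list) else [comparator]
        common = study.universe
        for e in ext_list:
            common = common & e.universe
        if not common:
            raise ValueError("empty common universe between datasets")
        s = study.direction(direction) & common
        x: frozenset[str] = frozenset()
        for e in ext_list:
            x = x | (e.direction(direction) & common)
        genes = tuple(sorted(s & x))
        p = overlap_significance(len(genes), len(s), len(x), len(common))
        dataset_id = (
            "+".join(e.dataset_id for e in ext_list)
            if isinstance(comparator, list)
            else comparator.dataset_id
        )
        return OverlapResult(
            direction=direction,
            genes=genes,
            k=len(genes),
            hypergeom_p=p,
            universe_size=len(common),
            n_study=len(s),
            n_external=len(x),
            dataset_id=dataset_id,
        )

    if mode == "union_of_external":
        return {d: _one(d, external) for d in DIRECTIONS}
    return {d: [_one(d, e) for e in external] for d in DIRECTIONS}


def venn_counts(result: OverlapResult) -> dict[str, int]:
    """Two-set Venn partition sizes for one overlap result."""
    return {
        "study_only": result.n_study - result.k,
        "external_only": result.n_external - result.k,
        "shared": result.k,
    }


def read_external_lists(
    path: str | Path, universe: frozenset[str] | None = None
) -> list[DEGeneList]:
    """Read external DE lists from TSV (gene_symbol, direction, dataset_id).

    When `universe` is not given, each dataset's universe defaults to its
    own listed genes (overlap tests should then supply a study-side
    universe restriction via the common-universe rule).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_symbol", "direction", "dataset_id"}
    if not required <= set(df.columns):
        raise ValueError(f"external list {path} must have columns {sorted(required)}")
    bad = set(df["direction"]) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown directions in {path}: {sorted(bad)}")
    lists = []
    for dataset_id, sub in df.groupby("dataset_id", sort=True):
        up_old = frozenset(sub.loc[sub["direction"] == "up_in_old", "gene_symbol"])
        up_young = frozenset(sub.loc[sub["direction"] == "up_in_young", "gene_symbol"])
        uni = universe if universe is not None else (up_old | up_young)
        lists.append(
            DEGeneList(
                dataset_id=str(dataset_id),
                up_in_old=up_old,
                up_in_young=up_young,
                universe=frozenset(uni) | up_old | up_young,
            )
        )
    return lists


def study_list_from_de(results, dataset_id: str = "study") -> DEGeneList:
    """Build the study-side DEGeneList from fitted DE results."""
    return DEGeneList(
        dataset_id=dataset_id,
        up_in_old=results.gene_list("up_in_old"),
        up_in_young=results.gene_list("up_in_young"),
        universe=frozenset(results.table.index),
    )
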