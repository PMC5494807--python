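"""Signed fold-change differential expression between age groups.

For each gene the group means are compared as a *signed fold change*: the
ratio ``r`` of the young-group mean to the old-group mean (computed on the
linear intensity scale after undoing the log2) is reported as ``r`` when
``r >= 1`` and as ``-1/r`` otherwise.  The magnitude is therefore always
at least 1 and the sign encodes direction: **negative = up-regulated in
the old group**, positive = up in young.  A gene is called differentially
expressed when the magnitude reaches the fold-change threshold (default
1.5); a two-sided Wilcoxon rank-sum p-value is reported alongside but is
not part of the call by default.

Two fold-change scales are available:

``ratio_of_means`` (default)
    ``r = mean(2**x_young) / mean(2**x_old)`` — the ratio of linearised
    group means.
``diff_of_log_means``
    ``r = 2**(mean(x_young) - mean(x_old))`` — the linearised difference
    of log2 means (equivalently the ratio of geometric means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

FC_MODES = ("ratio_of_means", "diff_of_log_means")


def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name}: needs at least one value")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name}: non-finite values")
    return arr


def _signed_from_ratio(r):
    r = np.asarray(r, dtype=float)
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if out.ndim == 0 else out


def signed_fold_change(
    values_young, values_old, fc_mode: str = "ratio_of_means"
) -> float:
    """Signed fold change of young over old from log2 intensities.

    Returns ``r`` if ``r >= 1`` else ``-1/r``; negative values mean the
    gene is higher in the old group.
    """
    if fc_mode not in FC_MODES:
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    y = _as_clean_array(values_young, "values_young")
    o = _as_clean_array(values_old, "values_old")
    if fc_mode == "ratio_of_means":
        r = np.mean(np.exp2(y)) / np.mean(np.exp2(o))
    else:
        r = 2.0 ** (np.mean(y) - np.mean(o))
    return _signed_from_ratio(r)


def wilcoxon_rank_sum(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.  When every
    value in both groups is identical the ranking is degenerate and the
    p-value is 1 by convention.
    """
    a = _as_clean_array(values_a, "values_a")
    b = _as_clean_array(values_b, "values_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.debug("degenerate ranking (all values identical); p = 1")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class DifferentialExpressionResults:
    """Fitted differential-expression table.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per gene (index = symbol), sorted by `signed_fc`
        ascending — most strongly up-in-old first — with columns
        ``mean_young``, ``mean_old`` (log2), ``signed_fc``,
        ``wilcoxon_p`` and ``is_de``.
    threshold : float
        Fold-change magnitude used for the DE call.
    fc_mode : str
        Fold-change scale used.
    """

    table: pd.DataFrame
    threshold: float
    fc_mode: str
    p_threshold: float | None = field(default=None)

    @property
    def n_up_old(self) -> int:
        """DE genes with higher expression in the old group."""
        t = self.table
        return int((t["is_de"] & (t["signed_fc"] < 0)).sum())

    @property
    def n_up_young(self) -> int:
        """DE genes with higher expression in the young group."""
        t = self.table
        return int((t["is_de"] & (t["signed_fc"] > 0)).sum())

    @property
    def de_genes(self) -> pd.DataFrame:
        return self.table[self.table["is_de"]]

    def gene_list(self, direction: str) -> frozenset[str]:
        """DE symbols for ``"up_in_old"`` or ``"up_in_young"``."""
        t = self.de_genes
        if direction == "up_in_old":
            return frozenset(t.index[t["signed_fc"] < 0])
        if direction == "up_in_young":
            return frozenset(t.index[t["signed_fc"] > 0])
        raise ValueError(f"unknown direction {direction!r}")

    def ranked_list(self):
        """Genes ranked by signed fold change (for enrichment scoring)."""
        from .gsea import rank_genes

        return rank_genes(self)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_symbol")

    def summary(self) -> str:
        lines = [
            "Differential expression (signed fold change, young vs old)",
            f"  genes tested        : {len(self.table)}",
            f"  fold-change scale   : {self.fc_mode}",
            f"  |FC| threshold      : {self.threshold}",
            f"  DE up in old  (FC<0): {self.n_up_old}",
            f"  DE up in young(FC>0): {self.n_up_young}",
        ]
        if self.p_threshold is not None:
            lines.insert(4, f"  Wilcoxon p threshold: {self.p_threshold}")
        return "\n".join(lines)


class DifferentialExpression:
    """Model object: per-gene age-group comparison on an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Collapsed (one row per gene symbol) log2 expression matrix with
        young/old sample labels.
    threshold : float
        Fold-change magnitude for the DE call; must exceed 1.
    fc_mode : {"ratio_of_means", "diff_of_log_means"}
        Fold-change scale (see module docstring).
    p_threshold : float, optional
        If given, the DE call additionally requires
        ``wilcoxon_p <= p_threshold``.  Off by default: the study's rule
        is fold change alone.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        threshold: float = 1.5,
        fc_mode: str = "ratio_of_means",
        p_threshold: float | None = None,
    ) -> None:
        if threshold <= 1:
            raise ValueError("fold-change threshold must exceed 1")
        if fc_mode not in FC_MODES:
            raise ValueError(f"unknown fc_mode {fc_mode!r}")
        self.matrix = matrix
        self.threshold = float(threshold)
        self.fc_mode = fc_mode
        self.p_threshold = p_threshold

    def fit(self, compute_wilcoxon: bool = True) -> DifferentialExpressionResults:
        m = self.matrix
        young = m.group_values("young").to_numpy(dtype=float)
        old = m.group_values("old").to_numpy(dtype=float)
        if self.fc_mode == "ratio_of_means":
            r = np.exp2(young).mean(axis=1) / np.exp2(old).mean(axis=1)
        else:
            r = 2.0 ** (young.mean(axis=1) - old.mean(axis=1))
        fc = _signed_from_ratio(r)

        if compute_wilcoxon:
            pvals = np.array(
                [wilcoxon_rank_sum(young[i], old[i]) for i in range(m.n_rows)]
            )
        else:
            pvals = np.full(m.n_rows, np.nan)

        is_de = np.abs(fc) >= self.threshold
        if self.p_threshold is not None:
            if not compute_wilcoxon:
                raise ValueError("p_threshold requires compute_wilcoxon=True")
            is_de &= pvals <= self.p_threshold

        table = pd.DataFrame(
            {
                "mean_young": young.mean(axis=1),
                "mean_old": old.mean(axis=1),
                "signed_fc": fc,
                "wilcoxon_p": pvals,
                "is_de": is_de,
            },
            index=m.values.index,
        )
        # most up-in-old first, mirroring the published table; symbol
        # breaks exact ties deterministically
        order = np.lexsort((table.index.to_numpy(), table["signed_fc"].to_numpy()))
        table = table.iloc[order]
        return DifferentialExpressionResults(
            table=table,
            threshold=self.threshold,
            fc_mode=self.fc_mode,
            p_threshold=self.p_threshold,
        )


def run_diffexp(
    matrix: ExpressionMatrix,
    threshold: float = 1.5,
    fc_mode: str = "ratio_of_means",
    p_threshold: float | None = None,
    compute_wilcoxon: bool = True,
) -> DifferentialExpressionResults:
    """Fit :class:`DifferentialExpression` on `matrix` (functional form)."""
    model = DifferentialExpression(
        matrix, threshold=threshold, fc_mode=fc_mode, p_threshold=p_threshold
    )
    return model.fit(compute_wilcoxon=compute_wilcoxon)
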