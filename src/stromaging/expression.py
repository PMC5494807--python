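"""Normalised expression matrices and probe-to-gene collapsing.

Input is a probe/gene × sample matrix of log2-scale intensities, as
produced by standard microarray normalisation (e.g. fRMA); normalisation
itself is upstream of this package.  Samples carry a two-level age-group
label (``young`` / ``old``).  Multiple probe sets for one gene symbol are
collapsed by averaging on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("young", "old")


class MatrixParseError(ValueError):
    """Raised on malformed matrix input; carries a line number when known."""


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix with per-sample age-group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are probes or gene symbols, columns are sample ids; entries
        are finite log2 intensities.
    groups : pandas.Series
        Maps every column of `values` to ``"young"`` or ``"old"``;
        each group must have at least two samples.
    symbols : pandas.Series, optional
        Per-row gene symbol annotation (missing entries allowed before
        collapsing).  After :meth:`collapse_probes` the index itself is
        the symbol and `symbols` mirrors it.
    """

    values: pd.DataFrame
    groups: pd.Series
    symbols: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate row id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        if self.symbols is not None:
            self.symbols = self.symbols.reindex(self.values.index)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to `group`."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return self.values.loc[:, self.groups == group]

    def with_groups(self, groups: pd.Series) -> "ExpressionMatrix":
        """Same data under a different sample labelling (used by
        phenotype-permutation nulls)."""
        return ExpressionMatrix(self.values, groups, self.symbols)

    def collapse_probes(
        self, mapping: Mapping[str, str] | pd.Series | None = None
    ) -> "ExpressionMatrix":
        """Collapse probe rows to one row per gene symbol.

        Each collapsed value is the unweighted arithmetic mean of the
        gene's probe values on the log2 scale, per sample.  Probes with
        no (or blank) symbol are dropped.  Rows come back sorted
        lexicographically by symbol.  Idempotent on an already collapsed
        matrix.

        Parameters
        ----------
        mapping : mapping of probe id -> symbol, optional
            Defaults to the matrix's own `symbols` annotation.
        """
        if mapping is None:
            if self.symbols is None:
                raise ValueError("no probe-to-symbol mapping available")
            sym = self.symbols.copy()
        else:
            sym = pd.Series(dict(mapping) if not isinstance(mapping, pd.Series) else mapping)
            sym = sym.reindex(self.values.index)
        sym = sym.astype("string").str.strip()
        keep = sym.notna() & (sym != "")
        if not keep.any():
            raise ValueError("probe-to-symbol mapping leaves no rows")
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("dropping %d rows without symbol annotation", dropped)
        collapsed = (
            self.values.loc[keep]
            .groupby(sym[keep].astype(str))
            .mean()
            .sort_index()
        )
        symbols = pd.Series(collapsed.index, index=collapsed.index, dtype="string")
        return ExpressionMatrix(collapsed, self.groups, symbols)


def _read_table_lines(path: Path) -> tuple[list[str], int]:
    """Return the data lines of a plain or series-matrix-style file and
    the 1-based line offset of the first returned line."""
    lines = path.read_text(encoding="utf-8").splitlines()
    begin = end = None
    for i, ln in enumerate(lines):
        low = ln.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            begin = i
        elif low.startswith("!series_matrix_table_end"):
            end = i
    if begin is not None:
        table = lines[begin + 1 : end if end is not None else len(lines)]
        offset = begin + 2
    else:
        table = [ln for ln in lines if not ln.startswith("!")]
        offset = 1
    table = [ln for ln in table if ln.strip()]
    if not table:
        raise MatrixParseError(f"no table content found in {path}")
    return table, offset


def read_matrix(
    path: str | Path, group_map: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Read a log2 expression matrix with an age-group assignment.

    Accepts either a plain TSV (header row of sample ids, first column
    row ids) or GEO series-matrix-style text, in which ``!``-prefixed
    metadata lines are skipped and the table is delimited by the
    ``!series_matrix_table_begin`` / ``_end`` markers.  Samples absent
    from `group_map` are dropped with a logged warning.

    Raises
    ------
    MatrixParseError
        On ragged rows (message carries the line number) or when no file
        sample overlaps the group map.
    """
    path = Path(path)
    table, offset = _read_table_lines(path)
    header = table[0].split("\t")
    ncol = len(header)
    rows: list[list[str]] = []
    for i, ln in enumerate(table[1:], start=1):
        cells = ln.split("\t")
        if len(cells) != ncol:
            raise MatrixParseError(
                f"{path} line {offset + i}: expected {ncol} fields, got {len(cells)}"
            )
        rows.append(cells)
    sample_ids = [c.strip().strip('"') for c in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise MatrixParseError(f"duplicate sample ids in header of {path}")
    df = pd.DataFrame(
        [[c.strip().strip('"') for c in r] for r in rows],
        columns=["__row_id__"] + sample_ids,
    ).set_index("__row_id__")
    df.index.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixParseError(f"non-numeric expression value in {path}: {exc}") from exc

    gmap = pd.Series(dict(group_map) if not isinstance(group_map, pd.Series) else group_map)
    present = [s for s in sample_ids if s in gmap.index]
    absent = [s for s in sample_ids if s not in gmap.index]
    if not present:
        raise MatrixParseError(
            f"no overlap between samples in {path} and the group map"
        )
    if absent:
        logger.warning("dropping %d samples not in group map: %s", len(absent), absent)
    return ExpressionMatrix(df[present], gmap[present])


def collapse_probes(
    matrix: ExpressionMatrix, mapping: Mapping[str, str] | pd.Series | None = None
) -> ExpressionMatrix:
    """Functional alias of :meth:`ExpressionMatrix.collapse_probes`."""
    return matrix.collapse_probes(mapping)


def read_group_map(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (sample id, group) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise MatrixParseError(f"group map {path} needs 2 tab-separated columns")
    first = df.iloc[0]
    if set(df.iloc[:, 1].str.lower()) - set(GROUPS) and str(first[1]).lower() not in GROUPS:
        # tolerate a header row
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].str.lower().to_numpy(), index=df.iloc[:, 0].to_numpy())


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (probe id, gene symbol) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise MatrixParseError(f"probe map {path} needs 2 tab-separated columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
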