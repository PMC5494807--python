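"""Shipped reference tables from the stromal-ageing breast cancer study.

The package carries, as plain-text fixtures, the study's printed result
tables: the signed fold-change differential-expression list (227 genes),
the four curated senescence-programme gene sets, the 17-patient cohort
annotation, and the ten-gene cross-dataset validated overlap.  These are
transcriptions of published tables, used as ground truth in tests and as
demo inputs; no expression values ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .genesets import GeneSetCollection, read_gmt

_DATA_PACKAGE = "stromaging.data"

#: sign convention of the shipped DE table: negative signed fold change
#: means higher expression in the old group, positive means higher in young.
SIGN_NOTE = "negative signed_fc = up-regulated in old; positive = up in young"


class FixtureError(RuntimeError):
    """A shipped fixture file is missing or fails its integrity checks."""


def _fixture_path(name: str) -> Path:
    path = resources.files(_DATA_PACKAGE).joinpath(name)
    with resources.as_file(path) as p:
        if not p.exists():
            raise FixtureError(f"missing fixture file: {p}")
        return Path(p)


@dataclass(frozen=True)
class PublishedDERecord:
    """One row of the published DE table: symbol, full name, signed FC."""

    gene_symbol: str
    full_name: str
    signed_fc: float


@dataclass(frozen=True)
class PatientRecord:
    """One cohort member; `group` is derived from age at diagnosis."""

    patient_id: int
    age_years: int
    group: str  # "young" (<45 y) or "old" (>=80 y)
    tumour_grade: str
    max_size_cm: float
    pT: str
    pN: str


def load_de_table() -> list[PublishedDERecord]:
    """Load the published 227-gene signed fold-change list.

    The table keeps the published sign convention (see :data:`SIGN_NOTE`)
    and contains no fold change of magnitude below 1.5.

    Raises
    ------
    FixtureError
        If the shipped file is malformed or violates its invariants.
    """
    path = _fixture_path("published_de_genes.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "full_name": str})
    expected = ["gene_symbol", "full_name", "signed_fc"]
    if list(df.columns) != expected or df.isna().any().any():
        raise FixtureError(f"corrupted DE-table fixture: {path}")
    records = [
        PublishedDERecord(r.gene_symbol, r.full_name, float(r.signed_fc))
        for r in df.itertuples(index=False)
    ]
    symbols = [r.gene_symbol for r in records]
    if len(set(symbols)) != len(symbols):
        raise FixtureError(f"duplicate symbols in DE-table fixture: {path}")
    if any(abs(r.signed_fc) < 1.5 or r.signed_fc == 0 for r in records):
        raise FixtureError(f"signed fold change below cut-off in fixture: {path}")
    return records


def load_de_frame() -> pd.DataFrame:
    """The published DE list as a DataFrame indexed by gene symbol."""
    df = pd.DataFrame([r.__dict__ for r in load_de_table()])
    return df.set_index("gene_symbol")


def load_curated_sets(include_provisional: bool = False) -> GeneSetCollection:
    """Load the four curated gene programmes (senescence, ddr, sasp, ast).

    The secretome (sasp) set carries CCL3 as a provisional member; it is
    excluded from scoring unless `include_provisional` is True, in which
    case the returned collection has the provisional flags cleared so all
    members score.
    """
    collection = read_gmt(_fixture_path("curated_gene_sets.gmt"))
    if set(collection.names) != {"senescence", "ddr", "sasp", "ast"}:
        raise FixtureError("curated gene-set fixture does not contain the 4 sets")
    if include_provisional:
        from .genesets import GeneSet

        collection = GeneSetCollection(
            tuple(
                GeneSet(s.name, s.symbols, s.description, frozenset())
                for s in collection
            )
        )
    return collection


def load_patients() -> list[PatientRecord]:
    """Load the 17-patient cohort table (9 young < 45 y, 8 old >= 80 y)."""
    path = _fixture_path("patient_cohort.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for r in df.itertuples(index=False):
        age = int(r.age_years)
        group = "young" if age < 45 else "old"
        if group != r.group or (group == "old" and age < 80):
            raise FixtureError(f"patient {r.patient_id}: group/age mismatch")
        records.append(
            PatientRecord(
                patient_id=int(r.patient_id),
                age_years=age,
                group=group,
                tumour_grade=r.tumour_grade,
                max_size_cm=float(r.max_size_cm),
                pT=r.pT,
                pN=r.pN,
            )
        )
    return records


def load_validated_overlap() -> pd.DataFrame:
    """The ten cross-dataset validated genes with direction labels."""
    path = _fixture_path("validated_overlap.tsv")
    df = pd.read_csv(path, sep="\t")
    if set(df["direction"]) != {"up_in_old", "up_in_young"}:
        raise FixtureError(f"bad direction labels in fixture: {path}")
    return df


def external_lists_path() -> Path:
    """Path of the shipped synthetic external DE-list fixture.

    A stand-in for externally derived stromal DE lists (the study compared
    against three public laser-dissected stroma datasets); it contains the
    ten validated genes with their directions and is synthetic in the
    sense that the true external lists are not redistributable here.
    """
    return _fixture_path("external_lists_synthetic.tsv")
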