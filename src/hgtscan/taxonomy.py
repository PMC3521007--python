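"""Lineage-based kingdom assignment for gene-family leaves.

Sequences are classified into the screening kingdoms (Bacteria, Archaea,
Plantae, OtherEukaryote, Unknown) by containment of diagnostic clade names
anywhere in their ordered taxonomic lineage — the same rule one applies by
hand when reading a UniProt lineage string. No live taxonomy service is
consulted; lineages come from a TSV table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, TextIO, Union

import pandas as pd

__all__ = [
    "BACTERIA",
    "ARCHAEA",
    "PLANTAE",
    "OTHER_EUKARYOTE",
    "UNKNOWN",
    "KINGDOMS",
    "DEFAULT_RULES",
    "TaxonRecord",
    "assign_kingdom",
    "build_kingdom_map",
    "read_taxonomy_table",
    "write_taxonomy_table",
]

BACTERIA = "Bacteria"
ARCHAEA = "Archaea"
PLANTAE = "Plantae"
OTHER_EUKARYOTE = "OtherEukaryote"
UNKNOWN = "Unknown"

KINGDOMS = (BACTERIA, ARCHAEA, PLANTAE, OTHER_EUKARYOTE, UNKNOWN)

#: name (case-insensitive) found anywhere in the lineage → kingdom label.
#: More specific names take precedence over the generic eukaryote fallback.
DEFAULT_RULES: dict[str, str] = {
    "bacteria": BACTERIA,
    "archaea": ARCHAEA,
    "viridiplantae": PLANTAE,
    "eukaryota": OTHER_EUKARYOTE,
}

#: Preference when several rule names occur in one lineage (a plant lineage
#: contains both "Eukaryota" and "Viridiplantae"; the specific label wins).
_PRECEDENCE = (PLANTAE, BACTERIA, ARCHAEA, OTHER_EUKARYOTE)

_COLUMNS = ("id", "name", "lineage")


@dataclass
class TaxonRecord:
    """One sequence's taxonomic annotation.

    ``lineage`` is root-first (domain level first), as in UniProt exports.
    """

    id: str
    name: str
    lineage: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("TaxonRecord requires a sequence id")
        self.lineage = [x.strip() for x in self.lineage if x and x.strip()]
        if not self.lineage:
            raise ValueError(f"record {self.id!r} has an empty lineage")


def assign_kingdom(
    record: TaxonRecord, rules: Optional[Mapping[str, str]] = None
) -> str:
    """Map a record to exactly one kingdom label.

    Matching is exact and case-insensitive at any lineage position; when
    several diagnostic names occur, the most specific (by the fixed
    Bacteria < Archaea < Plantae < OtherEukaryote precedence) wins.
    ``Unknown`` is the total-function fallback.
    """
    rules = {k.lower(): v for k, v in (rules or DEFAULT_RULES).items()}
    hits = {
        rules[part.lower()]
        for part in record.lineage
        if part.lower() in rules
    }
    if not hits:
        return UNKNOWN
    for label in _PRECEDENCE:
        if label in hits:
            return label
    return sorted(hits)[0]  # custom rule labels outside the built-in set


def build_kingdom_map(
    records: Iterable[TaxonRecord], rules: Optional[Mapping[str, str]] = None
) -> dict[str, str]:
    """Sequence id → kingdom label over a record collection."""
    return {r.id: assign_kingdom(r, rules) for r in records}


def read_taxonomy_table(source: Union[str, TextIO]) -> list[TaxonRecord]:
    """Read a taxonomy TSV (columns: id, name, semicolon-delimited lineage).

    Malformed rows are collected and reported in a single warning; a
    duplicated id is an error naming the id.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing required columns: {missing}")
    if df.empty:
        warnings.warn("taxonomy table is empty", stacklevel=2)
        return []
    records: list[TaxonRecord] = []
    bad: list[int] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        try:
            rec = TaxonRecord(
                id=row["id"],
                name=row["name"],
                lineage=str(row["lineage"]).split(";"),
            )
        except ValueError:
            bad.append(int(idx) + 2)  # 1-based line number incl. header
            continue
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in taxonomy table: {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    if bad:
        warnings.warn(
            f"skipped {len(bad)} malformed taxonomy rows (lines {bad})",
            stacklevel=2,
        )
    return records


def write_taxonomy_table(
    records: Iterable[TaxonRecord], dest: Union[str, TextIO]
) -> None:
    records = list(records)
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "name": [r.name for r in records],
            "lineage": [";".join(r.lineage) for r in records],
        },
        columns=list(_COLUMNS),
    )
    df.to_csv(dest, sep="\t", index=False)


def records_to_tsv(records: Iterable[TaxonRecord]) -> str:
    buf = io.StringIO()
    write_taxonomy_table(records, buf)
    return buf.getvalue()
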