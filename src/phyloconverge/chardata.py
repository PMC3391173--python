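"""Taxon annotation tables and single-character maps.

Each taxon (a louse genus/species, matching a tree tip label) carries two
categorical annotations: the *host group* (the avian order or family it
parasitizes) and the *microhabitat niche* — where on the host the louse
escapes preening, one of ``wing``, ``body``, ``head`` or ``generalist``.
Mammal-louse outgroups have no niche and are recorded as missing.

A packaged fixture transcribes the 43-row specimen table of the study this
pipeline reproduces: 39 ingroup avian-louse genera with host group and niche,
plus 4 trichodectid outgroups.  One host-group spelling in the source
("Alcidinidae", apparently for the kingfisher family Alcedinidae) is kept
verbatim rather than corrected, so the fixture is a faithful transcription.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "NICHES",
    "TaxonRecord",
    "TaxonTable",
    "CharacterMap",
    "TableValidationError",
    "read_taxon_table",
    "read_alias_map",
    "table1_fixture",
    "character_from_table",
]

#: Canonical microhabitat states, lower-case.
NICHES = ("wing", "body", "head", "generalist")

_FIXTURE_NAME = "table1_ingroup_outgroup.tsv"


class TableValidationError(ValueError):
    """Raised when a taxon table violates its contract."""


def _norm_label(label: str) -> str:
    """Trim surrounding whitespace and collapse internal runs to one space."""
    return re.sub(r"\s+", " ", label.strip())


@dataclass(frozen=True)
class TaxonRecord:
    taxon: str
    host_group: str
    niche: Optional[str]  # one of NICHES, or None for unannotated taxa


@dataclass
class TaxonTable:
    """An ordered collection of taxon records with unique labels."""

    records: list[TaxonRecord]
    provenance: str = "user"

    def __post_init__(self):
        if not self.records:
            raise TableValidationError("taxon table is empty")
        seen = set()
        for rec in self.records:
            if rec.taxon in seen:
                raise TableValidationError(f"duplicate taxon: {rec.taxon!r}")
            seen.add(rec.taxon)
            if rec.niche is not None and rec.niche not in NICHES:
                raise TableValidationError(
                    f"taxon {rec.taxon!r} has unknown niche {rec.niche!r}; "
                    f"expected one of {NICHES}"
                )
        self._by_taxon = {rec.taxon: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._by_taxon

    def get(self, taxon: str) -> TaxonRecord:
        return self._by_taxon[taxon]

    @property
    def taxa(self) -> list[str]:
        return [rec.taxon for rec in self.records]

    @property
    def annotated(self) -> "TaxonTable":
        """Sub-table of records with a non-missing niche."""
        return TaxonTable(
            [r for r in self.records if r.niche is not None],
            provenance=self.provenance,
        )

    def host_groups(self) -> list[str]:
        out, seen = [], set()
        for rec in self.records:
            if rec.host_group not in seen:
                seen.add(rec.host_group)
                out.append(rec.host_group)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [r.taxon for r in self.records],
                "host_group": [r.host_group for r in self.records],
                "niche": [r.niche for r in self.records],
            }
        )


@dataclass
class CharacterMap:
    """One unordered multistate character: taxon -> state.

    Taxa with a missing state are recorded explicitly (value ``None``), never
    dropped silently — downstream parsimony treats them as compatible with
    every state.
    """

    assignments: dict[str, Optional[str]]

    def __post_init__(self):
        self.alphabet = frozenset(
            s for s in self.assignments.values() if s is not None
        )

    @property
    def assigned(self) -> dict[str, str]:
        return {t: s for t, s in self.assignments.items() if s is not None}

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return len(self.assignments)


def _records_from_frame(df: pd.DataFrame, provenance: str) -> TaxonTable:
    required = {"taxon", "host_group", "niche"}
    missing = required - set(df.columns)
    if missing:
        raise TableValidationError(f"missing required columns: {sorted(missing)}")
    records, bad_rows = [], []
    for idx, row in df.iterrows():
        taxon = _norm_label(str(row["taxon"]))
        host = _norm_label(str(row["host_group"]))
        raw_niche = row["niche"]
        if pd.isna(raw_niche) or str(raw_niche).strip() == "":
            niche = None
        else:
            niche = str(raw_niche).strip().lower()
            if niche not in NICHES:
                bad_rows.append((idx, taxon, str(raw_niche)))
                continue
        records.append(TaxonRecord(taxon=taxon, host_group=host, niche=niche))
    if bad_rows:
        detail = "; ".join(f"row {i} ({t!r}): {v!r}" for i, t, v in bad_rows)
        raise TableValidationError(f"unknown niche values: {detail}")
    return TaxonTable(records, provenance=provenance)


def read_taxon_table(path) -> TaxonTable:
    """Read a tab-separated taxon table with columns taxon/host_group/niche.

    Niche values are normalized case-insensitively to the four canonical
    states; empty niche cells mean missing (allowed, e.g. for outgroups).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    return _records_from_frame(df, provenance=str(path))


def read_alias_map(path) -> dict[str, str]:
    """Read a two-column TSV (tree_label, table_taxon) reconciling tip labels
    that differ from table spellings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tree_label", "table_taxon"}
    if required - set(df.columns):
        raise TableValidationError(
            "alias map needs columns tree_label and table_taxon"
        )
    return {
        _norm_label(a): _norm_label(b)
        for a, b in zip(df["tree_label"], df["table_taxon"])
    }


def table1_fixture() -> TaxonTable:
    """The packaged 43-row specimen table: 39 avian-louse ingroup genera with
    host group and niche, and 4 mammal-louse outgroups with niche missing."""
    ref = resources.files("phyloconverge.data") / _FIXTURE_NAME
    with resources.as_file(ref) as path:
        table = read_taxon_table(path)
    table.provenance = "fixture"
    return table


def character_from_table(
    table: TaxonTable,
    field: str,
    taxa: Optional[Iterable[str]] = None,
) -> CharacterMap:
    """Project one annotation column onto a set of tree tips.

    ``field`` is ``"niche"`` or ``"host_group"``.  Missing values are kept as
    missing.  A tip absent from the table is an error naming the label.
    """
    if field not in ("niche", "host_group"):
        raise ValueError(f"field must be 'niche' or 'host_group', got {field!r}")
    if taxa is None:
        taxa = table.taxa
    assignments: dict[str, Optional[str]] = {}
    for label in taxa:
        norm = _norm_label(label)
        if norm not in table:
            raise KeyError(f"tip label not found in taxon table: {label!r}")
        rec = table.get(norm)
        assignments[label] = rec.niche if field == "niche" else rec.host_group
    return CharacterMap(assignments)
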