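"""Presence-absence matrices and strict co-occurrence pattern matching.

Builds boolean family-or-orthogroup x species matrices (from orthogroup
gene-list tables or gene-family count tables) and extracts the rows that
follow a strict presence/absence pattern across a set of required species —
the phylogenetic-profiling screen used to find orthogroups co-distributed
with a gene family of interest.  Matching is strict by default (every
required species must agree); a mismatch allowance is available but the
default is zero, keeping only high-confidence candidates.  Presence is
defined at the species level (>=1 gene), never weighted by copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd


@dataclass
class PresenceMatrix:
    """Boolean rows (families or orthogroups) x species matrix."""

    df: pd.DataFrame  # bool, index = row ids, columns = species ids
    provenance: str = "orthogroups"  # or "family_counts"

    def __post_init__(self):
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate species ids")
        self.df = self.df.astype(bool)

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.astype(int)
        out.index.name = "row_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "orthogroups") -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df=df.astype(bool), provenance=provenance)


@dataclass(frozen=True)
class PatternQuery:
    """A strict presence/absence query over a set of required species.

    ``required`` maps species_id -> expected presence; species in
    ``free_species`` are excluded from matching (their value is ignored).
    """

    required: Mapping[str, bool]
    free_species: frozenset = frozenset()

    def __post_init__(self):
        if not self.required:
            raise ValueError("query must name at least one required species")
        clash = set(self.required) & set(self.free_species)
        if clash:
            raise ValueError(f"species both required and free: {sorted(clash)}")


def read_pattern(path: str | Path) -> PatternQuery:
    """Pattern file: two-column TSV (species_id, 0/1)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species_id", "present"],
                     comment="#", dtype={"species_id": str})
    required = {r.species_id: bool(int(r.present)) for r in df.itertuples()}
    return PatternQuery(required=required)


def binarize_orthogroups(table: str | Path | pd.DataFrame) -> PresenceMatrix:
    """Binarize a standard orthogroup table (row = OG; per-species gene lists).

    Accepts a path to the usual orthology-inference TSV (first column the
    orthogroup id, one column per species holding comma-separated gene ids,
    possibly empty) or an equivalent DataFrame.  A cell is present iff the
    species' gene list is non-empty after stripping whitespace.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    else:
        df = table.copy().astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate orthogroup ids: {dups[:5]}")
    presence = df.apply(lambda col: col.str.strip() != "")
    return PresenceMatrix(df=presence, provenance="orthogroups")


def match_pattern(
    matrix: PresenceMatrix,
    query: PatternQuery,
    max_mismatches: int = 0,
) -> list[str]:
    """Rows whose values agree with the query at every required species.

    Strict by default: a row matches iff its value equals ``query.required``
    at each required species; ``free_species`` are ignored.  With
    ``max_mismatches`` k > 0, rows disagreeing at up to k required species
    are also returned.  Output preserves matrix row order.
    """
    unknown = set(query.required) - set(matrix.species_ids)
    if unknown:
        raise ValueError(f"query species not in matrix: {sorted(unknown)}")
    species = list(query.required)
    expected = pd.Series({sp: query.required[sp] for sp in species})
    sub = matrix.df[species]
    mismatches = (sub != expected).sum(axis=1)
    return list(matrix.df.index[mismatches <= max_mismatches])


def profile_agreement(
    matrix: PresenceMatrix, row_a: str, row_b: str
) -> tuple[float, float]:
    """(Jaccard, Hamming agreement) between two presence profiles.

    Jaccard is |A∩B| / |A∪B| over present-species sets, defined as 1.0 when
    both are empty; Hamming agreement is the fraction of species at which
    the two rows take equal values.
    """
    for r in (row_a, row_b):
        if r not in matrix.df.index:
            raise KeyError(f"row {r!r} not in matrix")
    a = matrix.df.loc[row_a]
    b = matrix.df.loc[row_b]
    union = int((a | b).sum())
    inter = int((a & b).sum())
    jaccard = 1.0 if union == 0 else inter / union
    hamming = float((a == b).mean())
    return jaccard, hamming


def family_presence_from_counts(
    *count_tables: pd.DataFrame,
) -> PresenceMatrix:
    """Presence matrix from one or more family-count tables.

    Each table is species (index) x family (columns) with non-negative
    counts — e.g. the architecture counts plus an EDS1-family / helper-NLR
    count table.  All tables must cover the same species; presence is
    count >= 1.  Output rows are families, columns species.
    """
    if not count_tables:
        raise ValueError("at least one count table required")
    species = set(count_tables[0].index)
    for t in count_tables[1:]:
        if set(t.index) != species:
            diff = species.symmetric_difference(t.index)
            raise ValueError(f"species mismatch between count tables: {sorted(diff)}")
    combined = pd.concat([t.sort_index() for t in count_tables], axis=1)
    if (combined.values < 0).any():
        raise ValueError("counts must be non-negative")
    presence = (combined >= 1).T  # rows = families, columns = species
    return PresenceMatrix(df=presence, provenance="family_counts")


def write_matches(
    row_ids: Sequence[str],
    path: str | Path,
    keep_list: Optional[Iterable[str]] = None,
) -> None:
    """Matched-row list TSV, formatted for downstream manual refinement.

    ``keep_list`` (e.g. the outcome of reciprocal sequence searches in
    discriminatory species) restricts the output when given.
    """
    if keep_list is not None:
        keep = set(keep_list)
        row_ids = [r for r in row_ids if r in keep]
    pd.DataFrame({"row_id": list(row_ids)}).to_csv(path, sep="\t", index=False)


def read_keep_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
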