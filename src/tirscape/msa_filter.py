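"""Alignment gap-column filtering and per-column residue summaries.

Columns with a gap fraction strictly above the threshold (default 40%) are
removed; kept columns are reported as a new->old 1-based index map so that
downstream per-column statistics (motif conservation, reference mapping)
can always be traced back to original alignment coordinates.

Gap characters are ``-`` and ``.``; residues are uppercased on read and any
letter (including ``X``) counts as a residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class Alignment:
    """An ordered protein multiple sequence alignment."""

    records: tuple  # of (sequence_id, aligned string)

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, idx: int) -> str:
        """1-based column access."""
        if not (1 <= idx <= self.n_columns):
            raise IndexError(f"column {idx} out of range 1..{self.n_columns}")
        return "".join(s[idx - 1] for _, s in self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        recs = tuple(
            (r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")
        )
        return cls(records=recs)

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=i, description="") for i, s in self.records],
            str(path),
            "fasta",
        )


def _gap_count(col: str) -> int:
    return sum(1 for c in col if c in GAP_CHARS)


def filter_gap_columns(
    aln: Alignment, max_gap_frac: float = 0.40
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_frac``.

    Returns the filtered alignment and the kept-column list mapping new
    1-based column indices to original 1-based indices (entry ``k`` is the
    original index of new column ``k+1``).  Sequence order is preserved.
    All-gap columns are always removed when ``max_gap_frac < 1``.
    """
    if not (0.0 <= max_gap_frac <= 1.0):
        raise ValueError(f"max_gap_frac must be in [0, 1], got {max_gap_frac}")
    n_seq = aln.n_sequences
    if n_seq == 0:
        return aln, []
    kept = [
        c
        for c in range(1, aln.n_columns + 1)
        if _gap_count(aln.column(c)) / n_seq <= max_gap_frac
    ]
    keep_idx = [c - 1 for c in kept]
    records = tuple((sid, "".join(s[i] for i in keep_idx)) for sid, s in aln.records)
    return Alignment(records=records), kept


@dataclass(frozen=True)
class ColumnProfile:
    column: int  # 1-based index into the alignment it was computed on
    frequencies: dict  # residue -> frequency over non-gap residues
    gap_frac: float
    all_gap: bool


def column_frequencies(
    aln: Alignment, columns: Optional[Sequence[int]] = None
) -> list[ColumnProfile]:
    """Per-column residue frequencies over non-gap characters.

    Frequencies in each profile sum to 1 unless the column is all-gap, in
    which case the profile is flagged and the frequency table is empty.  Gap
    fraction is reported separately.
    """
    if columns is None:
        columns = range(1, aln.n_columns + 1)
    profiles = []
    for c in columns:
        col = aln.column(c)  # range-checks
        residues = [ch for ch in col if ch not in GAP_CHARS]
        gap_frac = (len(col) - len(residues)) / len(col) if col else 0.0
        if residues:
            counts: dict[str, int] = {}
            for ch in residues:
                counts[ch] = counts.get(ch, 0) + 1
            freqs = {ch: n / len(residues) for ch, n in sorted(counts.items())}
            profiles.append(ColumnProfile(c, freqs, gap_frac, all_gap=False))
        else:
            profiles.append(ColumnProfile(c, {}, gap_frac, all_gap=True))
    return profiles


def map_reference_columns(aln: Alignment, ref_id: str) -> dict[int, int]:
    """Map alignment columns to ungapped positions of a reference sequence.

    The mapping is defined exactly for the columns where the reference row is
    non-gap; values are 1-based ungapped positions, strictly increasing.
    Useful for expressing motif columns in the coordinates of a reference
    TIR domain.
    """
    ref = dict(aln.records).get(ref_id)
    if ref is None:
        raise KeyError(f"reference sequence {ref_id!r} not in alignment")
    mapping = {}
    pos = 0
    for col, ch in enumerate(ref, start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[col] = pos
    return mapping


def write_column_map(kept: Sequence[int], path: str | Path) -> None:
    """Kept-column map as two-column TSV (new 1-based index, old 1-based index)."""
    pd.DataFrame(
        {"new_column": range(1, len(kept) + 1), "old_column": list(kept)}
    ).to_csv(path, sep="\t", index=False)


def write_frequency_table(profiles: Sequence[ColumnProfile], path: str | Path) -> None:
    """Frequency table as TSV (column, residue, freq, gap_frac)."""
    rows = []
    for p in profiles:
        if p.all_gap:
            rows.append({"column": p.column, "residue": "", "freq": float("nan"),
                         "gap_frac": p.gap_frac})
        for res, f in p.frequencies.items():
            rows.append({"column": p.column, "residue": res, "freq": f,
                         "gap_frac": p.gap_frac})
    pd.DataFrame(rows, columns=["column", "residue", "freq", "gap_frac"]).to_csv(
        path, sep="\t", index=False
    )
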