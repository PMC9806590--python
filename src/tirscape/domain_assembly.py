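"""Domain-hit assembly and protein architecture classification.

Consumes per-domain hit tables from an HMM search (HMMER3 ``--domtblout``
format or a simple 6-column TSV), removes redundant overlapping hits of the
same domain class, enforces per-class minimum domain lengths, and labels
full-length protein domain architectures (TNP, TNL, TN, TIR-only).

Coordinates are 1-based inclusive envelope coordinates throughout, matching
the hit-table convention.  Overlap between two envelopes is
``min(end1, end2) - max(start1, start2) + 1``.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

DOMAIN_CLASSES = ("TIR", "NBARC", "LRR", "TPR", "OTHER")

ARCH_LABELS = ("TNP", "TNL", "TN", "TIR_ONLY", "TIR_OTHER", "NON_TIR")

#: Fig-1B-style count columns: TNP is counted on its own, never in the others.
COUNT_COLUMNS = ("TNL", "TN", "TIR_ONLY", "TNP")


class HitTableParseError(ValueError):
    """Raised for malformed hit-table lines; carries the line number."""


@dataclass(frozen=True)
class DomainHit:
    """One HMM-vs-protein match with envelope coordinates.

    ``domain_class`` is one of :data:`DOMAIN_CLASSES`, derived from a
    configurable hmm_name -> class mapping at parse time.
    """

    protein_id: str
    hmm_name: str
    domain_class: str
    env_start: int
    env_end: int
    evalue: float

    def __post_init__(self):
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain_class {self.domain_class!r}")
        if self.env_start < 1:
            raise ValueError(f"env_start must be >= 1, got {self.env_start}")
        if self.env_end < self.env_start:
            raise ValueError(
                f"env_end ({self.env_end}) < env_start ({self.env_start})"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")

    @property
    def length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    species_id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered, deduplicated domain string plus an architecture label."""

    protein_id: str
    ordered_domains: tuple  # of (domain_class, env_start, env_end)
    label: str

    def domain_string(self) -> str:
        """e.g. ``"TIR(12-180);NBARC(210-520)"``."""
        return ";".join(f"{c}({s}-{e})" for c, s, e in self.ordered_domains)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping hmm_name -> domain_class."""
    df = pd.read_csv(path, sep="\t", header=None, names=["hmm_name", "domain_class"],
                     comment="#", dtype=str)
    mapping = {}
    for _, row in df.iterrows():
        cls = row["domain_class"].strip().upper()
        if cls not in DOMAIN_CLASSES:
            raise ValueError(
                f"class map entry {row['hmm_name']!r}: unknown class {cls!r}"
            )
        mapping[row["hmm_name"].strip()] = cls
    return mapping


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1


def _detect_format(fields: list[str]) -> str:
    # domtblout data rows have 23 columns (description may add more);
    # the TSV dialect has exactly 6.
    if len(fields) >= 23:
        return "domtblout"
    if len(fields) == 6:
        return "tsv"
    raise ValueError(f"cannot determine hit-table dialect from {len(fields)} fields")


def parse_hit_table(
    path: str | Path,
    class_map: Mapping[str, str],
    max_evalue: float = 0.01,
    fmt: str = "auto",
) -> list[DomainHit]:
    """Parse a per-domain hit table and apply the E-value inclusion cutoff.

    Parameters
    ----------
    path
        HMMER3 ``--domtblout`` file ('#'-comment lines, whitespace-delimited,
        target = protein, query = HMM) or a 6-column TSV
        (protein_id, hmm_name, env_start, env_end, evalue, protein_length).
    class_map
        hmm_name -> domain class; unknown names map to ``OTHER``.
    max_evalue
        Hits with evalue strictly above this are dropped.  For domtblout
        input the per-domain independent E-value (i-Evalue) is used.
    fmt
        ``"auto"`` (default), ``"domtblout"`` or ``"tsv"``.

    Returns hits in file order with envelope coordinates preserved verbatim.
    """
    if max_evalue <= 0:
        raise ValueError(f"max_evalue must be > 0, got {max_evalue}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if fmt == "tsv":
                fields = line.split("\t")
                dialect = "tsv"
            else:
                fields = line.split()
                try:
                    dialect = _detect_format(fields) if fmt == "auto" else fmt
                except ValueError as exc:
                    raise HitTableParseError(f"line {lineno}: {exc}") from None
            try:
                if dialect == "domtblout":
                    protein_id = fields[0]
                    hmm_name = fields[3]
                    evalue = float(fields[12])  # i-Evalue, per-domain
                    env_start = int(fields[19])
                    env_end = int(fields[20])
                else:
                    if len(fields) != 6:
                        raise ValueError(f"expected 6 tab-separated fields, got {len(fields)}")
                    protein_id, hmm_name = fields[0], fields[1]
                    env_start, env_end = int(fields[2]), int(fields[3])
                    evalue = float(fields[4])
            except (ValueError, IndexError) as exc:
                raise HitTableParseError(f"line {lineno}: {exc}") from None
            if env_start < 1 or env_end < env_start:
                raise HitTableParseError(
                    f"line {lineno}: invalid envelope coordinates "
                    f"[{env_start}, {env_end}]"
                )
            if evalue < 0:
                raise HitTableParseError(f"line {lineno}: negative E-value {evalue}")
            if evalue > max_evalue:
                continue
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    hmm_name=hmm_name,
                    domain_class=class_map.get(hmm_name, "OTHER"),
                    env_start=env_start,
                    env_end=env_end,
                    evalue=evalue,
                )
            )
    return hits


def read_proteome_fasta(path: str | Path, species_of: Mapping[str, str] | str) -> list[ProteinRecord]:
    """Load protein records from FASTA.

    ``species_of`` maps protein_id -> species_id, or is a single species id
    applied to every record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        sp = species_of if isinstance(species_of, str) else species_of[pid]
        seq = str(rec.seq).upper()
        records.append(ProteinRecord(protein_id=pid, species_id=sp,
                                     length=len(seq), sequence=seq))
    return records


# ---------------------------------------------------------------------------
# Redundancy removal and length filtering
# ---------------------------------------------------------------------------

def merge_overlapping_hits(hits: Sequence[DomainHit], max_overlap: int = 20) -> list[DomainHit]:
    """Remove redundant same-class hits overlapping by more than ``max_overlap``.

    Hits of the same domain class whose envelopes overlap by strictly more
    than ``max_overlap`` residues are considered redundant (the same domain
    found by different HMMs).  Redundancy is transitive: within each connected
    component of the over-overlap graph exactly one representative is kept —
    the lowest E-value, ties broken by longer envelope, then lexicographic
    hmm_name.  Hits of different domain classes never suppress each other.

    All hits must share one protein_id.  Output is sorted by
    (env_start, env_end, hmm_name).
    """
    hits = list(hits)
    if not hits:
        return []
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")

    kept: list[DomainHit] = []
    by_class: dict[str, list[DomainHit]] = collections.defaultdict(list)
    for h in hits:
        by_class[h.domain_class].append(h)

    for cls_hits in by_class.values():
        n = len(cls_hits)
        # union-find over pairs with overlap > max_overlap
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if _overlap(cls_hits[i], cls_hits[j]) > max_overlap:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        comps: dict[int, list[DomainHit]] = collections.defaultdict(list)
        for i, h in enumerate(cls_hits):
            comps[find(i)].append(h)
        for members in comps.values():
            best = min(members, key=lambda h: (h.evalue, -h.length, h.hmm_name))
            kept.append(best)

    kept.sort(key=lambda h: (h.env_start, h.env_end, h.hmm_name))
    return kept


def filter_domain_length(
    hits: Iterable[DomainHit], min_len: Mapping[str, int]
) -> list[DomainHit]:
    """Drop hits shorter than the per-class minimum; unlisted classes pass."""
    return [h for h in hits if h.length >= min_len.get(h.domain_class, 0)]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_architecture(
    protein: ProteinRecord,
    domains: Sequence[DomainHit],
    max_len_tir_only: int = 400,
    require_tir_first: bool = False,
) -> ProteinArchitecture:
    """Label a protein's domain architecture.

    Rules applied in order to the deduplicated, length-filtered hits:

    1. TIR + NBARC + TPR present -> ``TNP``
    2. TIR + NBARC + LRR present -> ``TNL``
    3. TIR + NBARC present -> ``TN``
    4. TIR present, length < ``max_len_tir_only``, and no non-TIR domain
       -> ``TIR_ONLY``
    5. TIR present otherwise -> ``TIR_OTHER``
    6. no TIR -> ``NON_TIR``

    TNP takes precedence over TNL: a TIR+NBARC+LRR+TPR protein is a TNP.
    With ``require_tir_first`` the TIR/NBARC rules additionally require the
    first TIR to start before the first NBARC (off by default; domain order
    is descriptive, not diagnostic).
    """
    for d in domains:
        if d.protein_id != protein.protein_id:
            raise ValueError(
                f"hit for {d.protein_id!r} passed with protein {protein.protein_id!r}"
            )
    ordered = tuple(
        (h.domain_class, h.env_start, h.env_end)
        for h in sorted(domains, key=lambda h: (h.env_start, h.env_end, h.domain_class))
    )
    classes = {h.domain_class for h in domains}
    has_tir = "TIR" in classes
    has_nbarc = "NBARC" in classes
    if require_tir_first and has_tir and has_nbarc:
        first_tir = min(h.env_start for h in domains if h.domain_class == "TIR")
        first_nbarc = min(h.env_start for h in domains if h.domain_class == "NBARC")
        has_nbarc = first_tir < first_nbarc

    if has_tir and has_nbarc and "TPR" in classes:
        label = "TNP"
    elif has_tir and has_nbarc and "LRR" in classes:
        label = "TNL"
    elif has_tir and has_nbarc:
        label = "TN"
    elif has_tir and protein.length < max_len_tir_only and classes == {"TIR"}:
        label = "TIR_ONLY"
    elif has_tir:
        label = "TIR_OTHER"
    else:
        label = "NON_TIR"
    return ProteinArchitecture(protein_id=protein.protein_id,
                               ordered_domains=ordered, label=label)


def classify_proteome(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    max_overlap: int = 20,
    min_len: Optional[Mapping[str, int]] = None,
    max_len_tir_only: int = 400,
    require_tir_first: bool = False,
) -> list[ProteinArchitecture]:
    """Deduplicate, length-filter and classify every protein in one pass."""
    if min_len is None:
        min_len = {"TIR": 50, "NBARC": 150}
    hits_by_protein: dict[str, list[DomainHit]] = collections.defaultdict(list)
    for h in hits:
        hits_by_protein[h.protein_id].append(h)
    out = []
    for prot in proteins:
        cleaned = merge_overlapping_hits(hits_by_protein.get(prot.protein_id, []),
                                         max_overlap=max_overlap)
        cleaned = filter_domain_length(cleaned, min_len)
        out.append(
            classify_architecture(prot, cleaned, max_len_tir_only=max_len_tir_only,
                                  require_tir_first=require_tir_first)
        )
    return out


def tabulate_architectures(
    architectures: Sequence[ProteinArchitecture],
    species_of: Mapping[str, str],
    taxonomy_species: Iterable[str],
) -> pd.DataFrame:
    """Count TNL / TN / TIR-only / TNP architectures per species.

    TNP is counted in its own column only.  TIR_OTHER and NON_TIR proteins
    contribute to no column, so each row total equals the number of
    TIR-positive proteins in that species excluding TIR_OTHER.
    """
    known = set(taxonomy_species)
    counts = pd.DataFrame(0, index=sorted(known), columns=list(COUNT_COLUMNS),
                          dtype=int)
    for arch in architectures:
        sp = species_of.get(arch.protein_id)
        if sp is None or sp not in known:
            raise ValueError(
                f"protein {arch.protein_id!r}: species {sp!r} not in taxonomy"
            )
        if arch.label in COUNT_COLUMNS:
            counts.loc[sp, arch.label] += 1
    counts.index.name = "species_id"
    return counts


def write_architecture_table(
    architectures: Sequence[ProteinArchitecture],
    species_of: Mapping[str, str],
    path: str | Path,
) -> None:
    """Per-protein architecture TSV: protein_id, species, label, domain string."""
    rows = [
        {
            "protein_id": a.protein_id,
            "species_id": species_of[a.protein_id],
            "label": a.label,
            "domains": a.domain_string(),
        }
        for a in architectures
    ]
    pd.DataFrame(rows, columns=["protein_id", "species_id", "label", "domains"]).to_csv(
        path, sep="\t", index=False
    )
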