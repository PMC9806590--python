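"""Shared threshold configuration.

Every numeric cutoff used across the pipeline lives here so that all stages
agree on the strictness conventions.  Comparisons are strict where noted:

* ``max_overlap_aa`` — two same-class domain hits are redundant iff their
  envelope overlap is strictly greater than this many residues.
* ``max_len_tir_only`` — a TIR-only protein is strictly shorter than this.
* ``max_gap_frac`` — an alignment column is removed iff its gap fraction is
  strictly greater than this.
* ``min_ufboot`` / ``min_sh_alrt`` — a clade qualifies iff its support is
  strictly greater than the threshold.
* ``tpm_threshold`` — a gene counts as expressed iff tpm is strictly greater.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class ThresholdConfig:
    """Numeric thresholds shared by all pipeline stages.

    Defaults reflect a conservative domain-annotation screen on plant
    proteomes: an E-value inclusion cutoff of 0.01, redundant-hit removal at
    >20 aa envelope overlap, minimum domain lengths of 50 aa (TIR) and
    150 aa (NBARC), a 400 aa ceiling for TIR-only proteins, removal of
    alignment columns with >40% gaps, clade support cutoffs of >90 ultrafast
    bootstrap and >80 SH-aLRT, a two-lineage minimum for taxonomically
    shared clades, and a tpm>0 expression call.
    """

    max_evalue: float = 0.01
    max_overlap_aa: int = 20
    min_len_tir: int = 50
    min_len_nbarc: int = 150
    max_len_tir_only: int = 400
    max_gap_frac: float = 0.40
    min_ufboot: float = 90.0
    min_sh_alrt: Optional[float] = 80.0
    min_lineages: int = 2
    tpm_threshold: float = 0.0
    star_alphas: tuple[float, float, float] = (0.05, 0.01, 0.001)

    def validate(self) -> list[str]:
        """Return a list of human-readable problems; empty if valid."""
        problems = []
        if self.max_evalue <= 0:
            problems.append(f"max_evalue must be > 0, got {self.max_evalue}")
        if self.max_overlap_aa < 0:
            problems.append(f"max_overlap_aa must be >= 0, got {self.max_overlap_aa}")
        for name in ("min_len_tir", "min_len_nbarc", "max_len_tir_only"):
            v = getattr(self, name)
            if v < 1:
                problems.append(f"{name} must be >= 1, got {v}")
        if not (0.0 <= self.max_gap_frac <= 1.0):
            problems.append(f"max_gap_frac must be in [0, 1], got {self.max_gap_frac}")
        if not (0.0 <= self.min_ufboot <= 100.0):
            problems.append(f"min_ufboot must be in [0, 100], got {self.min_ufboot}")
        if self.min_sh_alrt is not None and not (0.0 <= self.min_sh_alrt <= 100.0):
            problems.append(f"min_sh_alrt must be in [0, 100], got {self.min_sh_alrt}")
        if self.min_lineages < 1:
            problems.append(f"min_lineages must be >= 1, got {self.min_lineages}")
        if self.tpm_threshold < 0:
            problems.append(f"tpm_threshold must be >= 0, got {self.tpm_threshold}")
        alphas = self.star_alphas
        if len(alphas) != 3 or not all(0 < a <= 1 for a in alphas) or not (
            alphas[0] > alphas[1] > alphas[2]
        ):
            problems.append(
                f"star_alphas must be three decreasing values in (0, 1], got {alphas}"
            )
        return problems

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["star_alphas"] = list(self.star_alphas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        d = dict(d)
        if "star_alphas" in d:
            d["star_alphas"] = tuple(d["star_alphas"])
        return cls(**d)

    def min_len_map(self) -> dict[str, int]:
        """Per-class minimum domain lengths used by the length filter."""
        return {"TIR": self.min_len_tir, "NBARC": self.min_len_nbarc}


DEFAULT_THRESHOLDS = ThresholdConfig()
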