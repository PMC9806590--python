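"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

Stands in for downloaded proteomes, inferred trees, orthogroup tables and
RNA-seq: each generator is a pure function of (spec, seed) and emits exactly
the text formats the analysis modules read, together with a ground-truth
object sufficient to score the corresponding stage.

Protein sequences are random residues — the classifiers read hit tables,
not sequence content — and trees are random-join topologies with supports
assigned by specification rather than inferred, which is all the clade
detector needs.  Injected noise is designed to be filterable: spurious hits
carry E-values above the inclusion cutoff or sub-minimum domain lengths,
and redundant same-class hits overlap their true domain by more than the
redundancy limit with strictly worse E-values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .domain_assembly import DomainHit, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_LINEAGES = ("Rosids", "Asterids", "monocots", "magnoliids")

#: hmm_name -> domain class used by the simulated hit tables
DEFAULT_CLASS_MAP = {
    "TIR_hmm1": "TIR",
    "TIR_hmm2": "TIR",
    "TIR_like": "TIR",
    "NBARC_hmm": "NBARC",
    "NBARC_alt": "NBARC",
    "LRR_hmm": "LRR",
    "TPR_hmm1": "TPR",
    "TPR_hmm2": "TPR",
}

_REDUNDANT_ALT = {"TIR": ("TIR_hmm2", "TIR_like"), "NBARC": ("NBARC_alt",),
                  "TPR": ("TPR_hmm2",)}
_PRIMARY_HMM = {"TIR": "TIR_hmm1", "NBARC": "NBARC_hmm", "LRR": "LRR_hmm",
                "TPR": "TPR_hmm1"}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSpec:
    """Planted per-species architecture counts and hit-noise parameters."""

    n_species: int = 10
    counts: tuple = (("TNL", 5), ("TN", 3), ("TIR_ONLY", 2), ("TNP", 1), ("NON_TIR", 9))
    spurious_hit_rate: float = 0.3  # expected filterable spurious hits per protein
    redundant_hit_prob: float = 0.4  # chance of a redundant same-class hit per domain
    evalue_log10_range: tuple = (-30.0, -4.0)

    def validate(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if any(n < 0 for _, n in self.counts):
            raise ValueError("architecture counts must be >= 0")
        for p in (self.spurious_hit_rate, self.redundant_hit_prob):
            if p < 0:
                raise ValueError("noise rates must be >= 0")


@dataclass(frozen=True)
class PlantedClade:
    n_leaves: int
    lineages: tuple  # >= 2 lineage ids spanned
    ufboot: float = 95.0
    sh_alrt: float = 90.0


@dataclass(frozen=True)
class TreeSpec:
    """Planted well-supported mixed-lineage clades plus decoys.

    Decoys alternate between two failure modes: multi-lineage clades with
    support below threshold, and well-supported single-lineage clades.
    """

    n_leaves: int = 200
    lineages: tuple = DEFAULT_LINEAGES
    species_per_lineage: int = 3
    clades: tuple = (
        PlantedClade(18, ("Rosids", "Asterids")),
        PlantedClade(14, ("Rosids", "Asterids", "monocots")),
        PlantedClade(12, ("monocots", "magnoliids")),
        PlantedClade(10, ("Asterids", "magnoliids")),
    )
    n_decoys: int = 12
    decoy_size: int = 8
    decoy_low_support: tuple = (20.0, 85.0)  # ufboot range for failing decoys

    def validate(self):
        planted = sum(c.n_leaves for c in self.clades)
        if planted + self.n_decoys * self.decoy_size > self.n_leaves:
            raise ValueError("planted clades and decoys exceed n_leaves")
        for c in self.clades:
            if len(c.lineages) < 2:
                raise ValueError("planted clades must span >= 2 lineages")
            if c.n_leaves < len(c.lineages):
                raise ValueError("clade smaller than its lineage span")
            unknown = set(c.lineages) - set(self.lineages)
            if unknown:
                raise ValueError(f"unknown lineages in clade spec: {sorted(unknown)}")


@dataclass(frozen=True)
class OgSpec:
    """Orthogroup table with planted pattern-matching rows."""

    n_og: int = 1000
    n_species: int = 10
    n_planted: int = 7
    n_required_present: int = 5
    background_presence: float = 0.3
    max_rejection_tries: int = 200

    def validate(self):
        if not (0 <= self.n_required_present <= self.n_species):
            raise ValueError("n_required_present out of range")
        if self.n_planted > self.n_og:
            raise ValueError("more planted rows than orthogroups")
        if not (0.0 <= self.background_presence <= 1.0):
            raise ValueError("background_presence must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionSpec:
    """Expression study with planted trigger-responsive genes."""

    n_genes: int = 12
    n_responsive: int = 6
    n_triggered: int = 5
    n_control: int = 5
    detection_prob: float = 1.0  # P(expressed | responsive, triggered)
    leak_prob: float = 0.0  # P(expressed | responsive, control)
    background_expression_prob: float = 0.6  # non-responsive genes, any sample
    lognormal_mu: float = 2.0
    lognormal_sigma: float = 1.0

    def validate(self):
        if self.n_triggered < 1 or self.n_control < 1:
            raise ValueError("need >= 1 triggered and >= 1 control sample")
        if self.n_responsive > self.n_genes:
            raise ValueError("n_responsive exceeds n_genes")
        for p in (self.detection_prob, self.leak_prob, self.background_expression_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Bundle of all stage specs; the study conditions for a synthetic run."""

    proteome: ProteomeSpec = ProteomeSpec()
    tree: TreeSpec = TreeSpec()
    og: OgSpec = OgSpec()
    expression: ExpressionSpec = ExpressionSpec()


# ---------------------------------------------------------------------------
# Proteome + hit table
# ---------------------------------------------------------------------------

@dataclass
class SimulatedProteome:
    proteins: list  # ProteinRecord
    hits: list  # DomainHit (noisy; pre-filter)
    true_labels: dict  # protein_id -> architecture label
    species_of: dict  # protein_id -> species_id
    species_lineage: dict  # species_id -> lineage_id
    n_redundant_injected: int
    n_spurious_injected: int

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "proteome.fasta"
        with open(fasta, "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.protein_id}\n{p.sequence}\n")
        hits_path = outdir / "hits.tsv"
        with open(hits_path, "w") as fh:
            lengths = {p.protein_id: p.length for p in self.proteins}
            for h in self.hits:
                fh.write(
                    f"{h.protein_id}\t{h.hmm_name}\t{h.env_start}\t{h.env_end}\t"
                    f"{h.evalue!r}\t{lengths[h.protein_id]}\n"
                )
        class_map_path = outdir / "class_map.tsv"
        with open(class_map_path, "w") as fh:
            for name, cls in DEFAULT_CLASS_MAP.items():
                fh.write(f"{name}\t{cls}\n")
        tax_path = outdir / "taxonomy.tsv"
        rows = [
            {"leaf_id": p.protein_id, "species_id": self.species_of[p.protein_id],
             "lineage_id": self.species_lineage[self.species_of[p.protein_id]]}
            for p in self.proteins
        ]
        pd.DataFrame(rows).to_csv(tax_path, sep="\t", index=False)
        truth_path = outdir / "truth_architectures.tsv"
        pd.DataFrame(
            [{"protein_id": pid, "label": lab} for pid, lab in self.true_labels.items()]
        ).to_csv(truth_path, sep="\t", index=False)
        return {"fasta": fasta, "hits": hits_path, "class_map": class_map_path,
                "taxonomy": tax_path, "truth": truth_path}


def _random_sequence(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def _evalue(rng: random.Random, spec: ProteomeSpec) -> float:
    lo, hi = spec.evalue_log10_range
    return 10.0 ** rng.uniform(lo, hi)


_ARCH_PLAN = {
    # label -> (protein length range, list of (class, start, min_len, max_len))
    "TNL": ((850, 1100), [("TIR", 10, 120, 180), ("NBARC", 220, 200, 300),
                          ("LRR", 560, 150, 250)]),
    "TN": ((550, 700), [("TIR", 10, 120, 180), ("NBARC", 220, 200, 300)]),
    "TNP": ((850, 1100), [("TIR", 10, 120, 180), ("NBARC", 220, 200, 300),
                          ("TPR", 560, 80, 150)]),
    "TIR_ONLY": ((180, 399), [("TIR", 5, 60, 160)]),
    "NON_TIR": ((200, 600), []),
}


def simulate_proteome_hits(spec: ProteomeSpec, seed: int) -> SimulatedProteome:
    """Generate a multi-species proteome, a noisy hit table and its truth.

    Planted domains always survive the filters (TIR >= 50 aa, NBARC >= 150 aa,
    E-values far below the cutoff; TIR-only proteins < 400 aa).  Spurious
    hits are injected at ``spurious_hit_rate`` per protein and are filterable
    by construction (E-value above 0.01 or domain length below the class
    minimum); redundant same-class hits overlap their true domain by > 20 aa
    with strictly worse E-values, exercising the redundancy merge.
    """
    spec.validate()
    rng = random.Random(seed)
    lineage_cycle = DEFAULT_LINEAGES
    proteins, hits = [], []
    true_labels, species_of, species_lineage = {}, {}, {}
    n_redundant = n_spurious = 0

    for si in range(spec.n_species):
        sp = f"sp{si + 1:02d}"
        species_lineage[sp] = lineage_cycle[si % len(lineage_cycle)]
        pi = 0
        for label, count in spec.counts:
            for _ in range(count):
                pi += 1
                pid = f"{sp}_p{pi:03d}"
                (lo, hi), plan = _ARCH_PLAN[label]
                length = rng.randint(lo, hi)
                doms = []
                for cls, start0, dlo, dhi in plan:
                    start = start0 + rng.randint(0, 8)
                    dlen = rng.randint(dlo, dhi)
                    end = min(start + dlen - 1, length - 1)
                    doms.append((cls, start, end))
                if label == "TIR_ONLY":
                    # keep the single TIR inside a <400 aa protein, >= 50 aa
                    cls, start, end = doms[0]
                    end = min(end, length - 1)
                    if end - start + 1 < 50:
                        end = start + 49
                    doms = [(cls, start, end)]
                proteins.append(
                    ProteinRecord(pid, sp, length, _random_sequence(rng, length))
                )
                true_labels[pid] = label
                species_of[pid] = sp
                for cls, start, end in doms:
                    ev = _evalue(rng, spec)
                    hits.append(DomainHit(pid, _PRIMARY_HMM[cls], cls, start, end, ev))
                    alts = _REDUNDANT_ALT.get(cls)
                    if alts and rng.random() < spec.redundant_hit_prob:
                        # shifted alternate-HMM hit; overlap with the true
                        # domain stays > 20 aa, E-value strictly worse
                        shift = rng.randint(-10, 10)
                        s2 = max(1, start + shift)
                        e2 = max(s2 + (end - start) - rng.randint(0, 5), s2)
                        hits.append(
                            DomainHit(pid, rng.choice(alts), cls, s2, e2,
                                      min(ev * 10 ** rng.uniform(1, 3), 9e-3))
                        )
                        n_redundant += 1
                # filterable spurious hits
                n_extra = int(rng.random() < spec.spurious_hit_rate)
                for _ in range(n_extra):
                    n_spurious += 1
                    if rng.random() < 0.5:
                        # E-value above the 0.01 inclusion cutoff
                        cls = rng.choice(["TIR", "NBARC", "LRR", "TPR"])
                        s = rng.randint(1, max(1, length - 60))
                        e = min(s + rng.randint(50, 200), length)
                        hits.append(DomainHit(pid, _PRIMARY_HMM[cls], cls, s, e,
                                              rng.uniform(0.02, 5.0)))
                    else:
                        # included E-value but sub-minimum length (TIR < 50 aa);
                        # E-value worse than any true hit and placement clear
                        # of planted domains, so it reaches the length filter
                        # intact and never perturbs the redundancy merge
                        for _try in range(50):
                            s = rng.randint(1, max(1, length - 50))
                            e = s + rng.randint(10, 48)
                            if all(
                                e < ds - 12 or s > de + 12 for _, ds, de in doms
                            ):
                                hits.append(
                                    DomainHit(pid, "TIR_like", "TIR", s, e,
                                              rng.uniform(1e-3, 9e-3))
                                )
                                break
                        else:
                            n_spurious -= 1
    return SimulatedProteome(proteins, hits, true_labels, species_of,
                             species_lineage, n_redundant, n_spurious)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "name", "length", "sh", "uf")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []
        self.length = 0.1
        self.sh = None
        self.uf = None

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.4f}"
        inner = ",".join(c.newick() for c in self.children)
        label = "" if self.uf is None else f"{self.sh:.1f}/{self.uf:.1f}"
        return f"({inner}){label}:{self.length:.4f}"


@dataclass
class SimulatedTree:
    newick: str  # dual-dialect, rooted
    taxonomy: pd.DataFrame  # leaf_id, species_id, lineage_id
    planted_leafsets: list  # list of frozenset of leaf ids
    decoy_leafsets: list

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tree_path = outdir / "tree.nwk"
        tree_path.write_text(self.newick + "\n")
        tax_path = outdir / "tree_taxonomy.tsv"
        self.taxonomy.to_csv(tax_path, sep="\t", index=False)
        truth_path = outdir / "truth_clades.tsv"
        rows = [{"clade": f"planted_{i + 1}", "leaves": ",".join(sorted(s))}
                for i, s in enumerate(self.planted_leafsets)]
        pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
        return {"tree": tree_path, "taxonomy": tax_path, "truth": truth_path}


def _random_join(rng: random.Random, nodes: list) -> _Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = _Node(children=[a, b])
        nodes.append(parent)
    return nodes[0]


def simulate_tree(spec: TreeSpec, seed: int) -> SimulatedTree:
    """Random-join topology with planted qualifying clades and failing decoys.

    Planted clades receive dual supports above the detection thresholds and
    leaves drawn from all their assigned lineages; every other internal node
    (including decoy roots of the low-support kind) receives supports below
    threshold, and well-supported decoys are confined to a single lineage.
    """
    spec.validate()
    rng = random.Random(seed)
    species = {}
    for lin in spec.lineages:
        for k in range(spec.species_per_lineage):
            species.setdefault(lin, []).append(f"{lin[:3].lower()}_sp{k + 1}")

    leaf_counter = 0
    tax_rows = []

    def new_leaf(lineage: str) -> _Node:
        nonlocal leaf_counter
        leaf_counter += 1
        name = f"t{leaf_counter:04d}"
        sp = rng.choice(species[lineage])
        tax_rows.append({"leaf_id": name, "species_id": sp, "lineage_id": lineage})
        node = _Node(name=name)
        node.length = rng.uniform(0.01, 0.4)
        return node

    def low_supports(node: _Node):
        for c in node.children:
            if c.children:
                c.sh = rng.uniform(10.0, 75.0)
                c.uf = rng.uniform(*spec.decoy_low_support)
                low_supports(c)

    def build_subtree(lineages: Sequence[str], n: int) -> _Node:
        leaves = [new_leaf(lineages[i % len(lineages)]) for i in range(n)]
        sub = _random_join(rng, leaves)
        sub.length = rng.uniform(0.05, 0.4)
        low_supports(sub)
        return sub

    planted_roots, planted_sets = [], []
    for clade in spec.clades:
        sub = build_subtree(clade.lineages, clade.n_leaves)
        sub.sh = clade.sh_alrt
        sub.uf = clade.ufboot
        planted_roots.append(sub)
        planted_sets.append(frozenset(r["leaf_id"] for r in tax_rows[-clade.n_leaves:]))

    decoy_roots, decoy_sets = [], []
    for d in range(spec.n_decoys):
        if d % 2 == 0:
            # multi-lineage but under-supported
            sub = build_subtree(list(spec.lineages[:2]), spec.decoy_size)
            sub.sh = rng.uniform(10.0, 75.0)
            sub.uf = rng.uniform(*spec.decoy_low_support)
        else:
            # well-supported but single-lineage
            lin = spec.lineages[d % len(spec.lineages)]
            sub = build_subtree([lin], spec.decoy_size)
            sub.sh = rng.uniform(85.0, 99.0)
            sub.uf = rng.uniform(92.0, 99.9)
        decoy_roots.append(sub)
        decoy_sets.append(frozenset(r["leaf_id"] for r in tax_rows[-spec.decoy_size:]))

    n_background = spec.n_leaves - leaf_counter
    background = [new_leaf(rng.choice(spec.lineages)) for _ in range(n_background)]
    root = _random_join(rng, planted_roots + decoy_roots + background)
    # supports for the join scaffold above the planted/decoy roots
    def scaffold_supports(node: _Node):
        if node.children and node.uf is None:
            node.sh = rng.uniform(10.0, 75.0)
            node.uf = rng.uniform(*spec.decoy_low_support)
        if node.uf is not None and node not in planted_roots and node not in decoy_roots:
            for c in node.children:
                if c.children and c not in planted_roots and c not in decoy_roots:
                    scaffold_supports(c)

    # assign low supports to every scaffold internal node not already set
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.children and nd.uf is None:
            nd.sh = rng.uniform(10.0, 75.0)
            nd.uf = rng.uniform(*spec.decoy_low_support)
        if nd in planted_roots or nd in decoy_roots:
            continue
        stack.extend(nd.children)
    root.sh = root.uf = None  # the root carries no support

    newick = root.newick()
    # strip the root's branch length and trailing label
    if newick.endswith(f":{root.length:.4f}"):
        newick = newick[: -len(f":{root.length:.4f}")]
    return SimulatedTree(
        newick=newick + ";",
        taxonomy=pd.DataFrame(tax_rows),
        planted_leafsets=planted_sets,
        decoy_leafsets=decoy_sets,
    )


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

@dataclass
class SimulatedOgTable:
    table: pd.DataFrame  # OG id index, per-species comma-separated gene lists
    pattern: dict  # species_id -> required presence
    planted_ids: list

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        og_path = outdir / "orthogroups.tsv"
        out = self.table.copy()
        out.index.name = "Orthogroup"
        out.to_csv(og_path, sep="\t")
        pat_path = outdir / "pattern.tsv"
        with open(pat_path, "w") as fh:
            for sp, pres in self.pattern.items():
                fh.write(f"{sp}\t{int(pres)}\n")
        truth_path = outdir / "truth_planted_ogs.tsv"
        pd.DataFrame({"row_id": self.planted_ids}).to_csv(truth_path, sep="\t",
                                                          index=False)
        return {"orthogroups": og_path, "pattern": pat_path, "truth": truth_path}


def simulate_og_matrix(spec: OgSpec, seed: int) -> SimulatedOgTable:
    """Orthogroup gene-list table with planted pattern-matching rows.

    The query pattern requires presence in the first ``n_required_present``
    species and absence elsewhere.  Background rows are drawn i.i.d. per
    species at ``background_presence`` and resampled if they accidentally
    match the pattern, so the planted rows are the unique matches.
    """
    spec.validate()
    rng = random.Random(seed)
    species = [f"og_sp{k + 1:02d}" for k in range(spec.n_species)]
    pattern = {sp: (i < spec.n_required_present) for i, sp in enumerate(species)}
    planted_idx = sorted(rng.sample(range(spec.n_og), spec.n_planted))
    planted_set = set(planted_idx)

    gene_counter = 0

    def gene_list(sp: str, present: bool) -> str:
        nonlocal gene_counter
        if not present:
            return ""
        n = rng.randint(1, 3)
        genes = []
        for _ in range(n):
            gene_counter += 1
            genes.append(f"{sp}_g{gene_counter:05d}")
        return ", ".join(genes)

    rows = {}
    planted_ids = []
    target = [pattern[sp] for sp in species]
    for i in range(spec.n_og):
        og_id = f"OG{i + 1:07d}"
        if i in planted_set:
            presence = list(target)
            planted_ids.append(og_id)
        else:
            for _ in range(spec.max_rejection_tries):
                presence = [rng.random() < spec.background_presence for _ in species]
                if presence != target:
                    break
            else:
                raise RuntimeError(
                    "could not draw a non-matching background row; "
                    "increase n_species or adjust background_presence"
                )
        rows[og_id] = [gene_list(sp, p) for sp, p in zip(species, presence)]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    return SimulatedOgTable(table=table, pattern=pattern, planted_ids=planted_ids)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExpression:
    tpm: pd.DataFrame  # genes x samples
    triggered: dict  # sample_id -> bool
    responsive_genes: list

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tpm_path = outdir / "tpm.tsv"
        out = self.tpm.copy()
        out.index.name = "gene_id"
        out.to_csv(tpm_path, sep="\t")
        meta_path = outdir / "samples.tsv"
        pd.DataFrame(
            {
                "sample_id": list(self.tpm.columns),
                "triggered": [int(self.triggered[s]) for s in self.tpm.columns],
                "study_id": "synthetic_study",
            }
        ).to_csv(meta_path, sep="\t", index=False)
        truth_path = outdir / "truth_responsive_genes.tsv"
        pd.DataFrame({"gene_id": self.responsive_genes}).to_csv(truth_path, sep="\t",
                                                                index=False)
        return {"tpm": tpm_path, "meta": meta_path, "truth": truth_path}


def simulate_expression(spec: ExpressionSpec, seed: int) -> SimulatedExpression:
    """tpm table with planted trigger-responsive genes.

    Responsive genes are silent in controls except at ``leak_prob`` and
    expressed in triggered samples at ``detection_prob``; non-responsive
    genes are expressed independently of trigger status.  Non-zero tpm
    magnitudes are lognormal — only exceedance of the 0 threshold matters
    for the association test, so magnitudes are display-level realism.
    """
    spec.validate()
    rng = random.Random(seed)
    samples = [f"trig_{i + 1}" for i in range(spec.n_triggered)] + [
        f"ctrl_{i + 1}" for i in range(spec.n_control)
    ]
    triggered = {s: s.startswith("trig_") for s in samples}
    responsive = [f"tironly_{i + 1:02d}" for i in range(spec.n_responsive)]
    others = [f"gene_{i + 1:04d}" for i in range(spec.n_genes - spec.n_responsive)]

    def tpm_value() -> float:
        return rng.lognormvariate(spec.lognormal_mu, spec.lognormal_sigma)

    data = {}
    for g in responsive + others:
        row = []
        for s in samples:
            if g in responsive:
                p = spec.detection_prob if triggered[s] else spec.leak_prob
            else:
                p = spec.background_expression_prob
            row.append(tpm_value() if rng.random() < p else 0.0)
        data[g] = row
    tpm = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return SimulatedExpression(tpm=tpm, triggered=triggered,
                               responsive_genes=responsive)


# ---------------------------------------------------------------------------
# Full-run bundle
# ---------------------------------------------------------------------------

def generate_all(spec: SimulationSpec, seed: int, outdir: str | Path) -> dict:
    """Write every synthetic input for a full pipeline run under ``outdir``.

    Stage seeds are expanded deterministically from the single top-level
    seed.  Returns the generated objects and file paths keyed by stage,
    including a small gapped alignment for the column-filtering stage.
    """
    rng = random.Random(seed)
    subseeds = [rng.randrange(2**31) for _ in range(5)]
    outdir = Path(outdir)

    proteome = simulate_proteome_hits(spec.proteome, subseeds[0])
    tree = simulate_tree(spec.tree, subseeds[1])
    og = simulate_og_matrix(spec.og, subseeds[2])
    expr = simulate_expression(spec.expression, subseeds[3])

    paths = {
        "proteome": proteome.write(outdir / "proteome"),
        "tree": tree.write(outdir / "tree"),
        "og": og.write(outdir / "og"),
        "expression": expr.write(outdir / "expression"),
    }

    # small gapped alignment for the MSA-filtering stage
    arng = random.Random(subseeds[4])
    n_seq, n_col = 20, 120
    aln_path = outdir / "alignment" / "aln.fasta"
    aln_path.parent.mkdir(parents=True, exist_ok=True)
    with open(aln_path, "w") as fh:
        for i in range(n_seq):
            row = "".join(
                "-" if arng.random() < 0.3 else arng.choice(AMINO_ACIDS)
                for _ in range(n_col)
            )
            fh.write(f">aln_seq{i + 1:02d}\n{row}\n")
    paths["alignment"] = {"alignment": aln_path}

    return {
        "objects": {"proteome": proteome, "tree": tree, "og": og,
                    "expression": expr},
        "paths": paths,
    }


def full_run_config(bundle_paths: dict, out_dir: str | Path, seed: int) -> dict:
    """Pipeline configuration covering every stage of a synthetic bundle."""
    p = bundle_paths
    return {
        "seed": seed,
        "out_dir": str(out_dir),
        "stages": {
            "classify": {
                "hits": str(p["proteome"]["hits"]),
                "proteome": str(p["proteome"]["fasta"]),
                "taxonomy": str(p["proteome"]["taxonomy"]),
                "class_map": str(p["proteome"]["class_map"]),
            },
            "filter_msa": {"alignment": str(p["alignment"]["alignment"])},
            "shared_clades": {
                "tree": str(p["tree"]["tree"]),
                "dialect": "dual",
                "taxonomy": str(p["tree"]["taxonomy"]),
            },
            "cooccur": {
                "orthogroups": str(p["og"]["orthogroups"]),
                "pattern": str(p["og"]["pattern"]),
            },
            "expr_assoc": {
                "tpm": str(p["expression"]["tpm"]),
                "meta": str(p["expression"]["meta"]),
            },
        },
    }
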