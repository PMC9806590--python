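"""Detection of taxonomically shared, well-supported clades on phylogenies.

Reads Newick trees whose internal node labels carry branch support in one of
two dialects: ``single`` (one ultrafast-bootstrap value, e.g. ``"95"``) or
``dual`` (``"SH-aLRT/UFboot"``, e.g. ``"80/95"``, as written by ML inference
run with both an SH-aLRT test and ultrafast bootstrapping).  A clade is
*taxonomically shared* when its support exceeds the thresholds (strictly)
and its leaves span at least ``min_lineages`` lineages from a user-supplied
taxonomy (e.g. Rosids / Asterids / monocots / magnoliids); the taxonomy is
never inferred.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .cooccurrence import PresenceMatrix


class SupportParseError(ValueError):
    """Raised when an internal node label cannot be parsed under the dialect."""


@dataclass
class AnnotatedTree:
    """Rooted phylogeny with per-node support and leaf taxonomy annotation.

    ``tree`` is a dendropy tree whose internal nodes carry ``sh_alrt`` and
    ``ufboot`` attributes (``None`` when absent).  ``leaf_annotations`` maps
    leaf_id -> (species_id, lineage_id).
    """

    tree: dendropy.Tree
    leaf_annotations: dict

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def lineage_of(self, leaf_id: str) -> str:
        return self.leaf_annotations[leaf_id][1]

    def species_of(self, leaf_id: str) -> str:
        return self.leaf_annotations[leaf_id][0]


@dataclass(frozen=True)
class CladeGroup:
    """A well-supported clade spanning multiple lineages."""

    member_leaves: frozenset
    lineages: frozenset
    ufboot: float
    sh_alrt: Optional[float]
    group_label: str

    @property
    def size(self) -> int:
        return len(self.member_leaves)


def _parse_support_label(label: Optional[str], dialect: str):
    """Return (sh_alrt, ufboot), either possibly None."""
    if label is None or label.strip() == "":
        return None, None
    label = label.strip()
    try:
        if dialect == "dual":
            if "/" in label:
                sh_s, uf_s = label.split("/", 1)
                return float(sh_s), float(uf_s)
            # tolerate single-value labels in a dual-dialect file
            return None, float(label)
        if dialect == "single":
            return None, float(label)
    except ValueError:
        pass
    raise SupportParseError(
        f"cannot parse support label {label!r} under {dialect!r} dialect"
    )


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str]]:
    """Taxonomy TSV (leaf_id, species_id, lineage_id) -> annotation dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"leaf_id", "species_id", "lineage_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxonomy table must have columns {sorted(required)}")
    return {r.leaf_id: (r.species_id, r.lineage_id) for r in df.itertuples()}


def parse_newick_with_support(
    path: str | Path,
    dialect: str = "dual",
    taxonomy: Optional[Mapping[str, tuple[str, str]]] = None,
) -> AnnotatedTree:
    """Parse a support-annotated Newick tree.

    Dual-dialect labels ``"80/95"`` become (sh_alrt 80, ufboot 95); single
    labels ``"95"`` become (absent, ufboot 95); unlabeled nodes carry no
    support.  Support values must lie in [0, 100].  Unrooted trees (basal
    polytomy) are midpoint-rooted when branch lengths are available.

    ``taxonomy`` maps leaf_id -> (species_id, lineage_id); every leaf must be
    covered when it is given.
    """
    if dialect not in ("single", "dual"):
        raise ValueError(f"unknown dialect {dialect!r}")
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    # unrooted convention: basal polytomy -> midpoint root
    root = tree.seed_node
    if len(root.child_nodes()) > 2 and all(
        e.length is not None for e in tree.preorder_edge_iter() if e.head_node is not root
    ):
        tree.reroot_at_midpoint(update_bipartitions=False)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sh_alrt = node.ufboot = None
            continue
        sh, uf = _parse_support_label(node.label, dialect)
        for name, v in (("SH-aLRT", sh), ("UFboot", uf)):
            if v is not None and not (0.0 <= v <= 100.0):
                raise SupportParseError(
                    f"{name} value {v} out of [0, 100] at node {node.label!r}"
                )
        node.sh_alrt, node.ufboot = sh, uf

    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_ids)) != len(leaf_ids):
        raise ValueError("duplicate leaf ids in tree")
    annotations = {}
    if taxonomy is not None:
        missing = [l for l in leaf_ids if l not in taxonomy]
        if missing:
            raise ValueError(f"leaves missing from taxonomy: {missing[:5]}")
        annotations = {l: tuple(taxonomy[l]) for l in leaf_ids}
    return AnnotatedTree(tree=tree, leaf_annotations=annotations)


def find_shared_clades(
    atree: AnnotatedTree,
    min_ufboot: float = 90.0,
    min_sh_alrt: Optional[float] = 80.0,
    min_lineages: int = 2,
    include_nested: bool = False,
) -> list[CladeGroup]:
    """Find maximal well-supported clades spanning multiple lineages.

    A clade qualifies when its ultrafast bootstrap is strictly greater than
    ``min_ufboot``, its SH-aLRT is strictly greater than ``min_sh_alrt``
    (when that threshold is set), and its leaves span at least
    ``min_lineages`` lineages.  Nodes lacking a required support value fail
    the thresholds rather than erroring.  Only maximal qualifying clades are
    returned (no returned clade is a descendant of another) unless
    ``include_nested`` is set.

    Groups are labelled ``group_1..group_k`` ordered by clade size
    descending (ties broken by sorted leaf list).
    """
    if not atree.leaf_annotations:
        raise ValueError("tree has no taxonomy annotation; supply a taxonomy table")

    def qualifies(node) -> bool:
        if node.is_leaf():
            return False
        uf = getattr(node, "ufboot", None)
        if uf is None or not (uf > min_ufboot):
            return False
        if min_sh_alrt is not None:
            sh = getattr(node, "sh_alrt", None)
            if sh is None or not (sh > min_sh_alrt):
                return False
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        lineages = {atree.lineage_of(l) for l in leaves}
        return len(lineages) >= min_lineages

    selected = []
    for node in atree.tree.preorder_node_iter():
        if not qualifies(node):
            continue
        if not include_nested:
            anc_qualifies = any(qualifies(a) for a in node.ancestor_iter())
            if anc_qualifies:
                continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        lineages = frozenset(atree.lineage_of(l) for l in leaves)
        selected.append((leaves, lineages, node.ufboot, node.sh_alrt))

    selected.sort(key=lambda t: (-len(t[0]), sorted(t[0])))
    return [
        CladeGroup(member_leaves=lv, lineages=ln, ufboot=uf, sh_alrt=sh,
                   group_label=f"group_{i}")
        for i, (lv, ln, uf, sh) in enumerate(selected, start=1)
    ]


def select_representatives(
    atree: AnnotatedTree,
    groups: Sequence[CladeGroup],
    per_group: int,
    seed: int,
) -> list[str]:
    """Pick representative leaves per group for a reduced tree.

    Each group contributes ``min(per_group, group size)`` leaves.  Within a
    group selection is stratified by lineage: one leaf per lineage is taken
    first (random within lineage), then remaining slots are filled at random.
    Deterministic under a fixed seed.
    """
    if per_group < 1:
        raise ValueError(f"per_group must be >= 1, got {per_group}")
    rng = random.Random(seed)
    chosen: list[str] = []
    for g in sorted(groups, key=lambda g: g.group_label):
        members = sorted(g.member_leaves)
        k = min(per_group, len(members))
        by_lineage: dict[str, list[str]] = {}
        for leaf in members:
            by_lineage.setdefault(atree.lineage_of(leaf), []).append(leaf)
        picked = []
        for lineage in sorted(by_lineage):
            if len(picked) >= k:
                break
            picked.append(rng.choice(by_lineage[lineage]))
        remaining = [m for m in members if m not in picked]
        rng.shuffle(remaining)
        picked.extend(remaining[: k - len(picked)])
        chosen.extend(sorted(picked))
    return chosen


def lineage_presence_from_clades(
    groups: Sequence[CladeGroup],
    leaf_species: Mapping[str, str],
    species_ids: Optional[Sequence[str]] = None,
) -> PresenceMatrix:
    """Group x species presence matrix: true iff >=1 member leaf of the species.

    Feeds the co-occurrence stage (presence of each shared clade per species,
    alongside gene-family presence rows).
    """
    if species_ids is None:
        species_ids = sorted({leaf_species[l] for g in groups for l in g.member_leaves})
    species_ids = list(species_ids)
    rows = {}
    for g in groups:
        present = {leaf_species[l] for l in g.member_leaves}
        missing = present - set(species_ids)
        if missing:
            raise ValueError(f"species not in taxonomy: {sorted(missing)}")
        rows[g.group_label] = [sp in present for sp in species_ids]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=species_ids).astype(bool)
    return PresenceMatrix(df=df, provenance="family_counts")


def write_groups_table(
    groups: Sequence[CladeGroup], path: str | Path
) -> None:
    """Groups TSV: group_label, ufboot, sh_alrt, n_leaves, lineages, leaf list."""
    rows = [
        {
            "group_label": g.group_label,
            "ufboot": g.ufboot,
            "sh_alrt": "" if g.sh_alrt is None else g.sh_alrt,
            "n_leaves": g.size,
            "lineages": ",".join(sorted(g.lineages)),
            "leaves": ",".join(sorted(g.member_leaves)),
        }
        for g in groups
    ]
    pd.DataFrame(
        rows,
        columns=["group_label", "ufboot", "sh_alrt", "n_leaves", "lineages", "leaves"],
    ).to_csv(path, sep="\t", index=False)
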