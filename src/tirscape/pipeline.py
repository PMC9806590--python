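"""End-to-end orchestration from a single configuration file.

A run is described by a flat YAML document: a top-level seed, an output
directory, optional threshold overrides, and one block per enabled stage.
Stages execute in dependency order (classify -> family presence;
filter-msa independent; shared-clades -> clade presence; cooccur;
expr-assoc), every input file is hashed into the report, and all randomness
derives from the single top-level seed so a run is reproducible from its
emitted report alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clade_analysis, cooccurrence, domain_assembly, expression_assoc, msa_filter
from .config import ThresholdConfig

log = logging.getLogger("tirscape")

STAGE_ORDER = ("classify", "filter_msa", "shared_clades", "cooccur", "expr_assoc")

_STAGE_KEYS = {
    "classify": {"hits", "proteome", "taxonomy", "class_map"},
    "filter_msa": {"alignment", "reference"},
    "shared_clades": {"tree", "dialect", "taxonomy"},
    "cooccur": {"orthogroups", "pattern", "keep_list"},
    "expr_assoc": {"tpm", "meta", "genes"},
}
_STAGE_REQUIRED = {
    "classify": {"hits", "proteome", "taxonomy", "class_map"},
    "filter_msa": {"alignment"},
    "shared_clades": {"tree", "taxonomy"},
    "cooccur": {"orthogroups", "pattern"},
    "expr_assoc": {"tpm", "meta"},
}
_TOP_KEYS = {"seed", "out_dir", "thresholds", "stages"}


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning" | "info"
    message: str


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def validate_config(config) -> list[Finding]:
    """Check a run configuration; returns findings, never raises.

    Detects unknown keys, out-of-range thresholds, and dangling input paths.
    A threshold overridden from its default yields an info finding naming
    the default.
    """
    findings: list[Finding] = []
    try:
        cfg = _load_config(config)
    except Exception as exc:  # unreadable file
        return [Finding("error", f"cannot read config: {exc}")]

    for key in set(cfg) - _TOP_KEYS:
        findings.append(Finding("error", f"unknown top-level key {key!r}"))

    thr_cfg = cfg.get("thresholds") or {}
    try:
        thresholds = ThresholdConfig.from_dict(thr_cfg)
    except (TypeError, ValueError) as exc:
        findings.append(Finding("error", f"thresholds: {exc}"))
        thresholds = ThresholdConfig()
    else:
        for problem in thresholds.validate():
            findings.append(Finding("error", f"thresholds: {problem}"))
        defaults = ThresholdConfig()
        for key in thr_cfg:
            if getattr(thresholds, key) != getattr(defaults, key):
                findings.append(
                    Finding(
                        "info",
                        f"threshold {key} overridden to {getattr(thresholds, key)} "
                        f"(default {getattr(defaults, key)})",
                    )
                )

    stages = cfg.get("stages") or {}
    for name, block in stages.items():
        if name not in _STAGE_KEYS:
            findings.append(Finding("error", f"unknown stage {name!r}"))
            continue
        block = block or {}
        for key in set(block) - _STAGE_KEYS[name]:
            findings.append(Finding("error", f"stage {name}: unknown key {key!r}"))
        for key in _STAGE_REQUIRED[name] - set(block):
            findings.append(Finding("error", f"stage {name}: missing input {key!r}"))
        for key, value in block.items():
            if key in ("dialect",):
                if value not in ("single", "dual"):
                    findings.append(
                        Finding("error", f"stage {name}: dialect must be single|dual")
                    )
                continue
            if value and not Path(value).exists():
                findings.append(
                    Finding("error", f"stage {name}: input file not found: {value}")
                )
    return findings


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, strict_validate: bool = True) -> dict:
    """Execute the enabled stages and return (and write) the run report.

    The report records the resolved thresholds, per-stage input hashes, row
    counts and output paths.  Raises ``ValueError`` before any stage runs if
    validation finds errors and ``strict_validate`` is set.
    """
    cfg = _load_config(config)
    findings = validate_config(cfg)
    errors = [f for f in findings if f.level == "error"]
    if errors and strict_validate:
        raise ValueError(
            "invalid configuration:\n" + "\n".join(f"  - {f.message}" for f in errors)
        )

    thresholds = ThresholdConfig.from_dict(cfg.get("thresholds") or {})
    out_dir = Path(cfg.get("out_dir", "tirscape_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages") or {}

    report: dict = {
        "seed": seed,
        "thresholds": thresholds.to_dict(),
        "findings": [{"level": f.level, "message": f.message} for f in findings],
        "stages": {},
    }

    for name in STAGE_ORDER:
        if name not in stages:
            continue
        block = stages[name] or {}
        log.info("running stage %s", name)
        inputs = {
            k: {"path": str(v), "sha256": _sha256(v)}
            for k, v in block.items()
            if k not in ("dialect",) and v
        }
        entry: dict = {"inputs": inputs, "outputs": {}, "counts": {}}

        if name == "classify":
            class_map = domain_assembly.read_class_map(block["class_map"])
            taxonomy = pd.read_csv(block["taxonomy"], sep="\t", dtype=str)
            species_of = dict(zip(taxonomy["leaf_id"], taxonomy["species_id"]))
            proteins = domain_assembly.read_proteome_fasta(block["proteome"], species_of)
            hits = domain_assembly.parse_hit_table(
                block["hits"], class_map, max_evalue=thresholds.max_evalue
            )
            archs = domain_assembly.classify_proteome(
                proteins, hits,
                max_overlap=thresholds.max_overlap_aa,
                min_len=thresholds.min_len_map(),
                max_len_tir_only=thresholds.max_len_tir_only,
            )
            arch_path = out_dir / "architectures.tsv"
            domain_assembly.write_architecture_table(archs, species_of, arch_path)
            counts = domain_assembly.tabulate_architectures(
                archs, species_of, sorted(set(species_of.values()))
            )
            counts_path = out_dir / "architecture_counts.tsv"
            counts.to_csv(counts_path, sep="\t")
            entry["outputs"] = {"architectures": str(arch_path),
                                "counts": str(counts_path)}
            entry["counts"] = {"proteins": len(proteins), "hits": len(hits),
                               "architectures": len(archs)}

        elif name == "filter_msa":
            aln = msa_filter.Alignment.from_fasta(block["alignment"])
            filtered, kept = msa_filter.filter_gap_columns(
                aln, max_gap_frac=thresholds.max_gap_frac
            )
            aln_path = out_dir / "filtered.fasta"
            filtered.to_fasta(aln_path)
            map_path = out_dir / "kept_columns.tsv"
            msa_filter.write_column_map(kept, map_path)
            freq_path = out_dir / "column_frequencies.tsv"
            msa_filter.write_frequency_table(
                msa_filter.column_frequencies(filtered), freq_path
            )
            entry["outputs"] = {"alignment": str(aln_path), "column_map": str(map_path),
                                "frequencies": str(freq_path)}
            entry["counts"] = {"sequences": aln.n_sequences,
                               "columns_in": aln.n_columns,
                               "columns_kept": len(kept)}

        elif name == "shared_clades":
            taxonomy = clade_analysis.read_taxonomy(block["taxonomy"])
            atree = clade_analysis.parse_newick_with_support(
                block["tree"], dialect=block.get("dialect", "dual"), taxonomy=taxonomy
            )
            groups = clade_analysis.find_shared_clades(
                atree,
                min_ufboot=thresholds.min_ufboot,
                min_sh_alrt=thresholds.min_sh_alrt,
                min_lineages=thresholds.min_lineages,
            )
            groups_path = out_dir / "shared_clades.tsv"
            clade_analysis.write_groups_table(groups, groups_path)
            leaf_species = {l: atree.species_of(l) for l in atree.leaf_ids}
            presence = clade_analysis.lineage_presence_from_clades(
                groups, leaf_species,
                sorted({sp for sp, _ in atree.leaf_annotations.values()}),
            )
            presence_path = out_dir / "clade_presence.tsv"
            presence.to_tsv(presence_path)
            entry["outputs"] = {"groups": str(groups_path),
                                "presence": str(presence_path)}
            entry["counts"] = {"leaves": len(atree.leaf_ids), "groups": len(groups)}

        elif name == "cooccur":
            matrix = cooccurrence.binarize_orthogroups(block["orthogroups"])
            query = cooccurrence.read_pattern(block["pattern"])
            matches = cooccurrence.match_pattern(matrix, query)
            keep = (
                cooccurrence.read_keep_list(block["keep_list"])
                if block.get("keep_list")
                else None
            )
            matches_path = out_dir / "pattern_matches.tsv"
            cooccurrence.write_matches(matches, matches_path, keep_list=keep)
            entry["outputs"] = {"matches": str(matches_path)}
            entry["counts"] = {"orthogroups": len(matrix.row_ids),
                               "matches": len(matches)}

        elif name == "expr_assoc":
            study = expression_assoc.load_study(block["tpm"], block["meta"])
            gene_subset = None
            if block.get("genes"):
                with open(block["genes"]) as fh:
                    gene_subset = [l.strip() for l in fh if l.strip()]
            results = expression_assoc.run_association(
                study, gene_subset,
                tpm_threshold=thresholds.tpm_threshold,
                alphas=thresholds.star_alphas,
            )
            res_path = out_dir / "association.tsv"
            expression_assoc.write_results(results, res_path)
            z_path = out_dir / "zscores.tsv"
            expression_assoc.zscore_per_sample(study.tpm).to_csv(z_path, sep="\t")
            entry["outputs"] = {"results": str(res_path), "zscores": str(z_path)}
            entry["counts"] = {"genes_tested": len(results),
                               "samples": study.tpm.shape[1]}

        report["stages"][name] = entry

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["report_path"] = str(report_path)
    return report
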