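"""End-to-end orchestration: read -> filter -> polarize -> tree -> branch
assignment -> dating -> clade partition -> novelty, with TSV reports.

Every stage writes its table under the configured output directory and the
run log records versions, the seed, and per-stage site/sample counts, so a
rerun with the same config and seed reproduces the reports byte for byte.
"""

from __future__ import annotations

import csv
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clade_snps import (CladePartition, clade_variant_partition, name_novel,
                         novelty_check)
from .dating import DEFAULT_RATE, MutationRate, date_all_nodes, format_kya
from .errors import InputError
from .filtering import FilterConfig, run_filter_cascade
from .model import SnpCatalog, validate_meta
from .phylogeny import (assign_snps_to_branches, branch_snp_table,
                        build_tree, polarize)
from .tree import PhyloTree
from .variant_io import (read_haploid_vcf, read_newick, read_region_mask,
                         read_sample_meta, read_snp_catalog,
                         write_variable_sites_fasta)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    mask_bed: str
    metadata: str
    outgroup_id: str
    out_dir: str
    catalog: str | None = None
    newick: str | None = None
    #: named clades (sample-id lists) or the string "tree" to partition
    #: every internal clade of the built/loaded tree
    clades: dict[str, list[str]] | str = "tree"
    filter: FilterConfig = field(default_factory=FilterConfig)
    rate: MutationRate = field(default_factory=lambda: DEFAULT_RATE)
    high_coverage_only: bool = True
    novel_prefix: str = "GMP"
    novel_start: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        if "rate" in raw and isinstance(raw["rate"], dict):
            raw["rate"] = MutationRate(**raw["rate"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise InputError(f"bad config {path}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the report bundle (name -> path).

    Any stage failure aborts with the stage name prefixed to the cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}
    counts: dict[str, int] = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    name = stage("read")
    try:
        mask = read_region_mask(config.mask_bed)
        matrix = read_haploid_vcf(config.vcf, mask=mask)
        meta_rows = read_sample_meta(config.metadata)
        meta = validate_meta(matrix, meta_rows)
        if config.outgroup_id not in matrix.sample_ids:
            raise InputError(
                f"outgroup {config.outgroup_id!r} not in VCF samples")
        catalog = (read_snp_catalog(config.catalog)
                   if config.catalog else SnpCatalog())
        counts["samples"] = matrix.n_samples
        counts["sites_read"] = matrix.n_sites
        counts["callable_bp"] = mask.effective_length_bp

        name = stage("filter")
        filtered, freport = run_filter_cascade(matrix, mask, config.filter)
        bundle["filter_report"] = out / "filter_report.tsv"
        freport.to_tsv(bundle["filter_report"])
        counts["sites_filtered"] = filtered.n_sites
        bundle["fasta"] = out / "variable_sites.fasta"
        if filtered.n_sites:
            write_variable_sites_fasta(filtered, bundle["fasta"])

        name = stage("polarize")
        bmatrix = polarize(filtered, config.outgroup_id)
        counts["sites_polarized"] = bmatrix.n_sites

        name = stage("tree")
        if config.newick:
            tree = read_newick(config.newick)
            extra = set(tree.tip_names) - set(bmatrix.sample_ids)
            if extra:
                raise InputError(f"newick tips not in VCF: {sorted(extra)}")
        else:
            tree = build_tree(bmatrix)

        name = stage("assign")
        assign_snps_to_branches(tree, bmatrix)
        bundle["branch_snps"] = out / "branch_snps.tsv"
        _write_branch_table(tree, bundle["branch_snps"])
        counts["recurrent_sites"] = len(tree.recurrent)

        name = stage("date")
        table = date_all_nodes(tree, meta, mask, config.rate,
                               config.high_coverage_only)
        bundle["dating"] = out / "dating.tsv"
        table.to_csv(bundle["dating"], sep="\t", index=False,
                     float_format="%.6f")
        counts["nodes_dated"] = int((table["status"] == "dated").sum())

        name = stage("clades")
        clades = _resolve_clades(config, tree)
        bundle["clade_partition"] = out / "clade_partition.tsv"
        partitions = _partition_and_report(
            bmatrix, clades, catalog, tree, config,
            bundle["clade_partition"])
        counts["clades"] = len(clades)

        name = stage("summary")
        bundle["summary"] = out / "summary.txt"
        with open(bundle["summary"], "w") as fh:
            fh.write(summarize(bundle, partitions))
    except Exception as exc:
        exc.add_note(f"pipeline aborted in stage {name!r}")
        raise

    bundle["run_log"] = out / "run_log.json"
    with open(bundle["run_log"], "w") as fh:
        json.dump({"ychrono_version": __version__,
                   "python": platform.python_version(),
                   "seed": config.seed,
                   "counts": counts}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle


def _resolve_clades(config: PipelineConfig,
                    tree: PhyloTree) -> dict[str, list[str]]:
    if config.clades == "tree":
        out = {}
        for node in tree.internal_nodes():
            if node.parent is None:
                continue  # the full ingroup is not an informative clade
            out[node.name] = sorted(tree.tipset(node))
        return out
    if isinstance(config.clades, dict):
        return {k: list(v) for k, v in config.clades.items()}
    raise InputError(f"unsupported clades spec {config.clades!r}")


def _partition_and_report(bmatrix, clades, catalog, tree, config, path
                          ) -> dict[str, CladePartition]:
    partitions: dict[str, CladePartition] = {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["clade", "position", "class", "catalog_name",
                    "assigned_name"])
        start = config.novel_start
        for cname in sorted(clades):
            part = clade_variant_partition(bmatrix, clades[cname])
            partitions[cname] = part
            novel = novelty_check(part, catalog)
            name_novel(novel, prefix=config.novel_prefix, start_index=start)
            start += len(novel.positions)
            classes = [("defining", part.defining),
                       ("internal", part.internal - part.private),
                       ("private", part.private),
                       ("excluded", part.excluded),
                       ("unresolved", part.unresolved)]
            for cls, posset in classes:
                for pos in sorted(posset):
                    w.writerow([cname, pos, cls,
                                novel.known.get(pos, ""),
                                novel.names.get(pos, "")])
    return partitions


def _write_branch_table(tree: PhyloTree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["branch_id", "parent", "n_snps", "positions",
                    "recurrent"])
        for row in branch_snp_table(tree):
            w.writerow([row["branch_id"], row["parent"], row["n_snps"],
                        row["positions"],
                        "yes" if row["recurrent"] else "no"])


def summarize(bundle: dict[str, Path],
              partitions: dict[str, CladePartition] | None = None) -> str:
    """Human-readable per-clade one-liners assembled from the report TSVs
    (the formatter recomputes nothing)."""
    import pandas as pd

    lines = [f"ychrono {__version__} run summary", ""]
    dating = pd.read_csv(bundle["dating"], sep="\t")
    part = (pd.read_csv(bundle["clade_partition"], sep="\t")
            if bundle.get("clade_partition") else None)
    for _, row in dating.iterrows():
        node = row["node_id"]
        if row["status"] != "dated":
            lines.append(f"{node}: undated (<2 eligible tips)")
            continue
        t = format_kya(row["t_kya"])
        lo = format_kya(row["t_low_kya"])
        hi = format_kya(row["t_high_kya"])
        extra = ""
        if part is not None and (part["clade"] == node).any():
            sub = part[part["clade"] == node]
            n_def = int((sub["class"] == "defining").sum())
            n_new = int(sub["assigned_name"].notna().sum())
            extra = f", {n_def} defining SNPs, {n_new} novel"
        lines.append(f"{node}: n={int(row['n_tips'])}, rho={row['rho']:.3f},"
                     f" T={t} kya ({lo}-{hi}){extra}")
    return "\n".join(lines) + "\n"
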