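"""End-to-end orchestration: trees in, convergence report out.

Stages: parse and annotate gene trees -> root on the designated outgroup ->
collapse weak supports -> identify ortholog clusters -> call gains/losses
per lineage -> convergence statistics (and, when selection records are
supplied, the relaxed-selection post-processing).  Every stage is a pure
function of its inputs and the run configuration; the report echoes n,
marginals and null probabilities so every statistic can be recomputed from
the output files alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import apply_curation, assign_subfamily, find_ortholog_clusters
from .convstats import convergence_test, subfamily_enrichment
from .gainloss import CallTable, build_call_table
from .selection import (
    flag_convergent_relaxation,
    load_selection_records,
    loss_category_report,
)
from .treeio import (
    GeneTree,
    SpeciesConfig,
    collapse_low_support,
    parse_gene_tree,
    read_anchor_table,
    read_mapping_tsv,
    root_by_outgroup,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    tree_paths: list[str]
    mapping_path: str | None
    roles_path: str
    anchors_path: str | None = None
    selection_path: str | None = None
    curation_path: str | None = None
    outgroup_genes: list[str] = field(default_factory=list)
    support_threshold: float = 0.7
    alpha: float = 0.05
    conf_level: float = 0.95
    power_method: str = "exact"
    seed: int = 0
    outdir: str = "convloss_out"

    def __post_init__(self):
        for name in ("support_threshold", "alpha", "conf_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


class StageError(RuntimeError):
    """Wraps a failure with the stage and file context it occurred in."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def load_trees(config: RunConfig) -> tuple[list[GeneTree], SpeciesConfig]:
    mapping = read_mapping_tsv(config.mapping_path) if config.mapping_path else None
    roles_path = Path(config.roles_path)
    if roles_path.suffix in (".yaml", ".yml"):
        species_config = SpeciesConfig.from_yaml(roles_path)
    else:
        species_config = SpeciesConfig.from_tsv(roles_path)
    trees: list[GeneTree] = []
    for path in config.tree_paths:
        text = Path(path).read_text()
        for line in text.splitlines():
            line = line.strip()
            if line:
                trees.append(parse_gene_tree(line, mapping=mapping))
    return trees, species_config


def prepare_tree(
    gt: GeneTree,
    species_config: SpeciesConfig,
    outgroup_genes: list[str],
    support_threshold: float,
) -> GeneTree:
    """Root (when an outgroup is given or inferable) and support-collapse."""
    og = set(outgroup_genes) & set(gt.gene_species)
    if not og:
        og = {
            g for g, sp in gt.gene_species.items()
            if species_config.roles.get(sp) == "reference"
        }
    if og and og != set(gt.gene_species):
        try:
            gt = root_by_outgroup(gt, og)
        except Exception as exc:
            log.warning("keeping original rooting: %s", exc)
    return collapse_low_support(gt, support_threshold)


def cluster_stage(trees, species_config, config) -> list:
    clusters = []
    for i, gt in enumerate(trees):
        prepared = prepare_tree(
            gt, species_config, config.outgroup_genes, config.support_threshold
        )
        clusters.extend(
            find_ortholog_clusters(prepared, species_config, id_prefix=f"T{i:04d}_OC")
        )
    if config.curation_path:
        df = pd.read_csv(config.curation_path, sep="\t", dtype=str)
        clusters = apply_curation(clusters, dict(zip(df["gene_id"], df["cluster_id"])))
    if config.anchors_path:
        table = read_anchor_table(config.anchors_path)
        for c in clusters:
            assign_subfamily(c, table)
    return clusters


def clusters_frame(clusters, species_config: SpeciesConfig) -> pd.DataFrame:
    species = sorted(species_config.roles)
    rows = []
    for c in clusters:
        row = {"cluster_id": c.cluster_id, "subfamily": c.subfamily or ""}
        for sp in species:
            row[f"{sp}_raw"] = c.raw_count(sp)
            row[f"{sp}_count"] = c.count(sp)
            row[f"{sp}_gain"] = c.gain(sp)
        row["anchors"] = ",".join(sorted(c.anchors))
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write all reports under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    trees, species_config = _stage("load", load_trees, config)
    clusters = _stage("cluster", cluster_stage, trees, species_config, config)
    if not clusters:
        raise StageError("stage 'cluster' failed: no ortholog clusters found")
    table: CallTable = _stage("calls", build_call_table, clusters, species_config)

    results = {}
    for side in ("parasite", "host"):
        for event in ("loss", "gain"):
            res = _stage(
                "convergence",
                convergence_test,
                table,
                side=side,
                event=event,
                alpha=config.alpha,
                conf_level=config.conf_level,
                power_method=config.power_method,
                seed=config.seed,
            )
            results[f"{side}_{event}"] = res.to_dict()

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_trees": len(trees),
        "summary": table.summary(),
        "convergence": results,
        "settings": {
            "support_threshold": config.support_threshold,
            "alpha": config.alpha,
            "conf_level": config.conf_level,
            "power_method": config.power_method,
            "two_sided_convention": "point-probability (minlike), rel. tol. 1e-7",
            "support_dialect_rescaled": any(t.support_rescaled for t in trees),
            "unsupported_nodes": "retained (never collapsed)",
        },
    }

    clusters_frame(clusters, species_config).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    table.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    table.flags.to_csv(outdir / "flags.tsv", sep="\t")

    if config.anchors_path and any(c.subfamily for c in clusters):
        enrich = _stage(
            "enrich",
            subfamily_enrichment,
            table,
            {c.cluster_id: c.subfamily for c in clusters},
            conf_level=config.conf_level,
        )
        pd.DataFrame(
            [
                {
                    "subfamily": r.subfamily,
                    "x": r.x,
                    "n": r.n,
                    "obs_prob": r.p_obs,
                    "ci_low": r.ci[0],
                    "ci_high": r.ci[1],
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                }
                for r in enrich
            ]
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["enrichment_rows"] = len(enrich)
    else:
        log.warning("no anchor table / no subfamilies: enrichment stage skipped")

    if config.selection_path:
        records = _stage("selection", load_selection_records, config.selection_path)
        report["selection"] = flag_convergent_relaxation(records, config.alpha)
        cat_report = _stage("selection", loss_category_report, table, records)
        cat_report.to_csv(outdir / "selection_report.tsv", sep="\t", index=False)

    with open(outdir / "convergence.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
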