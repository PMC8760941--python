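"""Synthetic gene-family generator.

Gene families evolve by a linear birth-death process (duplication at rate
``lambda_dup``, loss at rate ``mu_loss`` per copy per unit branch length)
along a fixed species tree with three parasite-host pairs, two nonhost
relatives, and a reference outgroup.  Parasite terminal branches carry an
elevated loss rate (``parasite_multiplier``), and a designated fraction of
families -- the convergent targets -- carry a much higher multiplier still,
creating genuinely convergent losses.  The reference terminal branch has
loss rate zero so every family keeps at least one anchor gene, mirroring
curated data in which every ortholog cluster has a reference outgroup.

Outputs are exactly the files the analysis pipeline consumes (newick gene
trees with support values, gene-to-species mapping, species roles, anchor
table) plus a per-family truth table of copy counts and target flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .clustering import OrthologCluster
from .treeio import SpeciesConfig

# Three independent parasite-host pairs, two nonhosts, one reference
# outgroup; ultrametric, unit depth, every pair splitting 0.2 before the
# present so the three parasite terminal branches are comparable.
DEFAULT_SPECIES_TREE = (
    "(((HSUB:0.2,LACE:0.2):0.6,"
    "(((TRAV:0.2,TUNI:0.2):0.2,TNYL:0.4):0.2,"
    "((TAME:0.2,TLON:0.2):0.2,TRUG:0.4):0.2):0.2):0.2,"
    "REF:1.0);"
)

DEFAULT_ROLES = {
    "HSUB": "parasite",
    "LACE": "host",
    "TRAV": "parasite",
    "TUNI": "host",
    "TAME": "parasite",
    "TLON": "host",
    "TNYL": "nonhost",
    "TRUG": "nonhost",
    "REF": "reference",
}

DEFAULT_LINEAGES = {
    "pair1": ("HSUB", "LACE"),
    "pair2": ("TRAV", "TUNI"),
    "pair3": ("TAME", "TLON"),
}

SUBFAMILY_LABELS = ["9E", "A", "B", "C", "D", "E", "F", "G", "H", "L", "P", "V"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Default rates are calibrated so that, on the default tree, each parasite
    loses orthologs in roughly a quarter of families and each host in a few
    percent, the regime in which the convergence test operates on real
    chemoreceptor repertoires.
    """

    n_families: int = 300
    lambda_dup: float = 0.40
    mu_loss: float = 0.30
    parasite_multiplier: float = 5.0
    convergent_fraction: float = 0.1
    convergent_multiplier: float = 40.0
    support_noise: tuple[float, float] | None = None  # Beta(a, b); None = all 1.0
    topology_noise: float = 0.0  # reserved hook; only 0.0 is implemented
    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    lineages: dict = field(default_factory=lambda: dict(DEFAULT_LINEAGES))

    def __post_init__(self):
        if min(self.lambda_dup, self.mu_loss) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.convergent_fraction <= 1.0:
            raise ValueError("convergent_fraction must lie in [0, 1]")
        if self.parasite_multiplier < 1.0 or self.convergent_multiplier < 1.0:
            raise ValueError("loss multipliers must be >= 1")
        if self.topology_noise != 0.0:
            raise NotImplementedError("topology noise hook is not implemented")

    def species_config(self) -> SpeciesConfig:
        return SpeciesConfig(roles=dict(self.roles), lineages=dict(self.lineages))

    @property
    def n_targets(self) -> int:
        return int(round(self.convergent_fraction * self.n_families))

    def is_target(self, family_index: int) -> bool:
        return family_index < self.n_targets


# --- species tree --------------------------------------------------------

class _SpNode:
    __slots__ = ("name", "length", "children")

    def __init__(self, name, length, children):
        self.name = name
        self.length = length
        self.children = children


@lru_cache(maxsize=8)
def _parse_species_tree(newick: str) -> _SpNode:
    t = dendropy.Tree.get(
        data=newick, schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )

    def conv(nd):
        name = nd.taxon.label if nd.is_leaf() else None
        return _SpNode(name, nd.edge.length or 0.0, [conv(c) for c in nd.child_nodes()])

    return conv(t.seed_node)


def _load_species_tree(config: SimConfig) -> _SpNode:
    return _parse_species_tree(config.species_tree)


# --- genealogy -----------------------------------------------------------

class GNode:
    """Node of a simulated gene genealogy (duplication or speciation)."""

    __slots__ = ("children", "species", "gene_id", "blen")

    def __init__(self, children=None, species=None, blen=0.0):
        self.children = children or []
        self.species = species
        self.gene_id = None
        self.blen = blen

    def leaves(self):
        if not self.children:
            yield self
        else:
            for ch in self.children:
                yield from ch.leaves()


def _branch_rates(config: SimConfig, sp: _SpNode, target: bool) -> tuple[float, float]:
    lam, mu = config.lambda_dup, config.mu_loss
    if sp.name is not None and config.roles.get(sp.name) == "reference":
        return lam, 0.0  # anchors always survive
    if sp.name is not None and config.roles.get(sp.name) == "parasite":
        mult = config.convergent_multiplier if target else config.parasite_multiplier
        return lam, mu * mult
    return lam, mu


def _evolve_copy(sp: _SpNode, t_remain: float, config, target, rng) -> GNode | None:
    lam, mu = _branch_rates(config, sp, target)
    total = lam + mu
    elapsed = 0.0
    while True:
        t_next = rng.exponential(1.0 / total) if total > 0 else math.inf
        if elapsed + t_next >= t_remain:
            node = _reach_node(sp, config, target, rng)
            if node is not None:
                node.blen += t_remain - elapsed
            return node
        elapsed += t_next
        if rng.random() < mu / total:
            return None  # copy lost
        # duplication: two copies continue in parallel
        left = _evolve_copy(sp, t_remain - elapsed, config, target, rng)
        right = _evolve_copy(sp, t_remain - elapsed, config, target, rng)
        if left is None and right is None:
            return None
        if left is None or right is None:
            survivor = left or right
            survivor.blen += elapsed
            return survivor
        return GNode(children=[left, right], blen=elapsed)


def _reach_node(sp: _SpNode, config, target, rng) -> GNode | None:
    if not sp.children:
        return GNode(species=sp.name, blen=0.0)
    kids = [_evolve_copy(c, c.length, config, target, rng) for c in sp.children]
    survivors = [k for k in kids if k is not None]
    if not survivors:
        return None
    if len(survivors) == 1:
        return survivors[0]
    return GNode(children=survivors, blen=0.0)


@dataclass
class FamilyTruth:
    family_id: str
    counts: dict[str, int]  # raw tip copy counts
    collapsed_counts: dict[str, int]  # post in-paralog collapse
    convergent_target: bool


def _collapsed_counts(root: GNode) -> dict[str, int]:
    """Per-species count of maximal single-species clades in the genealogy
    (the truth analogue of in-paralog collapsing on a clean gene tree)."""
    counts: dict[str, int] = {}

    def walk(node) -> str | None:
        # returns the species if the subtree is single-species, else None
        if not node.children:
            return node.species
        kid_species = [walk(ch) for ch in node.children]
        if all(s is not None and s == kid_species[0] for s in kid_species):
            return kid_species[0]
        for s in kid_species:
            if s is not None:
                counts[s] = counts.get(s, 0) + 1
        return None

    top = walk(root)
    if top is not None:
        counts[top] = counts.get(top, 0) + 1
    return counts


def simulate_family(config: SimConfig, family_index: int) -> tuple[GNode | None, FamilyTruth]:
    """Simulate one family; deterministic in (config.seed, family_index)."""
    rng = np.random.default_rng([config.seed % (2**31), family_index])
    sp_root = _load_species_tree(config)
    target = config.is_target(family_index)
    root = _reach_node(sp_root, config, target, rng)
    fam = f"fam{family_index:04d}"
    counts: dict[str, int] = {}
    if root is not None:
        per_sp: dict[str, int] = {}
        for lf in root.leaves():
            k = per_sp.get(lf.species, 0)
            lf.gene_id = f"{lf.species}|{fam}_copy{k:02d}"
            per_sp[lf.species] = k + 1
        counts = per_sp
    truth = FamilyTruth(
        family_id=fam,
        counts=counts,
        collapsed_counts=_collapsed_counts(root) if root is not None else {},
        convergent_target=target,
    )
    return root, truth


def emit_gene_tree(
    genealogy: GNode,
    support_noise: tuple[float, float] | None = None,
    seed=None,
) -> str:
    """Serialize a genealogy to newick with supports on internal nodes."""
    rng = np.random.default_rng(seed)

    def sup() -> str:
        if support_noise is None:
            return "1.0"
        a, b = support_noise
        return format(float(rng.beta(a, b)), ".3f")

    def rec(node: GNode, top: bool = False) -> str:
        if not node.children:
            return f"{node.gene_id}:{node.blen:.6f}"
        inner = ",".join(rec(ch) for ch in node.children)
        label = "" if top else sup()
        return f"({inner}){label}:{node.blen:.6f}"

    if not genealogy.children:
        return f"({genealogy.gene_id}:{genealogy.blen:.6f});"
    return rec(genealogy, top=True) + ";"


@dataclass
class SimDataset:
    config: SimConfig
    newicks: list[str]
    mapping: dict[str, str]
    anchor_table: dict[str, str]
    truth: pd.DataFrame
    species_config: SpeciesConfig


def family_subfamily(family_index: int) -> str:
    return SUBFAMILY_LABELS[family_index % len(SUBFAMILY_LABELS)]


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate all families and assemble a self-consistent input set."""
    newicks: list[str] = []
    mapping: dict[str, str] = {}
    anchor_table: dict[str, str] = {}
    rows = []
    for i in range(config.n_families):
        root, truth = simulate_family(config, i)
        if root is not None:
            newicks.append(
                emit_gene_tree(
                    root,
                    support_noise=config.support_noise,
                    seed=[config.seed % (2**31), i, 7],
                )
            )
            for lf in root.leaves():
                mapping[lf.gene_id] = lf.species
                if config.roles.get(lf.species) == "reference":
                    anchor_table[lf.gene_id] = family_subfamily(i)
        for sp in sorted(config.roles):
            rows.append(
                {
                    "family_id": truth.family_id,
                    "species_id": sp,
                    "count": truth.counts.get(sp, 0),
                    "collapsed_count": truth.collapsed_counts.get(sp, 0),
                    "convergent_flag": truth.convergent_target,
                }
            )
    return SimDataset(
        config=config,
        newicks=newicks,
        mapping=mapping,
        anchor_table=anchor_table,
        truth=pd.DataFrame(rows),
        species_config=config.species_config(),
    )


def generate_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Write the simulated dataset in the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    paths = {
        "trees": outdir / "gene_trees.nwk",
        "mapping": outdir / "mapping.tsv",
        "roles": outdir / "roles.yaml",
        "anchors": outdir / "anchors.tsv",
        "truth": outdir / "truth.tsv",
    }
    paths["trees"].write_text("".join(nwk + "\n" for nwk in ds.newicks))
    pd.DataFrame(
        sorted(ds.mapping.items()), columns=["gene_id", "species_id"]
    ).to_csv(paths["mapping"], sep="\t", index=False)
    ds.species_config.to_yaml(paths["roles"])
    pd.DataFrame(
        sorted(ds.anchor_table.items()), columns=["gene_id", "subfamily"]
    ).to_csv(paths["anchors"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def truth_clusters(config: SimConfig) -> tuple[list[OrthologCluster], SpeciesConfig]:
    """Fast path for replicate studies: build ortholog clusters directly
    from simulated truth counts, skipping newick serialization and parsing.

    Families with no surviving focal copy are omitted, matching what the
    tree-based pipeline would recover.
    """
    cfg = config.species_config()
    focal = cfg.focal_species
    clusters = []
    for i in range(config.n_families):
        _, truth = simulate_family(config, i)
        if not any(truth.counts.get(sp, 0) for sp in focal):
            continue
        counts = {sp: c for sp, c in truth.collapsed_counts.items() if sp in focal}
        raw = {sp: c for sp, c in truth.counts.items() if sp in focal}
        gains = {sp: raw.get(sp, 0) > counts.get(sp, 0) for sp in raw}
        clusters.append(
            OrthologCluster(
                cluster_id=truth.family_id,
                members=[],
                raw_counts=raw,
                counts=counts,
                gains=gains,
                anchors=set(),
                subfamily=family_subfamily(i),
            )
        )
    return clusters, cfg
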