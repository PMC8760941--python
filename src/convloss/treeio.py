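"""Gene-tree input/output and tree surgery.

Gene trees arrive as newick with internal-node support values (FastTree /
IQ-TREE style).  This module parses them, annotates every leaf with its
species, reroots on a designated outgroup while keeping support values
attached to the correct bipartitions, and contracts poorly supported edges
into multifurcations.  It also reads the small tabular inputs the pipeline
needs: the gene-to-species mapping, the species role/pairing configuration,
and the ancestral-subfamily anchor table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import pandas as pd
import yaml

ROLES = ("parasite", "host", "nonhost", "reference")


class TreeFormatError(ValueError):
    """Raised when a newick string cannot be parsed."""


class LeafMappingError(KeyError):
    """Raised when a leaf name cannot be resolved to a species."""


class RootingError(ValueError):
    """Raised when the requested outgroup is absent or not monophyletic."""


class ConfigError(ValueError):
    """Raised when the species role/pairing configuration is inconsistent."""


@dataclass(frozen=True)
class SpeciesConfig:
    """Species roles and parasite-host pairings.

    ``roles`` maps each species to one of parasite/host/nonhost/reference;
    ``lineages`` maps a lineage identifier to its (parasite, host) pair.
    Each independent origin of parasitism contributes one lineage.
    """

    roles: dict[str, str]
    lineages: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for sp, role in self.roles.items():
            if role not in ROLES:
                raise ConfigError(f"unknown role {role!r} for species {sp!r}")
        if not self.references:
            raise ConfigError("configuration defines no reference species")
        seen: set[str] = set()
        for lid, (par, host) in self.lineages.items():
            if self.roles.get(par) != "parasite":
                raise ConfigError(f"lineage {lid!r}: {par!r} is not a parasite")
            if self.roles.get(host) != "host":
                raise ConfigError(f"lineage {lid!r}: {host!r} is not a host")
            if par in seen or host in seen:
                raise ConfigError(f"lineage {lid!r}: species reused across lineages")
            seen.update((par, host))

    @property
    def parasites(self) -> list[str]:
        return [p for p, _ in self.lineages.values()]

    @property
    def hosts(self) -> list[str]:
        return [h for _, h in self.lineages.values()]

    @property
    def references(self) -> set[str]:
        return {s for s, r in self.roles.items() if r == "reference"}

    @property
    def focal_species(self) -> set[str]:
        """Species that appear inside ortholog clusters (everything non-reference)."""
        return {s for s, r in self.roles.items() if r != "reference"}

    @classmethod
    def from_yaml(cls, path) -> "SpeciesConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        lineages = {
            lid: (d["parasite"], d["host"]) for lid, d in raw.get("lineages", {}).items()
        }
        return cls(roles=dict(raw["roles"]), lineages=lineages)

    @classmethod
    def from_tsv(cls, path) -> "SpeciesConfig":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        roles = dict(zip(df["species_id"], df["role"]))
        lineages: dict[str, dict[str, str]] = {}
        for _, row in df.iterrows():
            lid = row.get("lineage_id", "")
            if lid and row["role"] in ("parasite", "host"):
                lineages.setdefault(lid, {})[row["role"]] = row["species_id"]
        pairs = {}
        for lid, d in lineages.items():
            if set(d) != {"parasite", "host"}:
                raise ConfigError(f"lineage {lid!r} must pair one parasite with one host")
            pairs[lid] = (d["parasite"], d["host"])
        return cls(roles=roles, lineages=pairs)

    def to_yaml(self, path) -> None:
        raw = {
            "roles": dict(self.roles),
            "lineages": {
                lid: {"parasite": p, "host": h} for lid, (p, h) in self.lineages.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class GeneTree:
    """A rooted gene tree with species-annotated leaves.

    Wraps a :class:`dendropy.Tree`.  Each node carries a ``support``
    attribute (float in [0, 1] or ``None``); each leaf's taxon label is the
    gene id and ``gene_species`` resolves it to a species.
    """

    tree: dendropy.Tree
    gene_species: dict[str, str]
    support_rescaled: bool = field(default=False)

    def leaf_gene_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def species_of(self, gene_id: str) -> str:
        return self.gene_species[gene_id]

    def clone(self) -> "GeneTree":
        t = self.tree.clone(depth=1)
        for nd, src in zip(t.preorder_node_iter(), self.tree.preorder_node_iter()):
            nd.support = getattr(src, "support", None)
        return GeneTree(t, dict(self.gene_species), self.support_rescaled)


def read_mapping_tsv(path) -> dict[str, str]:
    """Read a two-column (gene_id, species_id) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "species_id"):
        if col not in df.columns:
            raise TreeFormatError(f"mapping TSV lacks required column {col!r}")
    return dict(zip(df["gene_id"], df["species_id"]))


def read_anchor_table(path) -> dict[str, str]:
    """Read the reference-gene -> ancestral-subfamily table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "subfamily"):
        if col not in df.columns:
            raise TreeFormatError(f"anchor table lacks required column {col!r}")
    return dict(zip(df["gene_id"], df["subfamily"]))


def parse_gene_tree(
    newick_text: str,
    mapping: dict[str, str] | None = None,
    delimiter: str = "|",
) -> GeneTree:
    """Parse a newick gene tree and annotate leaves with species.

    Species resolution: an explicit ``mapping`` wins; otherwise the leaf name
    is split on the first ``delimiter`` and the prefix taken as the species
    ("SPECIES|gene" convention).  Internal node labels are read as supports;
    trees on a 0-100 support scale (any value > 1) are rescaled to [0, 1].
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeFormatError(f"newick parse failure: {exc}") from exc

    supports: list[float] = []
    for nd in tree.preorder_node_iter():
        nd.support = None
        if not nd.is_leaf() and nd.label not in (None, ""):
            try:
                nd.support = float(nd.label)
            except ValueError:
                nd.support = None  # non-numeric label: treat as absent
            else:
                supports.append(nd.support)
    rescaled = any(s > 1.0 for s in supports)
    if rescaled:
        for nd in tree.preorder_node_iter():
            if nd.support is not None:
                nd.support /= 100.0

    gene_species: dict[str, str] = {}
    unmapped: list[str] = []
    for lf in tree.leaf_node_iter():
        gid = lf.taxon.label
        if mapping is not None and gid in mapping:
            gene_species[gid] = mapping[gid]
        elif delimiter in gid:
            gene_species[gid] = gid.split(delimiter, 1)[0]
        else:
            unmapped.append(gid)
    if unmapped:
        raise LeafMappingError(
            f"could not resolve species for leaves: {sorted(unmapped)}"
        )
    gids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(gids) != len(set(gids)):
        dupes = sorted({g for g in gids if gids.count(g) > 1})
        raise TreeFormatError(f"duplicate leaf gene ids: {dupes}")
    tree.suppress_unifurcations()
    return GeneTree(tree, gene_species, support_rescaled=rescaled)


def write_gene_tree(gt: GeneTree) -> str:
    """Serialize back to newick, supports as internal node labels."""
    t = gt.tree.clone(depth=1)
    for nd, src in zip(t.preorder_node_iter(), gt.tree.preorder_node_iter()):
        sup = getattr(src, "support", None)
        if not nd.is_leaf():
            nd.label = format(sup, "g") if sup is not None else None
    out = io.StringIO()
    t.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip() + "\n"


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = frozenset([nd.taxon.label])
        else:
            acc: set[str] = set()
            for ch in nd.child_nodes():
                acc |= sets[ch]
            sets[nd] = frozenset(acc)
    return sets


def _bipartition_key(leafset: frozenset, all_leaves: frozenset, anchor: str) -> frozenset:
    """Canonical key for the unrooted bipartition induced by an edge: the side
    that does not contain the (fixed, arbitrary) anchor leaf."""
    return leafset if anchor not in leafset else all_leaves - leafset


def bipartitions(gt: GeneTree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as its canonical side."""
    sets = _leafsets(gt.tree)
    allset = sets[gt.tree.seed_node]
    anchor = min(allset)
    out: set[frozenset[str]] = set()
    for nd, ls in sets.items():
        if nd is gt.tree.seed_node:
            continue
        key = _bipartition_key(ls, allset, anchor)
        if len(key) >= 2 and len(allset) - len(key) >= 2:
            out.add(key)
    return out


def root_by_outgroup(gt: GeneTree, outgroup_gene_ids: set[str]) -> GeneTree:
    """Reroot on the branch separating the outgroup clade from the rest.

    The outgroup must be monophyletic in the *unrooted* sense; supports are
    reassigned by bipartition so every retained edge keeps its value.
    """
    out = gt.clone()
    tree = out.tree
    if not outgroup_gene_ids:
        raise RootingError("empty outgroup")
    sets = _leafsets(tree)
    allset = sets[tree.seed_node]
    og = frozenset(outgroup_gene_ids)
    missing = og - allset
    if missing:
        raise RootingError(f"outgroup genes not in tree: {sorted(missing)}")
    if og == allset:
        raise RootingError("outgroup cannot contain every leaf")

    anchor = min(allset)
    support_by_split: dict[frozenset, float | None] = {}
    for nd, ls in sets.items():
        if nd is tree.seed_node:
            continue
        support_by_split[_bipartition_key(ls, allset, anchor)] = getattr(
            nd, "support", None
        )

    target = None
    for nd, ls in sets.items():
        if nd is tree.seed_node:
            continue
        if ls == og or ls == allset - og:
            target = nd
            break
    if target is None:
        # minimal conflict report: the extra leaves under the rooted MRCA
        taxa = [tx for tx in tree.taxon_namespace if tx.label in og]
        tree.is_rooted = True
        mrca = tree.mrca(taxa=taxa)
        extra = sorted(sets[mrca] - og)[:10]
        raise RootingError(
            f"outgroup is not monophyletic; conflicting leaves include {extra}"
        )

    already = target.parent_node is tree.seed_node and len(
        tree.seed_node.child_nodes()
    ) == 2
    if not already:
        tree.reroot_at_edge(target.edge, update_bipartitions=False)
        tree.suppress_unifurcations()

    sets = _leafsets(tree)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.support = None
            continue
        if nd is tree.seed_node:
            nd.support = None
            continue
        key = _bipartition_key(sets[nd], allset, anchor)
        nd.support = support_by_split.get(key)
    return out


def collapse_low_support(gt: GeneTree, threshold: float = 0.7) -> GeneTree:
    """Contract every internal edge whose support is strictly below ``threshold``.

    Children of a contracted node reattach to its parent (multifurcation);
    edges with absent support are retained.  Idempotent by construction.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = gt.clone()
    tree = out.tree
    for nd in list(tree.postorder_node_iter()):
        parent = nd.parent_node
        if parent is None or nd.is_leaf():
            continue
        sup = getattr(nd, "support", None)
        if sup is not None and sup < threshold:
            blen = nd.edge.length or 0.0
            for ch in list(nd.child_nodes()):
                nd.remove_child(ch)
                if ch.edge.length is not None:
                    ch.edge.length += blen
                parent.add_child(ch)
            parent.remove_child(nd)
    return out
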