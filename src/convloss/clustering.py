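"""Ortholog cluster identification by the reference-outgroup rule.

An orthologous cluster is a maximal clade of focal-species genes (parasites,
hosts and nonhosts) whose immediate outgroup contains at least one gene from
a reference species.  Formally we take every maximal focal-only clade of the
rooted, support-collapsed gene tree: maximality forces a reference leaf
elsewhere under the parent, and those reference leaves anchor the cluster to
an ancestral subfamily.  Species-specific expansions (in-paralogs, including
paralogs merged at multifurcations created by support collapsing) are
collapsed to a single representative, and any collapse marks a gene *gain*
for that species in that cluster.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import dendropy

from .treeio import ConfigError, GeneTree, SpeciesConfig

log = logging.getLogger(__name__)


@dataclass
class OrthologCluster:
    """One orthologous cluster with per-species copy counts.

    ``raw_counts`` are pre-collapse leaf counts, ``counts`` the post-collapse
    ortholog-lineage counts; ``gains[s]`` is true exactly when collapsing
    merged in-paralogs of species ``s``.  ``anchors`` are the reference genes
    in the sister subtree(s); ``anchor_paths`` gives each anchor's
    topological distance (edge count) to the cluster root.
    """

    cluster_id: str
    members: list[tuple[str, str]]  # (gene_id, species_id), pre-collapse
    raw_counts: dict[str, int]
    counts: dict[str, int]
    gains: dict[str, bool]
    anchors: set[str]
    anchor_paths: dict[str, int] = field(default_factory=dict)
    collapse_group: dict[str, str] = field(default_factory=dict)  # gene -> representative
    subfamily: str | None = None

    def count(self, species: str) -> int:
        return self.counts.get(species, 0)

    def raw_count(self, species: str) -> int:
        return self.raw_counts.get(species, 0)

    def gain(self, species: str) -> bool:
        return self.gains.get(species, False)


# --- species-specific expansion collapsing -------------------------------

def _collapse_node(node, species_of):
    """Collapse species-specific expansions under ``node``.

    Returns a nested structure where every post-collapse ortholog lineage of
    a species is a ("leaf", species, [gene_ids]) entry.  A pure
    single-species subtree reduces to one leaf; at a multifurcation, all
    single-species child subtrees of the same species are merged into one.
    """
    if node.is_leaf():
        gid = node.taxon.label
        return ("leaf", species_of(gid), [gid])
    children = [_collapse_node(ch, species_of) for ch in node.child_nodes()]
    leaf_children = [c for c in children if c[0] == "leaf"]
    if len(leaf_children) == len(children):
        species = {c[1] for c in leaf_children}
        if len(species) == 1:
            genes = sorted(g for c in leaf_children for g in c[2])
            return ("leaf", species.pop(), genes)
    merged: dict[str, list[str]] = {}
    new_children = []
    for c in children:
        if c[0] == "leaf":
            merged.setdefault(c[1], []).extend(c[2])
        else:
            new_children.append(c)
    for sp in sorted(merged):
        new_children.append(("leaf", sp, sorted(merged[sp])))
    return ("internal", new_children)


def _walk_collapsed(struct, out: list[tuple[str, list[str]]]) -> None:
    if struct[0] == "leaf":
        out.append((struct[1], struct[2]))
    else:
        for ch in struct[1]:
            _walk_collapsed(ch, out)


def collapse_expansions(subtree_root, species_of) -> tuple[dict[str, int], dict[str, bool], dict[str, str]]:
    """Collapse in-paralogs in one cluster subtree.

    Returns ``(counts, gains, collapse_group)``: post-collapse per-species
    counts, per-species gain flags, and a gene -> representative map where
    the representative of each merged group is its lexicographically
    smallest gene id.
    """
    struct = _collapse_node(subtree_root, species_of)
    lineages: list[tuple[str, list[str]]] = []
    _walk_collapsed(struct, lineages)
    counts: Counter = Counter()
    gains: dict[str, bool] = {}
    group: dict[str, str] = {}
    for sp, genes in lineages:
        counts[sp] += 1
        rep = min(genes)
        if len(genes) > 1:
            gains[sp] = True
        for g in genes:
            group[g] = rep
    return dict(counts), gains, group


# --- cluster identification ----------------------------------------------

def find_ortholog_clusters(
    gt: GeneTree, config: SpeciesConfig, id_prefix: str = "OC"
) -> list[OrthologCluster]:
    """Identify all ortholog clusters in a rooted, support-collapsed tree.

    Clusters are the maximal clades whose leaves all belong to focal
    (non-reference) species; anchors are the reference leaves found under
    the cluster's parent but outside the cluster.  Every focal leaf ends up
    in exactly one cluster.
    """
    tree = gt.tree
    refs = config.references
    species_of = gt.species_of

    for gid, sp in gt.gene_species.items():
        if sp not in config.roles:
            raise ConfigError(f"species {sp!r} of gene {gid!r} missing from config")

    leaves_below: dict[dendropy.Node, list[str]] = {}
    pure_focal: dict[dendropy.Node, bool] = {}
    n_ref = 0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            gid = nd.taxon.label
            leaves_below[nd] = [gid]
            is_ref = species_of(gid) in refs
            n_ref += is_ref
            pure_focal[nd] = not is_ref
        else:
            kids = nd.child_nodes()
            leaves_below[nd] = [g for ch in kids for g in leaves_below[ch]]
            pure_focal[nd] = all(pure_focal[ch] for ch in kids)
    if n_ref == 0:
        raise ConfigError("gene tree contains no reference-species leaf")
    if pure_focal[tree.seed_node]:
        raise ConfigError("tree root is focal-only despite reference leaves")
    if n_ref == len(leaves_below[tree.seed_node]):
        log.warning("gene tree contains no focal leaves; no clusters found")
        return []

    depth: dict[dendropy.Node, int] = {tree.seed_node: 0}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            depth[ch] = depth[nd] + 1

    clusters: list[OrthologCluster] = []
    idx = 0
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        if not pure_focal[nd]:
            continue
        if parent is not None and pure_focal[parent]:
            continue  # not maximal
        idx += 1
        members = [(g, species_of(g)) for g in sorted(leaves_below[nd])]
        raw = Counter(sp for _, sp in members)
        counts, gains, group = collapse_expansions(nd, species_of)
        anchors: set[str] = set()
        anchor_paths: dict[str, int] = {}
        if parent is not None:
            in_cluster = set(leaves_below[nd])
            for sib in parent.child_nodes():
                if sib is nd:
                    continue
                for lf in sib.leaf_iter():
                    gid = lf.taxon.label
                    if gid in in_cluster:
                        continue
                    if species_of(gid) in refs:
                        anchors.add(gid)
                        # up from cluster root to parent, then down to the leaf
                        anchor_paths[gid] = 1 + (depth[lf] - depth[parent])
        clusters.append(
            OrthologCluster(
                cluster_id=f"{id_prefix}{idx:04d}",
                members=members,
                raw_counts=dict(raw),
                counts=counts,
                gains=gains,
                anchors=anchors,
                anchor_paths=anchor_paths,
                collapse_group=group,
            )
        )
    return clusters


def assign_subfamily(
    cluster: OrthologCluster, anchor_table: dict[str, str]
) -> OrthologCluster:
    """Assign the ancestral subfamily by majority vote among anchors.

    Ties are broken in favour of the anchor closest to the cluster root,
    then lexicographically by label.  Clusters whose anchors are absent from
    the table stay unassigned.
    """
    labelled = {a: anchor_table[a] for a in cluster.anchors if a in anchor_table}
    if not labelled:
        if cluster.anchors:
            log.info("cluster %s: no anchor in subfamily table", cluster.cluster_id)
        cluster.subfamily = None
        return cluster
    votes = Counter(labelled.values())
    top = max(votes.values())
    tied = sorted(lab for lab, v in votes.items() if v == top)
    if len(tied) == 1:
        cluster.subfamily = tied[0]
        return cluster
    best = min(
        (a for a in labelled if labelled[a] in tied),
        key=lambda a: (cluster.anchor_paths.get(a, 10**9), labelled[a], a),
    )
    cluster.subfamily = labelled[best]
    return cluster


def apply_curation(
    clusters: list[OrthologCluster], override: dict[str, str]
) -> list[OrthologCluster]:
    """Apply a manual-curation override reassigning genes between clusters.

    ``override`` maps gene ids to target cluster ids (existing or new).
    Counts and gains are recomputed from the moved memberships; collapse
    groups travel with their genes, so moving one member of a merged
    in-paralog pair leaves one ortholog lineage on each side.  Emptied
    clusters are dropped.
    """
    if not override:
        return clusters
    known = {g for c in clusters for g, _ in c.members}
    unknown = sorted(set(override) - known)
    if unknown:
        raise ValueError(f"curation override names unknown genes: {unknown}")

    species_by_gene = {g: sp for c in clusters for g, sp in c.members}
    group_by_gene = {g: c.collapse_group.get(g, g) for c in clusters for g, _ in c.members}
    home = {g: c.cluster_id for c in clusters for g, _ in c.members}
    membership: dict[str, list[str]] = {}
    for g, cid in home.items():
        membership.setdefault(override.get(g, cid), []).append(g)

    anchors_by_id = {c.cluster_id: (c.anchors, c.anchor_paths, c.subfamily) for c in clusters}
    order = [c.cluster_id for c in clusters] + [
        cid for cid in membership if cid not in {c.cluster_id for c in clusters}
    ]
    out: list[OrthologCluster] = []
    for cid in order:
        genes = sorted(membership.get(cid, []))
        if not genes:
            continue
        members = [(g, species_by_gene[g]) for g in genes]
        raw = Counter(sp for _, sp in members)
        groups: dict[tuple[str, str], list[str]] = {}
        for g in genes:
            groups.setdefault((species_by_gene[g], group_by_gene[g]), []).append(g)
        counts: Counter = Counter()
        gains: dict[str, bool] = {}
        group_map: dict[str, str] = {}
        for (sp, _), gs in groups.items():
            counts[sp] += 1
            rep = min(gs)
            if len(gs) > 1:
                gains[sp] = True
            for g in gs:
                group_map[g] = rep
        anchors, paths, subfam = anchors_by_id.get(cid, (set(), {}, None))
        out.append(
            OrthologCluster(
                cluster_id=cid,
                members=members,
                raw_counts=dict(raw),
                counts=dict(counts),
                gains=gains,
                anchors=set(anchors),
                anchor_paths=dict(paths),
                collapse_group=group_map,
                subfamily=subfam,
            )
        )
    return out
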