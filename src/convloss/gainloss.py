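"""Per-cluster, per-lineage gain and loss calls.

For each ortholog cluster and each parasite-host pair, the call is the sign
of ``delta = parasite count - host count`` on post-collapse counts: a
negative delta is a parasite loss (the host retains orthologs the parasite
lost), a positive delta a host loss.  Gains are species-specific expansion
flags copied from clustering.  A loss or gain is *convergent* when it
occurred in all lineages (all parasites, or all hosts).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clustering import OrthologCluster
from .treeio import ConfigError, SpeciesConfig


@dataclass(frozen=True)
class LossCall:
    cluster_id: str
    lineage_id: str
    parasite: str
    host: str
    delta: int
    parasite_loss: bool
    host_loss: bool
    parasite_gain: bool
    host_gain: bool


def call_pair(
    cluster: OrthologCluster, lineage_id: str, parasite: str, host: str
) -> LossCall:
    """Call loss/gain for one cluster against one parasite-host pair."""
    delta = cluster.count(parasite) - cluster.count(host)
    return LossCall(
        cluster_id=cluster.cluster_id,
        lineage_id=lineage_id,
        parasite=parasite,
        host=host,
        delta=delta,
        parasite_loss=delta < 0,
        host_loss=delta > 0,
        parasite_gain=cluster.gain(parasite),
        host_gain=cluster.gain(host),
    )


class CallTable:
    """Matrix of loss/gain calls over clusters x lineages.

    ``calls`` is a tidy DataFrame with one row per (cluster, lineage);
    ``flags`` holds the four per-cluster convergence indicators.  The total
    cluster count ``n`` includes clusters with no call in some lineage
    (delta = 0), matching the denominators used throughout.
    """

    def __init__(self, clusters: list[OrthologCluster], config: SpeciesConfig):
        if not clusters:
            raise ValueError("call table requires at least one cluster")
        if not config.lineages:
            raise ValueError("call table requires at least one lineage")
        self.clusters = list(clusters)
        self.config = config
        rows = [
            call_pair(c, lid, par, host)
            for c in clusters
            for lid, (par, host) in config.lineages.items()
        ]
        self.calls = pd.DataFrame([r.__dict__ for r in rows])

        by_cluster = self.calls.groupby("cluster_id", sort=False)
        self.flags = pd.DataFrame(
            {
                "parasite_convergent_loss": by_cluster["parasite_loss"].all(),
                "host_convergent_loss": by_cluster["host_loss"].all(),
                "parasite_convergent_gain": by_cluster["parasite_gain"].all(),
                "host_convergent_gain": by_cluster["host_gain"].all(),
            }
        )

    @property
    def n(self) -> int:
        return len(self.clusters)

    def loss_count(self, species: str) -> int:
        """Number of clusters where ``species`` lost orthologs."""
        role = self.config.roles.get(species)
        if role == "parasite":
            sub = self.calls[self.calls["parasite"] == species]
            return int(sub["parasite_loss"].sum())
        if role == "host":
            sub = self.calls[self.calls["host"] == species]
            return int(sub["host_loss"].sum())
        raise ConfigError(f"{species!r} is not a parasite or host in the config")

    def gain_count(self, species: str) -> int:
        if species not in self.config.roles:
            raise ConfigError(f"unknown species {species!r}")
        return sum(c.gain(species) for c in self.clusters)

    def convergent_count(self, side: str = "parasite", event: str = "loss") -> int:
        col = f"{side}_convergent_{event}"
        if col not in self.flags.columns:
            raise ValueError(f"no convergence flag {col!r}")
        return int(self.flags[col].sum())

    def convergent_clusters(self, side: str = "parasite", event: str = "loss") -> list[str]:
        col = f"{side}_convergent_{event}"
        return list(self.flags.index[self.flags[col]])

    def summary(self) -> dict:
        out: dict = {"n_clusters": self.n, "species": {}, "convergent": {}}
        for lid, (par, host) in self.config.lineages.items():
            out["species"][par] = {
                "role": "parasite",
                "lineage": lid,
                "losses": self.loss_count(par),
                "gains": self.gain_count(par),
            }
            out["species"][host] = {
                "role": "host",
                "lineage": lid,
                "losses": self.loss_count(host),
                "gains": self.gain_count(host),
            }
        for side in ("parasite", "host"):
            for event in ("loss", "gain"):
                out["convergent"][f"{side}_{event}"] = self.convergent_count(side, event)
        return out


def build_call_table(clusters: list[OrthologCluster], config: SpeciesConfig) -> CallTable:
    return CallTable(clusters, config)
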