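"""Seed-expansion clustering of the refined interaction network.

Proteins are clustered into M mutually exclusive groups by repeatedly taking
the unassigned protein of highest node weight as a seed and absorbing those
of its immediate neighbours whose connecting edge weight clears the level's
edge threshold. Every protein of the refined network ends up in exactly one
cluster (possibly a singleton); cluster members form the method's test set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .network import ProteinNetwork, WeightTables, _check_level, edge_key


@dataclass
class Cluster:
    """One seed-expanded cluster; ``members`` starts with the seed."""

    seed: str
    members: list[str]
    level: str

    def __post_init__(self) -> None:
        if not self.members or self.members[0] != self.seed:
            raise ValueError("cluster members must be non-empty and start with the seed")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, protein: str) -> bool:
        return protein in self.members


@dataclass
class ClusterSet:
    """Mutually exclusive clusters covering the refined network at one level."""

    clusters: list[Cluster]
    level: str

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def members(self) -> set[str]:
        return {p for c in self.clusters for p in c.members}

    def cluster_of(self, protein: str) -> Cluster:
        for c in self.clusters:
            if protein in c:
                return c
        raise KeyError(f"protein {protein!r} not in any cluster")


def build_clusters(refined: ProteinNetwork, weights: WeightTables, level: str) -> ClusterSet:
    """Form mutually exclusive clusters by descending-node-weight seed expansion.

    Until no unassigned protein remains: the unassigned protein of maximal
    node weight (ties broken by lexicographically smallest identifier)
    seeds a cluster; every unassigned immediate neighbour whose edge weight
    to the seed is at least the level's edge threshold joins it; all
    members leave the candidate pool. Members are ordered by descending
    edge weight to the seed (then lexicographically). Only the seed's own
    level-1 neighbours are absorbed — no transitive growth.
    """
    _check_level(level)
    for p in refined.proteins:
        if p not in weights.node_weight:
            raise KeyError(f"missing node weight for protein {p!r}")
    for e in refined.edges:
        if e not in weights.edge_weight:
            raise KeyError(f"missing edge weight for edge {e}")

    th_edge = weights.threshold("edge", level)
    unassigned = set(refined.proteins)
    clusters: list[Cluster] = []
    while unassigned:
        seed = min(unassigned, key=lambda p: (-weights.node_weight[p], p))
        absorbed = [
            n
            for n in refined.neighbors(seed)
            if n in unassigned and weights.edge_weight[edge_key(seed, n)] >= th_edge
        ]
        absorbed.sort(key=lambda n: (-weights.edge_weight[edge_key(seed, n)], n))
        members = [seed] + absorbed
        unassigned.difference_update(members)
        clusters.append(Cluster(seed=seed, members=members, level=level))
    return ClusterSet(clusters=clusters, level=level)


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    """TSV writer: one row per member (cluster_id, level, seed, member)."""
    with Path(path).open("w") as fh:
        fh.write("cluster_id\tlevel\tseed\tmember\n")
        for i, c in enumerate(clusters.clusters):
            for m in c.members:
                fh.write(f"{i}\t{c.level}\t{c.seed}\t{m}\n")


def read_clusters(path: str | Path) -> ClusterSet:
    """Read a cluster TSV written by :func:`write_clusters`."""
    rows: dict[int, list[tuple[str, str, str]]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.setdefault(int(row["cluster_id"]), []).append(
                (row["level"], row["seed"], row["member"])
            )
    clusters = []
    level = "low"
    for cid in sorted(rows):
        level, seed, _ = rows[cid][0]
        clusters.append(Cluster(seed=seed, members=[m for _, _, m in rows[cid]], level=level))
    return ClusterSet(clusters=clusters, level=level)
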