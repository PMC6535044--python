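"""Protein-protein interaction network construction, weighting and refinement.

The pipeline starts from an undirected simple interaction graph. Each protein
gets a degree-derived *node weight* (essential proteins are the highly
connected ones) and each interaction a common-neighbour-derived *edge weight*
(reliable edges join proteins with overlapping neighbourhoods). Both weight
distributions are cut at three statistically derived thresholds

    Th_k = alpha + k * sigma * (1 - 1 / (1 + sigma**2)),   k in {1, 2, 3}

where ``alpha`` and ``sigma`` are the mean and population standard deviation
of the weight values; k = 1, 2, 3 correspond to the low, medium and high
cutoffs. Refinement is two-staged: nodes below the node-weight threshold are
dropped (giving G'), edge weights are recomputed on G' and edges below the
recomputed edge-weight threshold are dropped (giving G'').
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("ppifunc")

#: threshold level name -> multiplier k of the dispersion term
LEVELS: dict[str, int] = {"low": 1, "medium": 2, "high": 3}

NODE_SCHEMES = ("degree_over_mean", "raw_degree")
EDGE_SCHEMES = ("jaccard_cn", "common_neighbor_count")


class ParseError(ValueError):
    """Raised for malformed interaction-table rows."""


def _check_level(level: str) -> int:
    if level not in LEVELS:
        raise ValueError(f"unknown threshold level {level!r}; expected one of {sorted(LEVELS)}")
    return LEVELS[level]


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered key for an edge."""
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# interaction records and parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionRecord:
    """One row of an interaction table.

    The orientation of (protein_a, protein_b) carries no meaning; optional
    free-text fields default to the empty string.
    """

    protein_a: str
    protein_b: str
    experiment_type: str = ""
    function_a: str = ""
    function_b: str = ""


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for interaction TSVs (MIPS-style exports differ in headers)."""

    protein_a: str = "protein_a"
    protein_b: str = "protein_b"
    experiment: str = "experiment"
    function_a: str = "function_a"
    function_b: str = "function_b"


def read_interaction_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[InteractionRecord]:
    """Read a tab-separated interaction table into records.

    Lines starting with ``#`` are comments. The two protein columns are
    required; experiment/function columns are optional and become empty
    strings when absent. Identifiers are whitespace-trimmed.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [
            (lineno, row)
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1)
            if row and not row[0].lstrip().startswith("#")
        ]
    if not rows:
        return []
    _, header = rows[0]
    header = [h.strip() for h in header]
    col: dict[str, int | None] = {}
    for attr in ("protein_a", "protein_b", "experiment", "function_a", "function_b"):
        name = getattr(dialect, attr)
        col[attr] = header.index(name) if name in header else None
    for attr in ("protein_a", "protein_b"):
        if col[attr] is None:
            raise ParseError(
                f"{path}: required column {getattr(dialect, attr)!r} not in header {header}"
            )
    n_required = max(col["protein_a"], col["protein_b"]) + 1  # type: ignore[type-var]

    def cell(row: list[str], attr: str) -> str:
        idx = col[attr]
        if idx is None or idx >= len(row):
            return ""
        return row[idx].strip()

    records = []
    for lineno, row in rows[1:]:
        if len(row) < n_required:
            raise ParseError(f"{path}:{lineno}: expected >= {n_required} columns, got {len(row)}")
        a, b = cell(row, "protein_a"), cell(row, "protein_b")
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty protein identifier")
        records.append(
            InteractionRecord(
                protein_a=a,
                protein_b=b,
                experiment_type=cell(row, "experiment"),
                function_a=cell(row, "function_a"),
                function_b=cell(row, "function_b"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# the network container
# ---------------------------------------------------------------------------

@dataclass
class ProteinNetwork:
    """Undirected simple graph of protein identifiers (no self loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {edge_key(u, v) for u, v in self.graph.edges}

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, protein: str) -> set[str]:
        return set(self.graph.neighbors(protein))

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def subgraph_of(self, other: "ProteinNetwork") -> bool:
        return self.proteins <= other.proteins and self.edges <= other.edges

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], isolated: Iterable[str] = ()
    ) -> "ProteinNetwork":
        g = nx.Graph()
        g.add_nodes_from(isolated)
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls(g)


def build_network(
    records: Iterable[InteractionRecord], isolated: Iterable[str] = ()
) -> ProteinNetwork:
    """Build the simple undirected PPIN from interaction records.

    Self-interacting pairs are dropped and duplicate pairs (either
    orientation) are collapsed to a single edge.
    """
    g = nx.Graph()
    g.add_nodes_from(isolated)
    n_self = n_dup = 0
    for rec in records:
        if rec.protein_a == rec.protein_b:
            n_self += 1
            continue
        if g.has_edge(rec.protein_a, rec.protein_b):
            n_dup += 1
            continue
        g.add_edge(rec.protein_a, rec.protein_b)
    if n_self or n_dup:
        logger.info("build_network: dropped %d self-pairs, collapsed %d duplicates", n_self, n_dup)
    return ProteinNetwork(g)


# ---------------------------------------------------------------------------
# node and edge weights
# ---------------------------------------------------------------------------

def node_weights(net: ProteinNetwork, scheme: str = "degree_over_mean") -> dict[str, float]:
    """Degree-derived node weight per protein.

    ``degree_over_mean`` (default) scales degrees by the network's mean
    degree, so the weights average to exactly 1; ``raw_degree`` returns the
    plain degree.
    """
    if net.n_proteins == 0:
        raise ValueError("node_weights: empty network")
    if scheme not in NODE_SCHEMES:
        raise ValueError(f"unknown node-weight scheme {scheme!r}")
    degrees = dict(net.graph.degree())
    if scheme == "raw_degree":
        return {p: float(d) for p, d in degrees.items()}
    mean_deg = sum(degrees.values()) / len(degrees)
    if mean_deg == 0:  # edgeless network: every protein equally (non-)essential
        return {p: 0.0 for p in degrees}
    return {p: d / mean_deg for p, d in degrees.items()}


def edge_weights(
    net: ProteinNetwork, scheme: str = "jaccard_cn"
) -> dict[tuple[str, str], float]:
    """Common-neighbour-derived weight for every edge of the network.

    ``jaccard_cn`` (default) is |N(u) & N(v)| / |(N(u) | N(v)) - {u, v}|
    with weight 0 when the denominator is empty; ``common_neighbor_count``
    is the raw shared-neighbour count. N(.) is the open neighbourhood.
    """
    if net.n_proteins == 0:
        raise ValueError("edge_weights: empty network")
    if scheme not in EDGE_SCHEMES:
        raise ValueError(f"unknown edge-weight scheme {scheme!r}")
    out: dict[tuple[str, str], float] = {}
    for u, v in net.graph.edges:
        nu, nv = set(net.graph.neighbors(u)), set(net.graph.neighbors(v))
        common = len(nu & nv)
        if scheme == "common_neighbor_count":
            out[edge_key(u, v)] = float(common)
        else:
            denom = len((nu | nv) - {u, v})
            out[edge_key(u, v)] = common / denom if denom else 0.0
    return out


def weight_threshold(values: Iterable[float], k: int) -> float:
    """Statistical cutoff Th_k = alpha + k*sigma*(1 - 1/(1 + sigma^2)).

    ``alpha`` is the mean and ``sigma`` the population standard deviation of
    ``values``; k = 1/2/3 give the low/medium/high cutoffs. With sigma = 0
    every level collapses to the mean.
    """
    values = list(values)
    if not values:
        raise ValueError("weight_threshold: empty value list")
    if k not in (1, 2, 3):
        raise ValueError(f"threshold index k must be 1, 2 or 3, got {k}")
    alpha = statistics.fmean(values)
    sigma = statistics.pstdev(values)
    return alpha + k * sigma * (1.0 - 1.0 / (1.0 + sigma**2))


@dataclass
class WeightTables:
    """Node/edge weights of a network with their Eq-style three-level cutoffs."""

    node_weight: dict[str, float]
    edge_weight: dict[tuple[str, str], float]
    mean_nw: float
    std_nw: float
    mean_ew: float
    std_ew: float
    thresholds: dict[tuple[str, str], float]  # (kind, level) -> Th
    node_scheme: str = "degree_over_mean"
    edge_scheme: str = "jaccard_cn"

    def threshold(self, kind: str, level: str) -> float:
        _check_level(level)
        if kind not in ("node", "edge"):
            raise ValueError(f"unknown weight kind {kind!r}")
        return self.thresholds[(kind, level)]

    def edge_weight_of(self, u: str, v: str) -> float:
        key = edge_key(u, v)
        if key not in self.edge_weight:
            raise KeyError(f"no edge weight for pair {key}")
        return self.edge_weight[key]


def compute_weights(
    net: ProteinNetwork,
    node_scheme: str = "degree_over_mean",
    edge_scheme: str = "jaccard_cn",
) -> WeightTables:
    """Compute both weight tables and all six thresholds for a network."""
    nw = node_weights(net, node_scheme)
    ew = edge_weights(net, edge_scheme) if net.n_edges else {}
    thresholds: dict[tuple[str, str], float] = {}
    for level, k in LEVELS.items():
        thresholds[("node", level)] = weight_threshold(nw.values(), k)
        if ew:
            thresholds[("edge", level)] = weight_threshold(ew.values(), k)
        else:
            thresholds[("edge", level)] = 0.0
    return WeightTables(
        node_weight=nw,
        edge_weight=ew,
        mean_nw=statistics.fmean(nw.values()),
        std_nw=statistics.pstdev(nw.values()),
        mean_ew=statistics.fmean(ew.values()) if ew else 0.0,
        std_ew=statistics.pstdev(ew.values()) if ew else 0.0,
        thresholds=thresholds,
        node_scheme=node_scheme,
        edge_scheme=edge_scheme,
    )


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    """G' (node-pruned), G'' (node- and edge-pruned) and the per-level tables.

    Edge weights and their thresholds are recomputed on G' — each level has
    its own sub-network edge table — while node weights carry over from the
    full network.
    """

    level: str
    node_pruned: ProteinNetwork  # G'
    refined: ProteinNetwork  # G''
    weights: WeightTables  # node weights of G, edge weights recomputed on G'
    node_threshold: float
    edge_threshold: float


def refine(net: ProteinNetwork, weights: WeightTables, level: str) -> RefinementResult:
    """Two-stage prune of the PPIN at one threshold level.

    Stage 1 removes every protein whose node weight is below the level's
    node threshold (with its incident edges), producing G'. Stage 2
    recomputes edge weights on G', derives the edge threshold from G''s own
    edge-weight distribution, and removes every edge below it, producing
    G''. Proteins isolated by edge pruning are retained. Ties (weight equal
    to the threshold) survive, so a constant weight distribution prunes
    nothing.
    """
    _check_level(level)
    th_node = weights.threshold("node", level)
    keep = [p for p in net.proteins if weights.node_weight[p] >= th_node]
    g_prime = ProteinNetwork(nx.Graph(net.graph.subgraph(keep)))

    if g_prime.n_edges:
        ew_prime = edge_weights(g_prime, weights.edge_scheme)
        edge_thresholds = {
            lvl: weight_threshold(ew_prime.values(), k) for lvl, k in LEVELS.items()
        }
    else:
        ew_prime = {}
        edge_thresholds = {lvl: 0.0 for lvl in LEVELS}
    th_edge = edge_thresholds[level]

    g2 = nx.Graph()
    g2.add_nodes_from(g_prime.proteins)
    for (u, v), w in ew_prime.items():
        if w >= th_edge:
            g2.add_edge(u, v)
    refined = ProteinNetwork(g2)

    kept_weights = WeightTables(
        node_weight={p: weights.node_weight[p] for p in g_prime.proteins},
        edge_weight=ew_prime,
        mean_nw=weights.mean_nw,
        std_nw=weights.std_nw,
        mean_ew=statistics.fmean(ew_prime.values()) if ew_prime else 0.0,
        std_ew=statistics.pstdev(ew_prime.values()) if ew_prime else 0.0,
        thresholds={
            **{("node", lvl): weights.thresholds[("node", lvl)] for lvl in LEVELS},
            **{("edge", lvl): edge_thresholds[lvl] for lvl in LEVELS},
        },
        node_scheme=weights.node_scheme,
        edge_scheme=weights.edge_scheme,
    )
    return RefinementResult(
        level=level,
        node_pruned=g_prime,
        refined=refined,
        weights=kept_weights,
        node_threshold=th_node,
        edge_threshold=th_edge,
    )


def refine_network(net: ProteinNetwork, weights: WeightTables, level: str) -> ProteinNetwork:
    """The refined graph G'' at one level (see :func:`refine` for details)."""
    return refine(net, weights, level).refined


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_network(net: ProteinNetwork, edges_path: str | Path, isolated_path: str | Path) -> None:
    """Write a two-column TSV edge list plus a one-column isolated-protein list."""
    with Path(edges_path).open("w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
    connected = {p for e in net.edges for p in e}
    with Path(isolated_path).open("w") as fh:
        fh.write("protein\n")
        for p in sorted(net.proteins - connected):
            fh.write(f"{p}\n")


def weight_summary(weights: WeightTables) -> dict:
    """JSON-serialisable manifest fragment describing a weight table."""
    return {
        "node_scheme": weights.node_scheme,
        "edge_scheme": weights.edge_scheme,
        "mean_nw": weights.mean_nw,
        "std_nw": weights.std_nw,
        "mean_ew": weights.mean_ew,
        "std_ew": weights.std_ew,
        "thresholds": {f"{kind}_{level}": th for (kind, level), th in weights.thresholds.items()},
    }
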