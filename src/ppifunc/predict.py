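"""Function transfer by nearest level-1 neighbourhood cluster in PCP space.

For a test protein, each of its immediate (level-1) neighbours in the
node-pruned network seeds a candidate cluster containing that neighbour plus
the neighbour's own immediate neighbours whose edge weight clears the
level's threshold (the test protein itself is excluded). The test protein
inherits the full label union of the candidate cluster whose mean PCP score
is closest to its own. Pair-level predictions are the intersection of the
two members' predicted label sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .clustering import Cluster, build_clusters
from .network import ProteinNetwork, WeightTables, _check_level, compute_weights, edge_key, refine
from .physchem import (
    CLASSIFIER_IDS,
    REFERENCE_TOP5_RANKINGS,
    FeatureMatrix,
    rank_features,
    select_features,
)

logger = logging.getLogger("ppifunc")

PREDICTED = "predicted"
UNPREDICTABLE = "unpredictable"


@dataclass
class FunctionPrediction:
    """Outcome of function transfer for one test protein."""

    protein: str
    assigned_cluster: Cluster | None
    functions: frozenset[str]
    status: str
    distance: float | None = None

    @property
    def winning_seed(self) -> str | None:
        return self.assigned_cluster.seed if self.assigned_cluster else None


@dataclass
class PairPrediction:
    """Intersection-based prediction for an interacting protein pair."""

    protein_a: str
    protein_b: str
    functions: frozenset[str]
    status: str


def level1_clusters(
    test: str, graph: ProteinNetwork, weights: WeightTables, level: str
) -> list[Cluster]:
    """One candidate cluster per immediate neighbour of the test protein.

    Each neighbour N seeds a cluster holding N plus N's own immediate
    neighbours (the test protein excluded) whose edge weight to N is at
    least the level's edge threshold. Cluster count equals deg(test).
    """
    _check_level(level)
    if test not in graph.proteins:
        raise KeyError(f"test protein {test!r} not in graph")
    th_edge = weights.threshold("edge", level)
    clusters = []
    for seed in sorted(graph.neighbors(test)):
        members = [
            m
            for m in graph.neighbors(seed)
            if m != test and weights.edge_weight_of(seed, m) >= th_edge
        ]
        members.sort(key=lambda m: (-weights.edge_weight_of(seed, m), m))
        clusters.append(Cluster(seed=seed, members=[seed] + members, level=level))
    return clusters


def predict_functions(
    test: str,
    graph: ProteinNetwork,
    weights: WeightTables,
    level: str,
    matrix: FeatureMatrix,
    annotations: Mapping[str, set[str]],
) -> FunctionPrediction:
    """Assign the label union of the nearest level-1 cluster in PCP space.

    Candidate clusters are scored by |PCP(test) - mean cluster PCP| (means
    over members present in the feature matrix). Ties prefer the cluster
    whose seed has the larger edge weight to the test protein, then the
    lexicographically smaller seed. The test protein's own annotation never
    contributes to the transferred union. With no level-1 cluster the
    protein is unpredictable.
    """
    candidates = level1_clusters(test, graph, weights, level)
    test_score = matrix.pcp_score(test)

    best: tuple[float, float, str] | None = None
    best_cluster: Cluster | None = None
    for cluster in candidates:
        scores = [matrix.pcp_score(m) for m in cluster.members if m in matrix.raw.index]
        if not scores:
            continue
        dist = abs(test_score - sum(scores) / len(scores))
        seed_ew = weights.edge_weight_of(test, cluster.seed)
        key = (dist, -seed_ew, cluster.seed)
        if best is None or key < best:
            best, best_cluster = key, cluster
    if best_cluster is None:
        return FunctionPrediction(test, None, frozenset(), UNPREDICTABLE)

    functions: set[str] = set()
    for m in best_cluster.members:
        if m != test:
            functions |= set(annotations.get(m, ()))
    if not functions:
        logger.warning("winning cluster for %s has no annotated member", test)
    return FunctionPrediction(
        protein=test,
        assigned_cluster=best_cluster,
        functions=frozenset(functions),
        status=PREDICTED,
        distance=best[0],
    )


def predict_pair(
    pair: tuple[str, str], predictions: Mapping[str, FunctionPrediction]
) -> PairPrediction:
    """Pair functions = intersection of the two members' predicted sets.

    An empty intersection is a legal predicted outcome; the pair is
    unpredictable only when either member is.
    """
    a, b = pair
    pa, pb = predictions.get(a), predictions.get(b)
    if pa is None or pb is None or pa.status == UNPREDICTABLE or pb.status == UNPREDICTABLE:
        return PairPrediction(a, b, frozenset(), UNPREDICTABLE)
    return PairPrediction(a, b, frozenset(pa.functions & pb.functions), PREDICTED)


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings of a full refine -> cluster -> select -> predict run."""

    level: str = "high"
    node_scheme: str = "degree_over_mean"
    edge_scheme: str = "jaccard_cn"
    feature_selection: str = "classifiers"  # or "reference"
    min_hits: int = 2
    seed: int = 0
    reduced_cysteines: bool = False


@dataclass
class PipelineResult:
    predictions: list[FunctionPrediction]
    manifest: dict
    matrix: FeatureMatrix = field(repr=False, default=None)  # type: ignore[assignment]


def run_funpred(
    net: ProteinNetwork,
    sequences: Mapping[str, str],
    annotations: Mapping[str, set[str]],
    level: str = "high",
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full pipeline: refine the PPIN, cluster, select features, predict.

    All members of the seed-expansion clusters built on the refined network
    become the test set; each test protein's own annotation is masked while
    its functions are predicted. Returns the per-protein predictions plus a
    machine-readable manifest (thresholds, counts, seed).
    """
    config = config or PipelineConfig(level=level)
    _check_level(level)
    weights = compute_weights(net, config.node_scheme, config.edge_scheme)
    ref = refine(net, weights, level)
    clusters = build_clusters(ref.refined, ref.weights, level)
    test_set = sorted(clusters.members)

    missing = [p for p in test_set if p not in sequences]
    if missing:
        raise ValueError(f"clustered proteins without sequences: {missing[:10]}")

    matrix = FeatureMatrix.from_sequences(sequences, config.reduced_cysteines)
    report = _select(matrix, annotations, config)
    matrix = matrix.with_selection(report.selected)

    predictions = []
    for protein in test_set:
        masked = {p: fs for p, fs in annotations.items() if p != protein}
        predictions.append(
            predict_functions(protein, ref.node_pruned, ref.weights, level, matrix, masked)
        )
    if not test_set:
        logger.warning("empty test set: every protein fell below the node threshold")

    manifest = {
        "level": level,
        "seed": config.seed,
        "node_scheme": config.node_scheme,
        "edge_scheme": config.edge_scheme,
        "feature_selection": config.feature_selection,
        "selected_features": list(report.selected),
        "feature_hits": report.hits,
        "thresholds": {
            f"{kind}_{lvl}": th for (kind, lvl), th in ref.weights.thresholds.items()
        },
        "n_proteins_input": net.n_proteins,
        "n_edges_input": net.n_edges,
        "n_proteins_refined": ref.refined.n_proteins,
        "n_edges_refined": ref.refined.n_edges,
        "n_clusters": len(clusters),
        "n_test_proteins": len(test_set),
        "n_predicted": sum(p.status == PREDICTED for p in predictions),
        "n_unpredictable": sum(p.status == UNPREDICTABLE for p in predictions),
    }
    return PipelineResult(predictions=predictions, manifest=manifest, matrix=matrix)


def _select(matrix, annotations, config: PipelineConfig):
    """Run (or look up) the four-classifier vote behind the selected-feature set."""
    if config.feature_selection == "reference":
        return select_features(REFERENCE_TOP5_RANKINGS, config.min_hits)
    if config.feature_selection != "classifiers":
        raise ValueError(f"unknown feature_selection {config.feature_selection!r}")
    # train on the primary (lexicographically first) label of each annotated protein
    labels = {
        p: sorted(fs)[0] for p, fs in annotations.items() if fs and p in matrix.raw.index
    }
    if len(set(labels.values())) < 2:
        logger.warning(
            "fewer than 2 annotation classes; falling back to the reference feature set"
        )
        return select_features(REFERENCE_TOP5_RANKINGS, config.min_hits)
    rankings = {
        cid: rank_features(matrix, labels, cid, top_n=5, seed=config.seed)
        for cid in CLASSIFIER_IDS
    }
    report = select_features(rankings, config.min_hits)
    if not report.selected:
        logger.warning("classifier vote selected no features; using the reference set")
        return select_features(REFERENCE_TOP5_RANKINGS, config.min_hits)
    return report


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_predictions(predictions: Sequence[FunctionPrediction], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tstatus\twinning_seed\tdistance\tfunctions\n")
        for p in predictions:
            dist = "" if p.distance is None else f"{p.distance:.6g}"
            fh.write(
                f"{p.protein}\t{p.status}\t{p.winning_seed or ''}\t{dist}\t"
                f"{';'.join(sorted(p.functions))}\n"
            )


def read_predictions(path: str | Path) -> list[FunctionPrediction]:
    """Read a prediction TSV written by :func:`write_predictions`.

    Cluster membership beyond the winning seed is not round-tripped; the
    seed is restored as a singleton cluster."""
    import csv

    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            seed = row["winning_seed"]
            cluster = Cluster(seed=seed, members=[seed], level="high") if seed else None
            out.append(
                FunctionPrediction(
                    protein=row["protein"],
                    assigned_cluster=cluster,
                    functions=frozenset(x for x in row["functions"].split(";") if x),
                    status=row["status"],
                    distance=float(row["distance"]) if row["distance"] else None,
                )
            )
    return out


def write_pair_predictions(pairs: Sequence[PairPrediction], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\tfunctions\n")
        for p in pairs:
            label = "unable_to_predict" if p.status == UNPREDICTABLE else ";".join(sorted(p.functions))
            fh.write(f"{p.protein_a}\t{p.protein_b}\t{label}\n")
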