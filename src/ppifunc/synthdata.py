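"""Seeded generator of synthetic interactomes with planted structure.

The generator emulates a functionally annotated yeast-style interactome at
bench scale: a planted-partition graph (dense within clusters, sparse
between), one primary function label per cluster (occasionally resampled,
to model annotation noise) plus secondary labels shared between adjacent
clusters, cluster-biased amino-acid composition (so composition-level
descriptors separate clusters in PCP space) and per-cluster subcellular
locations. Everything is reproducible from a single integer seed.

It deliberately does not mimic real interactome degree distributions,
sequence motifs or hierarchical functional catalogues; sequences are i.i.d.
draws from a tilted residue distribution.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .localization import LOCATIONS, UNKNOWN, LocalizationTable, write_localization_table
from .network import ProteinNetwork, write_network
from .physchem import write_fasta

logger = logging.getLogger("ppifunc")

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: residue groups whose balance the cluster tilt shifts (they drive charge,
#: aromaticity, hydropathy and the aliphatic index)
_GROUPS = {"acidic": "DE", "basic": "KR", "aromatic": "FWY", "aliphatic": "AVIL"}


@dataclass
class SynthConfig:
    """Study conditions of a synthetic run.

    Defaults: 5 planted clusters of 40 proteins, within-cluster edge
    probability 0.3 versus 0.01 between, 5% label noise, sequences of
    200-400 residues with a 0.15 composition tilt.
    """

    n_clusters: int = 5
    cluster_size: int = 40
    p_in: float = 0.3
    p_out: float = 0.01
    label_pool: list[str] | None = None
    label_noise: float = 0.05
    secondary_rate: float = 0.3
    seq_length_range: tuple[int, int] = (200, 400)
    composition_shift: float = 0.15
    loc_pool: dict[str, float] = field(
        default_factory=lambda: {"nucleus": 0.4, "cytoplasm": 0.4, "interface": 0.2}
    )
    loc_noise: float = 0.1
    loc_unknown_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValueError("n_clusters and cluster_size must be positive")
        if self.seq_length_range[0] < 1 or self.seq_length_range[0] > self.seq_length_range[1]:
            raise ValueError("invalid seq_length_range")
        if self.composition_shift < 0:
            raise ValueError("composition_shift must be >= 0")
        if self.p_in * self.cluster_size < 1:
            warnings.warn(
                "expected within-cluster degree below 1; clusters will be mostly isolated",
                stacklevel=2,
            )


@dataclass
class SynthDataset:
    """A generated interactome with its ground truth."""

    network: ProteinNetwork
    annotations: dict[str, set[str]]
    localizations: LocalizationTable
    sequences: dict[str, str]
    true_clusters: dict[str, int]
    primary_labels: dict[int, str]  # cluster index -> planted primary label
    primary_locations: dict[int, str]
    config: SynthConfig


def _cluster_frequencies(cluster: int, shift: float) -> np.ndarray:
    """Residue frequencies for one cluster: uniform background tilted by a
    cluster-specific ±1 sign pattern over the four descriptor-relevant
    residue groups (16 distinct patterns, cycling beyond that)."""
    logf = np.zeros(len(AA_ORDER))
    for g, (_, residues) in enumerate(_GROUPS.items()):
        sign = 1.0 if (cluster >> g) & 1 else -1.0
        for r in residues:
            logf[AA_ORDER.index(r)] = sign * shift
    freq = np.exp(logf)
    return freq / freq.sum()


def simulate(config: SynthConfig | None = None) -> SynthDataset:
    """Generate one synthetic dataset under the configured study conditions."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_clusters * config.cluster_size
    proteins = [f"P{i:04d}" for i in range(n)]
    membership = np.repeat(np.arange(config.n_clusters), config.cluster_size)

    # planted-partition edges
    same = membership[:, None] == membership[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    draws = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = draws[iu, ju] < prob[iu, ju]
    edges = [(proteins[i], proteins[j]) for i, j in zip(iu[mask], ju[mask])]
    network = ProteinNetwork.from_edges(edges, isolated=proteins)

    # function labels: one primary per cluster plus adjacency-shared secondaries
    pool = config.label_pool or [f"F{c + 1:02d}" for c in range(config.n_clusters)]
    primary = {c: pool[c % len(pool)] for c in range(config.n_clusters)}
    secondary = {c: f"S{c + 1:02d}" for c in range(config.n_clusters)}
    annotations: dict[str, set[str]] = {}
    for i, p in enumerate(proteins):
        c = int(membership[i])
        label = primary[c]
        if rng.random() < config.label_noise:
            label = pool[rng.integers(len(pool))]
        labels = {label}
        if config.n_clusters > 1:
            if rng.random() < config.secondary_rate:
                labels.add(secondary[c])
            if rng.random() < config.secondary_rate:
                labels.add(secondary[(c - 1) % config.n_clusters])
        annotations[p] = labels

    # sequences with cluster-tilted residue composition
    freqs = {
        c: _cluster_frequencies(c, config.composition_shift) for c in range(config.n_clusters)
    }
    lo, hi = config.seq_length_range
    sequences = {}
    for i, p in enumerate(proteins):
        length = int(rng.integers(lo, hi + 1))
        sequences[p] = "".join(rng.choice(list(AA_ORDER), size=length, p=freqs[int(membership[i])]))

    # subcellular locations: one dominant location per cluster
    loc_names = list(config.loc_pool)
    loc_w = np.array([config.loc_pool[k] for k in loc_names], dtype=float)
    loc_w = loc_w / loc_w.sum()
    primary_loc = {
        c: loc_names[rng.choice(len(loc_names), p=loc_w)] for c in range(config.n_clusters)
    }
    localizations: LocalizationTable = {}
    for i, p in enumerate(proteins):
        loc = primary_loc[int(membership[i])]
        if rng.random() < config.loc_noise:
            loc = LOCATIONS[rng.integers(len(LOCATIONS))]
        if rng.random() < config.loc_unknown_rate:
            loc = UNKNOWN
        localizations[p] = loc

    return SynthDataset(
        network=network,
        annotations=annotations,
        localizations=localizations,
        sequences=sequences,
        true_clusters={p: int(membership[i]) for i, p in enumerate(proteins)},
        primary_labels=primary,
        primary_locations=primary_loc,
        config=config,
    )


# ---------------------------------------------------------------------------
# file emission in the dialects the other modules consume
# ---------------------------------------------------------------------------

def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    """Multi-label annotation TSV: ``protein<TAB>functions`` (;-separated)."""
    with Path(path).open("w") as fh:
        fh.write("protein\tfunctions\n")
        for p in sorted(annotations):
            fh.write(f"{p}\t{';'.join(sorted(annotations[p]))}\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    annotations: dict[str, set[str]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            labels = {x for x in row["functions"].split(";") if x}
            annotations[row["protein"].strip()] = labels
    return annotations


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit interactions, sequences, annotations, locations and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "isolated": outdir / "isolated.tsv",
        "sequences": outdir / "sequences.fasta",
        "annotations": outdir / "annotations.tsv",
        "localizations": outdir / "localizations.tsv",
        "truth": outdir / "true_clusters.tsv",
    }
    write_network(dataset.network, paths["interactions"], paths["isolated"])
    write_fasta(dataset.sequences, paths["sequences"])
    write_annotations(dataset.annotations, paths["annotations"])
    write_localization_table(dataset.localizations, paths["localizations"])
    with paths["truth"].open("w") as fh:
        fh.write("protein\tcluster\tprimary_label\tprimary_location\n")
        for p in sorted(dataset.true_clusters):
            c = dataset.true_clusters[p]
            fh.write(f"{p}\t{c}\t{dataset.primary_labels[c]}\t{dataset.primary_locations[c]}\n")
    return paths
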