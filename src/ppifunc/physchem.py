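"""Sequence-derived physicochemical descriptors, feature selection, PCP scores.

Ten candidate descriptors are computed per protein from its amino-acid
sequence (ProtParam-style, via Biopython): aromaticity, GRAVY, instability
index, isoelectric point, counts of negatively (D+E) and positively (K+R)
charged residues, molar extinction coefficient, aliphatic index, absorbance
(extinction / molecular weight) and pI / molecular weight. Four
importance-based classifiers each nominate their top five descriptors; the
descriptors nominated at least twice (six, on the reference data) form the
selected set, and a protein's PCP score is the mean of its z-scored selected
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

#: canonical descriptor order; ties in rankings resolve to this order
FEATURE_NAMES: tuple[str, ...] = (
    "aromaticity",
    "gravy",
    "instability_index",
    "isoelectric_point",
    "n_negative",
    "n_positive",
    "extinction_coefficient",
    "aliphatic_index",
    "absorbance",
    "ip_over_mw",
)

CLASSIFIER_IDS = ("xgboost", "random_forest", "extra_trees", "rfe")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Reference four-classifier top-5 nominations for the ten descriptors, as
#: reported for the yeast-interactome analysis this package re-implements
#: (training data unpublished; shipped as a fixture, not re-derived here).
REFERENCE_TOP5_RANKINGS: dict[str, list[str]] = {
    "xgboost": [
        "isoelectric_point",
        "n_negative",
        "n_positive",
        "extinction_coefficient",
        "aliphatic_index",
    ],
    "random_forest": [
        "aromaticity",
        "gravy",
        "instability_index",
        "isoelectric_point",
        "aliphatic_index",
    ],
    "extra_trees": [
        "aromaticity",
        "gravy",
        "isoelectric_point",
        "n_positive",
        "aliphatic_index",
    ],
    "rfe": [
        "gravy",
        "isoelectric_point",
        "n_negative",
        "n_positive",
        "absorbance",
    ],
}


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty amino-acid sequence")
    seq = sequence.upper()
    bad = [(i, c) for i, c in enumerate(seq) if c not in _STANDARD_AA]
    if bad:
        shown = ", ".join(f"{c!r}@{i}" for i, c in bad[:5])
        raise ValueError(f"non-standard residues in sequence: {shown}")
    return seq


def isoelectric_point(sequence: str) -> float:
    """pI by root-finding of the Bjellqvist net-charge curve on [0, 14].

    Uses Biopython's charge model; the returned pH has |net charge| well
    below 1e-3.
    """
    ip = IsoelectricPoint(_validate_sequence(sequence))
    return float(brentq(ip.charge_at_pH, 0.0, 14.0, xtol=1e-6))


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), mole %."""
    seq = _validate_sequence(sequence)
    n = len(seq)
    return 100.0 * (
        seq.count("A") / n
        + 2.9 * seq.count("V") / n
        + 3.9 * (seq.count("I") + seq.count("L")) / n
    )


@dataclass(frozen=True)
class FeatureVector:
    """The ten candidate physicochemical descriptors of one protein."""

    aromaticity: float
    gravy: float
    instability_index: float
    isoelectric_point: float
    n_negative: int
    n_positive: int
    extinction_coefficient: float
    aliphatic_index: float
    absorbance: float
    ip_over_mw: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


def compute_features(sequence: str, reduced_cysteines: bool = False) -> FeatureVector:
    """Compute all ten descriptors for one sequence.

    Charged-residue counts follow the ProtParam convention (negative = D+E,
    positive = K+R; histidine excluded). The extinction coefficient assumes
    oxidised cystines by default (``reduced_cysteines=True`` drops the
    cystine term); molecular weight is the average (not monoisotopic) mass.
    """
    seq = _validate_sequence(sequence)
    pa = ProteinAnalysis(seq)
    counts = pa.count_amino_acids()
    mw = pa.molecular_weight()
    ext_reduced, ext_oxidized = pa.molar_extinction_coefficient()
    ext = ext_reduced if reduced_cysteines else ext_oxidized
    pi = isoelectric_point(seq)
    return FeatureVector(
        aromaticity=pa.aromaticity(),
        gravy=pa.gravy(),
        instability_index=pa.instability_index(),
        isoelectric_point=pi,
        n_negative=counts["D"] + counts["E"],
        n_positive=counts["K"] + counts["R"],
        extinction_coefficient=float(ext),
        aliphatic_index=aliphatic_index(seq),
        absorbance=ext / mw,
        ip_over_mw=pi / mw,
    )


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Raw and z-scored descriptor values for a set of proteins.

    Standardisation is population z-scoring over the matrix's proteins;
    constant columns map to 0. ``selected`` names the descriptors that feed
    the scalar PCP score.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame
    selected: tuple[str, ...] = field(default_factory=tuple)

    @property
    def proteins(self) -> list[str]:
        return list(self.raw.index)

    @classmethod
    def from_sequences(
        cls, sequences: Mapping[str, str], reduced_cysteines: bool = False
    ) -> "FeatureMatrix":
        if not sequences:
            raise ValueError("no sequences given")
        raw = pd.DataFrame(
            {p: compute_features(s, reduced_cysteines).as_array() for p, s in sequences.items()},
            index=list(FEATURE_NAMES),
        ).T
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        standardized = (raw - mu).div(sd.where(sd > 0, 1.0), axis=1)
        standardized.loc[:, (sd == 0.0).to_numpy()] = 0.0
        return cls(raw=raw, standardized=standardized)

    def with_selection(self, names: Sequence[str]) -> "FeatureMatrix":
        unknown = set(names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        return replace(self, selected=tuple(names))

    def pcp_score(self, protein: str) -> float:
        """Mean of the protein's z-scored selected descriptors."""
        if protein not in self.raw.index:
            raise KeyError(f"protein {protein!r} not in feature matrix")
        if not self.selected:
            raise ValueError("no selected features; call with_selection first")
        return float(self.standardized.loc[protein, list(self.selected)].mean())

    def pcp_scores(self) -> dict[str, float]:
        return {p: self.pcp_score(p) for p in self.proteins}


# ---------------------------------------------------------------------------
# feature ranking and selection
# ---------------------------------------------------------------------------

def rank_features(
    matrix: FeatureMatrix,
    labels: Mapping[str, str],
    classifier_id: str,
    top_n: int = 5,
    seed: int = 0,
) -> list[str]:
    """Top-``top_n`` descriptors by importance of one trained ranker.

    Trains the named classifier on (z-scored descriptors -> label) over the
    labelled proteins and returns the leading descriptors, ties broken by
    canonical order. All rankers are seeded and single-threaded, so repeated
    calls give identical rankings.
    """
    if classifier_id not in CLASSIFIER_IDS:
        raise ValueError(f"unknown classifier {classifier_id!r}; expected one of {CLASSIFIER_IDS}")
    proteins = [p for p in matrix.proteins if p in labels]
    if not proteins:
        raise ValueError("no labelled proteins in matrix")
    y_raw = [labels[p] for p in proteins]
    if len(set(y_raw)) < 2:
        raise ValueError("feature ranking needs at least 2 distinct labels")
    X = matrix.standardized.loc[proteins].to_numpy()
    from sklearn.preprocessing import LabelEncoder

    y = LabelEncoder().fit_transform(y_raw)

    if classifier_id == "rfe":
        from sklearn.feature_selection import RFE
        from sklearn.linear_model import LogisticRegression

        rfe = RFE(LogisticRegression(max_iter=2000), n_features_to_select=1, step=1)
        rfe.fit(X, y)
        order = np.argsort(rfe.ranking_, kind="stable")  # rank 1 = most important
        return [FEATURE_NAMES[i] for i in order[:top_n]]

    if classifier_id == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(n_estimators=100, random_state=seed, n_jobs=1, verbosity=0)
    elif classifier_id == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    else:
        from sklearn.ensemble import ExtraTreesClassifier

        clf = ExtraTreesClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    importance = np.asarray(clf.feature_importances_, dtype=float)
    order = sorted(range(len(FEATURE_NAMES)), key=lambda i: (-importance[i], i))
    return [FEATURE_NAMES[i] for i in order[:top_n]]


@dataclass
class SelectionReport:
    """Hit counts of the four per-classifier nominations and the selected set."""

    rankings: dict[str, list[str]]
    hits: dict[str, int]
    selected: tuple[str, ...]


def select_features(
    rankings: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    min_hits: int = 2,
) -> SelectionReport:
    """Vote over four top-feature lists; keep descriptors with >= min_hits hits.

    Each list must contain distinct known descriptors (at most all ten).
    ``hits`` counts, for every descriptor, the number of lists naming it;
    the selected set is emitted in canonical descriptor order.
    """
    if isinstance(rankings, Mapping):
        named = {k: list(v) for k, v in rankings.items()}
    else:
        named = {f"classifier_{i}": list(v) for i, v in enumerate(rankings)}
    if len(named) != 4:
        raise ValueError(f"expected exactly 4 rankings, got {len(named)}")
    for name, lst in named.items():
        if len(lst) > len(FEATURE_NAMES):
            raise ValueError(f"ranking {name!r} longer than the {len(FEATURE_NAMES)} descriptors")
        if len(set(lst)) != len(lst):
            raise ValueError(f"ranking {name!r} contains duplicates")
        unknown = set(lst) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"ranking {name!r} names unknown features: {sorted(unknown)}")
    hits = {f: sum(f in lst for lst in named.values()) for f in FEATURE_NAMES}
    selected = tuple(f for f in FEATURE_NAMES if hits[f] >= min_hits)
    return SelectionReport(rankings=named, hits=hits, selected=selected)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein id -> sequence from a FASTA file (single-letter IUPAC)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """TSV: one row per protein, the ten raw descriptors, plus pcp_score if selected."""
    out = matrix.raw.copy()
    if matrix.selected:
        out["pcp_score"] = [matrix.pcp_score(p) for p in matrix.proteins]
    out.to_csv(path, sep="\t", index_label="protein")
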