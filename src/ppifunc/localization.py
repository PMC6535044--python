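"""Subcellular localization by level-1 neighbourhood majority vote.

Each protein is tagged nucleus, cytoplasm or interface (anything outside
the first two), or unknown. A test protein receives the modal known
location among its immediate interaction neighbours; when no neighbour has
a known location the vote fails — neighbourhood-free proteins cannot be
localized by this method.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

from .network import ProteinNetwork, WeightTables, edge_key

LOCATIONS = ("nucleus", "cytoplasm", "interface")
UNKNOWN = "unknown"
FAILED = None  # failure marker returned by predict_localization

LocalizationTable = dict[str, str]


def predict_localization(
    test: str,
    graph: ProteinNetwork,
    table: Mapping[str, str],
    weights: WeightTables | None = None,
) -> str | None:
    """Modal known location among the test protein's immediate neighbours.

    Ties are broken by the larger summed edge weight from the tied
    location's voters to the test protein (when ``weights`` is given), then
    by the fixed order nucleus > cytoplasm > interface. Returns ``None``
    when no neighbour has a known location.
    """
    if test not in graph.proteins:
        raise KeyError(f"test protein {test!r} not in graph")
    counts = {loc: 0 for loc in LOCATIONS}
    ew_sum = {loc: 0.0 for loc in LOCATIONS}
    for n in graph.neighbors(test):
        loc = table.get(n, UNKNOWN)
        if loc in counts:
            counts[loc] += 1
            if weights is not None:
                ew_sum[loc] += weights.edge_weight.get(edge_key(test, n), 0.0)
    if not any(counts.values()):
        return FAILED
    # LOCATIONS order gives the fixed final tie-break via stable min
    return min(LOCATIONS, key=lambda loc: (-counts[loc], -ew_sum[loc]))


def localization_accuracy(
    predictions: Mapping[str, str | None], truth: Mapping[str, str]
) -> dict[str, dict]:
    """Per-category tallies of a localization run.

    For every true category: ``matched`` (prediction equals truth),
    ``unmatched`` (prediction differs), ``failed`` (vote failed), ``total``
    and ``accuracy_pct`` = 100 * matched / total rounded to one decimal —
    failures count against accuracy. Accuracy is ``None`` when every
    protein of the category failed.
    """
    report: dict[str, dict] = {
        loc: {"matched": 0, "unmatched": 0, "failed": 0} for loc in LOCATIONS
    }
    for protein, predicted in predictions.items():
        if protein not in truth:
            raise KeyError(f"no truth entry for predicted protein {protein!r}")
        true_loc = truth[protein]
        if true_loc not in report:
            continue  # unknown-truth proteins are not scoreable
        if predicted is FAILED:
            report[true_loc]["failed"] += 1
        elif predicted == true_loc:
            report[true_loc]["matched"] += 1
        else:
            report[true_loc]["unmatched"] += 1
    for tally in report.values():
        total = tally["matched"] + tally["unmatched"] + tally["failed"]
        tally["total"] = total
        denom_known = tally["matched"] + tally["unmatched"]
        if total == 0 or denom_known == 0:
            tally["accuracy_pct"] = None
        else:
            tally["accuracy_pct"] = round(100.0 * tally["matched"] / total, 1)
    return report


def read_localization_table(path: str | Path) -> LocalizationTable:
    """TSV reader (columns ``protein``, ``location``); values outside the
    known categories raise."""
    table: LocalizationTable = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            loc = row["location"].strip()
            if loc not in LOCATIONS and loc != UNKNOWN:
                raise ValueError(f"invalid location {loc!r} for {row['protein']!r}")
            table[row["protein"].strip()] = loc
    return table


def write_localization_table(table: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tlocation\n")
        for p in sorted(table):
            fh.write(f"{p}\t{table[p]}\n")


def write_accuracy_report(report: Mapping[str, Mapping], path: str | Path) -> None:
    """Writer mirroring the per-category matched/unmatched/failed table."""
    with Path(path).open("w") as fh:
        fh.write("category\ttotal\tmatched\tunmatched\tfailed\taccuracy_pct\n")
        for loc in LOCATIONS:
            t = report[loc]
            acc = "NA" if t["accuracy_pct"] is None else t["accuracy_pct"]
            fh.write(
                f"{loc}\t{t['total']}\t{t['matched']}\t{t['unmatched']}\t{t['failed']}\t{acc}\n"
            )
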