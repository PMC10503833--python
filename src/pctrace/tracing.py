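"""Cross-compartment clonal lineage tracing.

Joins the clone partition with per-barcode genomic-state and compartment
labels into a clone x (compartment, state) count table, finds clones spanning
multiple nodes, and tabulates spleen-state x bone-marrow-state spanning
frequencies (the adjacency behind chord/Circos-style clone-sharing plots).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .clonotype import CloneAssignment

__all__ = [
    "SpanMatrix",
    "build_clone_state_table",
    "spanning_clones",
    "span_frequency_matrix",
    "export_chord_adjacency",
]


@dataclass
class SpanMatrix:
    """Spleen-state x BM-state clone (or cell) frequencies."""

    values: pd.DataFrame  # rows: axis_a states, cols: axis_b states
    normalized: bool
    empty_rows: list[str]


def build_clone_state_table(
    assignment: CloneAssignment,
    states: pd.Series,
    compartments: pd.Series,
    specificity: pd.Series | None = None,
    keep: set[str] | None = None,
) -> pd.DataFrame:
    """Aggregate clone membership into (clone, compartment, state) cell counts.

    Barcodes lacking a state or compartment label are excluded (their count is
    attached as ``table.attrs["n_unlabeled"]``); with ``keep``, cells whose
    specificity label is outside the set are dropped first.
    """
    df = assignment.assignments[["barcode", "clone_id"]].copy()
    if specificity is not None and keep is not None:
        df = df[df["barcode"].map(specificity).isin(keep)]
    df["state"] = df["barcode"].map(states)
    df["compartment"] = df["barcode"].map(compartments)
    labeled = df.dropna(subset=["state", "compartment"])
    n_unlabeled = len(df) - len(labeled)
    if labeled.empty:
        raise ValueError("no labeled cells to trace")
    table = (
        labeled.groupby(["clone_id", "compartment", "state"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    table.attrs["n_unlabeled"] = n_unlabeled
    return table


def spanning_clones(table: pd.DataFrame, min_nodes: int = 2) -> pd.DataFrame:
    """Clones present in at least ``min_nodes`` distinct (compartment, state) nodes.

    Returns one row per spanning clone with its node set and node count.
    """
    nodes = (
        table.assign(node=table["compartment"] + ":" + table["state"])
        .groupby("clone_id")["node"]
        .apply(lambda s: tuple(sorted(set(s))))
        .rename("nodes")
        .reset_index()
    )
    nodes["n_nodes"] = nodes["nodes"].map(len)
    return nodes[nodes["n_nodes"] >= min_nodes].reset_index(drop=True)


def span_frequency_matrix(
    table: pd.DataFrame,
    axis_a: tuple[str, list[str]] = ("spleen", None),
    axis_b: tuple[str, list[str]] = ("bone_marrow", None),
    normalize: bool = True,
    count: str = "clones",
) -> SpanMatrix:
    """Count clones spanning each (axis_a state, axis_b state) pair.

    Entry (i, j) counts clones with at least one cell in compartment-a state i
    and at least one cell in compartment-b state j (a clone touching several
    states contributes to every touched pair: the all-pairs convention). With
    ``count="cells"`` the entry sums the clone's cell counts over the pair
    instead. ``normalize=True`` row-normalizes so each compartment-a state's
    destinations sum to 1; rows with zero mass are reported in ``empty_rows``,
    never NaN-filled.
    """
    comp_a, states_a = axis_a
    comp_b, states_b = axis_b
    sub_a = table[table["compartment"] == comp_a]
    sub_b = table[table["compartment"] == comp_b]
    if states_a is None:
        states_a = sorted(sub_a["state"].unique())
    if states_b is None:
        states_b = sorted(sub_b["state"].unique())

    mat = pd.DataFrame(0.0, index=pd.Index(states_a, name=comp_a), columns=pd.Index(states_b, name=comp_b))
    merged = sub_a.merge(sub_b, on="clone_id", suffixes=("_a", "_b"))
    for _, row in merged.iterrows():
        sa, sb = row["state_a"], row["state_b"]
        if sa in mat.index and sb in mat.columns:
            if count == "clones":
                mat.loc[sa, sb] += 1.0
            elif count == "cells":
                mat.loc[sa, sb] += row["n_cells_a"] + row["n_cells_b"]
            else:
                raise ValueError(f"unknown count mode {count!r}")

    empty_rows: list[str] = []
    if normalize:
        sums = mat.sum(axis=1)
        empty_rows = list(sums.index[sums == 0])
        nonzero = sums > 0
        mat.loc[nonzero] = mat.loc[nonzero].div(sums[nonzero], axis=0)
    return SpanMatrix(values=mat, normalized=normalize, empty_rows=empty_rows)


def export_chord_adjacency(
    table: pd.DataFrame, out_path: str | Path, min_nodes: int = 2
) -> pd.DataFrame:
    """Write the long-format adjacency of spanning clones for chord diagrams.

    One row per spanning clone and unordered node pair
    (``source_node``, ``target_node``, ``clone_id``, ``weight``); nodes are
    named ``<compartment>:<state>`` and each row carries weight 1 (one
    clone-pair incidence), so the weight sum equals the total number of
    spanning incidences.
    """
    spanning = spanning_clones(table, min_nodes=min_nodes)
    rows = []
    for _, rec in spanning.iterrows():
        nodes = rec["nodes"]
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                rows.append(
                    {
                        "source_node": nodes[i],
                        "target_node": nodes[j],
                        "clone_id": rec["clone_id"],
                        "weight": 1,
                    }
                )
    out = pd.DataFrame(rows, columns=["source_node", "target_node", "clone_id", "weight"])
    out.to_csv(out_path, index=False)
    return out
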