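"""Antigen-specificity inference from IGHV gene usage rank lists.

NP (hapten) responses are dominated by a characteristic set of IGHV genes, so
specificity can be inferred from heavy V usage alone: genes from an
antigen-sorted NP reference that stay prevalent in both tracked samples are
NP-specific, while genes shared by both samples but absent from the reference
are attributed to the carrier (KLH).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RankList",
    "SpecificitySets",
    "strip_allele",
    "ighv_rank_list",
    "derive_specificity_sets",
    "assign_specificity",
]


def strip_allele(v_call: str) -> str:
    """Collapse an allele-suffixed call (``IGHV1-72*01``) to the gene name."""
    return v_call.split("*", 1)[0]


@dataclass
class RankList:
    """Top-N IGHV usage of one sample, ordered by descending cell count."""

    sample_id: str
    entries: pd.DataFrame  # columns: v_gene, n_cells, frequency
    top_n: int

    @property
    def genes(self) -> set[str]:
        return set(self.entries["v_gene"])


@dataclass(frozen=True)
class SpecificitySets:
    np_genes: frozenset[str]
    klh_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.np_genes & self.klh_genes:
            raise ValueError("np_genes and klh_genes must be disjoint")


def ighv_rank_list(
    cells: pd.DataFrame,
    top_n: int,
    sample_id: str = "",
    granularity: str = "allele",
) -> RankList:
    """Rank heavy V genes by per-cell frequency of occurrence.

    Counting is per cell (one resolved heavy chain each), frequencies are
    relative to all cells in the sample, and ties are broken lexicographically
    by gene name so the truncation is deterministic.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if cells.empty:
        raise ValueError("cells table is empty")
    calls = cells["heavy_v"]
    if granularity == "gene":
        calls = calls.map(strip_allele)
    elif granularity != "allele":
        raise ValueError(f"unknown granularity {granularity!r}")
    counts = calls.value_counts()
    total = int(counts.sum())
    entries = (
        pd.DataFrame({"v_gene": counts.index, "n_cells": counts.to_numpy()})
        .sort_values(["n_cells", "v_gene"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    entries["frequency"] = entries["n_cells"] / total
    return RankList(sample_id=sample_id, entries=entries, top_n=top_n)


def derive_specificity_sets(
    np_reference: RankList, sample_a: RankList, sample_b: RankList
) -> SpecificitySets:
    """Intersect rank lists into NP and KLH gene sets.

    NP genes are reference genes prevalent (top-N member) in both tracked
    samples; KLH genes are shared between the two samples but absent from the
    NP reference. Disjointness holds by construction.
    """
    for rl in (np_reference, sample_a, sample_b):
        if rl.entries.empty:
            raise ValueError(f"rank list {rl.sample_id!r} is empty")
    shared = sample_a.genes & sample_b.genes
    np_genes = frozenset(np_reference.genes & shared)
    klh_genes = frozenset(shared - np_reference.genes)
    return SpecificitySets(np_genes=np_genes, klh_genes=klh_genes)


def assign_specificity(
    cells: pd.DataFrame, sets: SpecificitySets, granularity: str = "allele"
) -> pd.Series:
    """Label each cell NP / KLH / unassigned from its heavy V call alone."""
    calls = cells["heavy_v"]
    if granularity == "gene":
        calls = calls.map(strip_allele)

    def label(v: str) -> str:
        if v in sets.np_genes:
            return "NP"
        if v in sets.klh_genes:
            return "KLH"
        return "unassigned"

    out = calls.map(label)
    out.index = cells.index
    out.name = "specificity"
    return out
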