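"""Somatic hypermutation quantification and high-affinity substitution calls.

Mutation counts are nucleotide substitutions between an observed V segment and
its germline, over a gap-padded alignment; the designated high-affinity
substitution (the W33L analogue in the IGHV1-72*01-like gene) is called at the
amino-acid level at a fixed 1-based residue index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "AffinityMutationSpec",
    "AlignmentError",
    "count_v_mutations",
    "detect_affinity_mutation",
    "mutation_profiles",
    "compare_mutation_distributions",
    "affinity_maturation_proportions",
]

_IGNORED = set("-.Nn")


class AlignmentError(ValueError):
    """Raised for malformed alignments or mis-specified residue numbering."""


@dataclass(frozen=True)
class AffinityMutationSpec:
    """The designated high-affinity substitution of one V gene."""

    v_gene: str = "IGHV1-72*01"
    position: int = 33  # 1-based residue index into the germline aa sequence
    from_aa: str = "W"
    to_aa: str = "L"

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError("from_aa and to_aa must differ")


def count_v_mutations(observed_nt: str, germline_nt: str) -> tuple[int, int]:
    """Count nucleotide substitutions over comparable alignment positions.

    Positions where either sequence carries a gap (``-``/``.``) or an ambiguous
    base (``N``) are excluded from both the numerator and the denominator.
    Symmetric in its two arguments.
    """
    if len(observed_nt) != len(germline_nt):
        raise AlignmentError(
            f"alignment lengths differ: {len(observed_nt)} vs {len(germline_nt)}"
        )
    n_mut = 0
    n_cmp = 0
    for o, g in zip(observed_nt, germline_nt):
        if o in _IGNORED or g in _IGNORED:
            continue
        n_cmp += 1
        if o != g:
            n_mut += 1
    if n_cmp == 0:
        raise AlignmentError("zero comparable positions in alignment")
    return n_mut, n_cmp


def detect_affinity_mutation(
    observed_aa: str, germline_aa: str, spec: AffinityMutationSpec
) -> bool:
    """True iff the residue at ``spec.position`` equals ``spec.to_aa``.

    The germline residue at that position must equal ``spec.from_aa``;
    otherwise the numbering is mis-specified for this sequence.
    """
    i = spec.position - 1
    if i >= len(germline_aa) or i >= len(observed_aa):
        raise AlignmentError(f"position {spec.position} beyond sequence length")
    if germline_aa[i] != spec.from_aa:
        raise AlignmentError(
            f"germline residue at position {spec.position} is {germline_aa[i]!r}, "
            f"expected {spec.from_aa!r}"
        )
    return observed_aa[i] == spec.to_aa


def mutation_profiles(
    cells: pd.DataFrame, spec: AffinityMutationSpec | None = None
) -> pd.DataFrame:
    """Per-cell mutation profiles from aligned heavy V sequences.

    ``cells`` must carry ``heavy_v_sequence_nt`` / ``heavy_germline_v_nt``
    (gap-padded, in frame). The affinity call is made only for cells whose
    heavy V matches ``spec.v_gene``; others get ``has_affinity_mutation=False``
    and ``affinity_evaluated=False``.
    """
    rows = []
    for _, cell in cells.iterrows():
        obs, germ = str(cell["heavy_v_sequence_nt"]), str(cell["heavy_germline_v_nt"])
        if not obs or not germ:
            continue
        n_mut, n_cmp = count_v_mutations(obs, germ)
        has_aff = False
        evaluated = False
        if spec is not None and cell["heavy_v"] == spec.v_gene:
            obs_aa = str(Seq(obs.replace("-", "").replace(".", "")).translate())
            germ_aa = str(Seq(germ.replace("-", "").replace(".", "")).translate())
            has_aff = detect_affinity_mutation(obs_aa, germ_aa, spec)
            evaluated = True
        rows.append(
            {
                "barcode": cell["barcode"],
                "v_gene": cell["heavy_v"],
                "n_mutations": n_mut,
                "aligned_length": n_cmp,
                "mutation_frequency": n_mut / n_cmp,
                "has_affinity_mutation": has_aff,
                "affinity_evaluated": evaluated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "v_gene",
            "n_mutations",
            "aligned_length",
            "mutation_frequency",
            "has_affinity_mutation",
            "affinity_evaluated",
        ],
    )


def compare_mutation_distributions(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two mutation-frequency groups.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``group_a``. The p-value
    is exact for combined n <= 20 without ties, and uses the normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    rank_sum_a = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return rank_sum_a, float(res.pvalue)


def affinity_maturation_proportions(
    profiles: pd.DataFrame, group_col: str, spec: AffinityMutationSpec | None = None
) -> pd.DataFrame:
    """Per-group fraction of V segments carrying the high-affinity substitution.

    Profiles are restricted to the designated V gene (via ``affinity_evaluated`` or
    an explicit ``spec``). Groups absent from the table are simply not reported
    (undefined, never 0).
    """
    df = profiles
    if spec is not None:
        df = df[df["v_gene"] == spec.v_gene]
    elif "affinity_evaluated" in df.columns:
        df = df[df["affinity_evaluated"]]
    out = (
        df.groupby(group_col)
        .agg(
            n_affinity=("has_affinity_mutation", "sum"),
            n_total=("has_affinity_mutation", "size"),
        )
        .reset_index()
    )
    out["fraction"] = out["n_affinity"] / out["n_total"]
    return out
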