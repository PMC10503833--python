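"""Clone calling by exact V(D)J identity.

A clone is the set of cells sharing identical heavy V/D/J gene calls, an
identical heavy CDR3 amino-acid sequence, and identical light V/J gene calls
(the productively rearranged light chain). Matching is exact string equality --
no junction-similarity clustering -- at either allele or gene granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .specificity import strip_allele

__all__ = ["ClonotypeKey", "CloneAssignment", "clonotype_key", "call_clones", "clone_sizes_by_state"]

KEY_FIELDS = ["heavy_v", "heavy_d", "heavy_j", "heavy_cdr3_aa", "light_v", "light_j"]


@dataclass(frozen=True)
class ClonotypeKey:
    heavy_v: str
    heavy_d: str  # may be empty; empty is preserved, not a wildcard
    heavy_j: str
    heavy_cdr3_aa: str
    light_v: str
    light_j: str
    light_cdr3_aa: str = ""  # populated only in strict mode

    def as_tuple(self) -> tuple[str, ...]:
        return (
            self.heavy_v,
            self.heavy_d,
            self.heavy_j,
            self.heavy_cdr3_aa,
            self.light_v,
            self.light_j,
            self.light_cdr3_aa,
        )


def clonotype_key(
    cell: pd.Series, granularity: str = "allele", require_light_cdr3: bool = False
) -> ClonotypeKey:
    """Extract the clonal identity tuple of one paired cell."""
    if not str(cell["heavy_cdr3_aa"]):
        raise ValueError(f"cell {cell['barcode']!r} has no heavy CDR3 amino-acid sequence")

    def g(v: str) -> str:
        return strip_allele(v) if granularity == "gene" else str(v)

    return ClonotypeKey(
        heavy_v=g(cell["heavy_v"]),
        heavy_d=g(cell["heavy_d"]) if str(cell["heavy_d"]) else "",
        heavy_j=g(cell["heavy_j"]),
        heavy_cdr3_aa=str(cell["heavy_cdr3_aa"]),
        light_v=g(cell["light_v"]),
        light_j=g(cell["light_j"]),
        light_cdr3_aa=str(cell["light_cdr3_aa"]) if require_light_cdr3 else "",
    )


@dataclass
class CloneAssignment:
    """A partition of paired cells into clones.

    ``assignments`` has one row per clonotyped barcode (barcode, clone_id,
    singleton); ``keys`` maps clone_id to its identity tuple. Clone ids are
    stable integers, numbered by descending clone size with ties broken by the
    lexicographic order of the key tuple.
    """

    assignments: pd.DataFrame
    keys: dict[int, ClonotypeKey]
    n_excluded_no_cdr3: int = 0
    members: dict[int, list[str]] = field(default_factory=dict)

    @property
    def clone_sizes(self) -> pd.Series:
        return self.assignments["clone_id"].value_counts().sort_index()


def call_clones(
    cells: pd.DataFrame,
    min_clone_size: int = 1,
    granularity: str = "allele",
    require_light_cdr3: bool = False,
) -> CloneAssignment:
    """Group paired cells into clones by exact clonotype-key equality.

    Cells missing a heavy CDR3 are excluded and counted. All clones are
    retained regardless of ``min_clone_size``; clones of size 1 (or below
    ``min_clone_size``) are flagged ``singleton``. Deterministic and invariant
    to input row order.
    """
    usable = cells[cells["heavy_cdr3_aa"].astype(str) != ""].copy()
    n_excluded = len(cells) - len(usable)

    if usable.empty:
        return CloneAssignment(
            assignments=pd.DataFrame(columns=["barcode", "clone_id", "singleton"]),
            keys={},
            n_excluded_no_cdr3=n_excluded,
        )

    def g(col: pd.Series) -> pd.Series:
        s = col.astype(str)
        return s.map(strip_allele) if granularity == "gene" else s

    usable["_key"] = list(
        zip(
            g(usable["heavy_v"]),
            g(usable["heavy_d"].fillna("")),
            g(usable["heavy_j"]),
            usable["heavy_cdr3_aa"].astype(str),
            g(usable["light_v"]),
            g(usable["light_j"]),
            usable["light_cdr3_aa"].astype(str)
            if require_light_cdr3
            else [""] * len(usable),
        )
    )
    groups = usable.groupby("_key", sort=False)["barcode"].apply(sorted)
    # numbering: descending size, then key lexicographic
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    keys: dict[int, ClonotypeKey] = {}
    members: dict[int, list[str]] = {}
    rows = []
    for cid, (key, barcodes) in enumerate(ordered, start=1):
        keys[cid] = ClonotypeKey(*key)
        members[cid] = list(barcodes)
        singleton = len(barcodes) < max(min_clone_size, 2)
        for bc in barcodes:
            rows.append({"barcode": bc, "clone_id": cid, "singleton": singleton})
    assignments = pd.DataFrame(rows).sort_values("barcode", kind="mergesort").reset_index(drop=True)
    return CloneAssignment(
        assignments=assignments, keys=keys, n_excluded_no_cdr3=n_excluded, members=members
    )


def clone_sizes_by_state(
    assignment: CloneAssignment,
    states: pd.Series,
    specificity: pd.Series | None = None,
    keep: set[str] | None = None,
) -> pd.DataFrame:
    """Tabulate cells per clone within each genomic state.

    ``states`` (and optional ``specificity``) are barcode-indexed labels;
    barcodes without a state label fall into an ``"unlabeled"`` bucket so that
    the table conserves cell counts. With ``keep`` (e.g. {"NP"}), cells whose
    specificity label is outside the set are dropped first.
    """
    df = assignment.assignments[["barcode", "clone_id"]].copy()
    if specificity is not None and keep is not None:
        spec = df["barcode"].map(specificity)
        df = df[spec.isin(keep)]
    df["state"] = df["barcode"].map(states).fillna("unlabeled")
    out = (
        df.groupby(["state", "clone_id"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    return out
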