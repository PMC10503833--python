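"""Repertoire and expression I/O plus heavy/light chain pairing.

Contig tables are held as pandas DataFrames with one row per sequenced chain
(canonical columns below); paired cells carry one resolved heavy + light chain
per barcode, the unit of clonotyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

__all__ = [
    "ContigFormatError",
    "CONTIG_COLUMNS",
    "CELL_COLUMNS",
    "PairedCells",
    "read_contigs",
    "write_contigs_tenx",
    "write_contigs_airr",
    "pair_cell_chains",
    "read_expression",
    "log_normalize",
]

CONTIG_COLUMNS = [
    "barcode",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "cdr3_aa",
    "cdr3_nt",
    "productive",
    "umi_count",
    "v_sequence_nt",
    "germline_v_nt",
]

CELL_COLUMNS = [
    "barcode",
    "heavy_v",
    "heavy_d",
    "heavy_j",
    "heavy_cdr3_aa",
    "heavy_umi",
    "heavy_v_sequence_nt",
    "heavy_germline_v_nt",
    "light_locus",
    "light_v",
    "light_j",
    "light_cdr3_aa",
    "light_umi",
    "resolution_note",
]

_VALID_LOCI = {"IGH", "IGK", "IGL"}

_TENX_REQUIRED = ["barcode", "chain", "v_gene", "d_gene", "j_gene", "cdr3", "productive", "umis"]
_AIRR_REQUIRED = ["cell_id", "locus", "v_call", "d_call", "j_call", "junction_aa", "productive"]


class ContigFormatError(ValueError):
    """Raised when a contig file is missing required columns or malformed."""


def _parse_productive(values: pd.Series) -> pd.Series:
    """10x encodes productivity as 'True'/'False'/'None'; None means not productive."""

    def one(v) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        return s in {"true", "t", "1"}

    return values.map(one)


def read_contigs(path: str | Path, dialect: str = "tenx_csv") -> pd.DataFrame:
    """Read a contig table in the 10x CSV or AIRR Rearrangement TSV dialect.

    Rows with loci outside IGH/IGK/IGL (e.g. TR chains) are skipped and
    counted; 10x rows flagged not-a-cell or low-confidence (when those columns
    exist) are dropped with a logged count.
    """
    path = Path(path)
    if dialect == "tenx_csv":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in _TENX_REQUIRED:
            if col not in raw.columns:
                raise ContigFormatError(f"10x contig CSV missing required column {col!r}")
        n0 = len(raw)
        if "is_cell" in raw.columns:
            raw = raw[_parse_productive(raw["is_cell"])]
        if "high_confidence" in raw.columns:
            raw = raw[_parse_productive(raw["high_confidence"])]
        if len(raw) < n0:
            logger.info("read_contigs: dropped %d not-a-cell/low-confidence rows", n0 - len(raw))
        keep = raw["chain"].isin(_VALID_LOCI)
        if (~keep).any():
            logger.warning("read_contigs: skipped %d rows with unknown locus", int((~keep).sum()))
        raw = raw[keep]
        out = pd.DataFrame(
            {
                "barcode": raw["barcode"],
                "locus": raw["chain"],
                "v_call": raw["v_gene"],
                "d_call": raw["d_gene"].replace("None", ""),
                "j_call": raw["j_gene"],
                "cdr3_aa": raw["cdr3"],
                "cdr3_nt": raw.get("cdr3_nt", pd.Series("", index=raw.index)),
                "productive": _parse_productive(raw["productive"]),
                "umi_count": pd.to_numeric(raw["umis"]).astype(int),
                "v_sequence_nt": raw.get("v_sequence_nt", pd.Series("", index=raw.index)),
                "germline_v_nt": raw.get("germline_v_nt", pd.Series("", index=raw.index)),
            }
        )
    elif dialect == "airr_tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in _AIRR_REQUIRED:
            if col not in raw.columns:
                raise ContigFormatError(f"AIRR TSV missing required column {col!r}")
        keep = raw["locus"].isin(_VALID_LOCI)
        if (~keep).any():
            logger.warning("read_contigs: skipped %d rows with unknown locus", int((~keep).sum()))
        raw = raw[keep]
        dup = raw.get("duplicate_count", pd.Series("0", index=raw.index)).replace("", "0")
        out = pd.DataFrame(
            {
                "barcode": raw["cell_id"],
                "locus": raw["locus"],
                "v_call": raw["v_call"],
                "d_call": raw["d_call"],
                "j_call": raw["j_call"],
                "cdr3_aa": raw["junction_aa"],
                "cdr3_nt": raw.get("junction", pd.Series("", index=raw.index)),
                "productive": _parse_productive(raw["productive"]),
                "umi_count": pd.to_numeric(dup).astype(int),
                "v_sequence_nt": raw.get("sequence_alignment", pd.Series("", index=raw.index)),
                "germline_v_nt": raw.get("germline_alignment", pd.Series("", index=raw.index)),
            }
        )
    else:
        raise ValueError(f"unknown contig dialect {dialect!r}")
    return out.reset_index(drop=True)[CONTIG_COLUMNS]


def write_contigs_tenx(contigs: pd.DataFrame, path: str | Path) -> None:
    """Write the 10x ``filtered_contig_annotations.csv`` dialect.

    The 10x dialect carries no V alignment sequences; those live in the AIRR
    TSV written alongside it.
    """
    out = pd.DataFrame(
        {
            "barcode": contigs["barcode"],
            "is_cell": "True",
            "contig_id": [f"{b}_contig_{i}" for i, b in enumerate(contigs["barcode"], 1)],
            "high_confidence": "True",
            "chain": contigs["locus"],
            "v_gene": contigs["v_call"],
            "d_gene": contigs["d_call"].replace("", "None"),
            "j_gene": contigs["j_call"],
            "cdr3": contigs["cdr3_aa"],
            "cdr3_nt": contigs["cdr3_nt"],
            "productive": contigs["productive"].map({True: "True", False: "False"}),
            "umis": contigs["umi_count"],
        }
    )
    out.to_csv(path, index=False)


def write_contigs_airr(contigs: pd.DataFrame, path: str | Path) -> None:
    """Write an AIRR Rearrangement TSV (lossless for this package's fields)."""
    out = pd.DataFrame(
        {
            "cell_id": contigs["barcode"],
            "locus": contigs["locus"],
            "v_call": contigs["v_call"],
            "d_call": contigs["d_call"],
            "j_call": contigs["j_call"],
            "junction_aa": contigs["cdr3_aa"],
            "junction": contigs["cdr3_nt"],
            "productive": contigs["productive"].map({True: "T", False: "F"}),
            "duplicate_count": contigs["umi_count"],
            "sequence_alignment": contigs["v_sequence_nt"],
            "germline_alignment": contigs["germline_v_nt"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


@dataclass
class PairedCells:
    """Resolved heavy+light records plus a QC accounting of exclusions."""

    cells: pd.DataFrame
    qc: dict[str, int] = field(default_factory=dict)


def pair_cell_chains(
    contigs: pd.DataFrame,
    heavy_policy: str = "drop",
    light_policy: str = "productive_then_max_umi",
) -> PairedCells:
    """Resolve each barcode's contigs into one heavy + one light chain.

    Multiple light chains are resolved to the productively rearranged one; among
    several productive lights the highest-UMI chain wins, ties broken
    lexicographically by ``v_call``. Barcodes with more than one heavy chain are
    excluded under ``heavy_policy="drop"`` (likely doublets) or resolved to the
    highest-UMI heavy under ``"max_umi"``. Barcodes lacking a heavy chain, any
    light chain, or any *productive* light chain are excluded; all exclusions
    are counted in ``qc``.

    The output is invariant to the row order of the input.
    """
    if heavy_policy not in {"drop", "max_umi"}:
        raise ValueError(f"unknown heavy_policy {heavy_policy!r}")
    if light_policy != "productive_then_max_umi":
        raise ValueError(f"unknown light_policy {light_policy!r}")

    igh = contigs[contigs["locus"] == "IGH"]
    lights = contigs[contigs["locus"].isin(["IGK", "IGL"])]
    all_barcodes = pd.Index(contigs["barcode"].unique())
    n_heavy = igh.groupby("barcode").size()
    n_light = lights.groupby("barcode").size().reindex(all_barcodes, fill_value=0)
    prod_lights = lights[lights["productive"]]
    n_prod = prod_lights.groupby("barcode").size().reindex(all_barcodes, fill_value=0)

    no_heavy = all_barcodes.difference(n_heavy.index)
    if heavy_policy == "drop":
        multi_heavy = n_heavy.index[n_heavy > 1]
        heavy_ok = n_heavy.index[n_heavy == 1]
    else:
        multi_heavy = pd.Index([])
        heavy_ok = n_heavy.index
    no_light = heavy_ok[n_light.reindex(heavy_ok, fill_value=0) == 0]
    with_light = heavy_ok[n_light.reindex(heavy_ok, fill_value=0) > 0]
    no_prod = with_light[n_prod.reindex(with_light, fill_value=0) == 0]
    paired_bcs = with_light[n_prod.reindex(with_light, fill_value=0) > 0]

    qc = {
        "paired": int(len(paired_bcs)),
        "no_heavy": int(len(no_heavy)),
        "multi_heavy_dropped": int(len(multi_heavy)),
        "no_light": int(len(no_light)),
        "no_productive_light": int(len(no_prod)),
    }

    # highest-UMI first, ties broken lexicographically by v_call
    def best_per_barcode(df: pd.DataFrame) -> pd.DataFrame:
        return (
            df.sort_values(
                ["barcode", "umi_count", "v_call"],
                ascending=[True, False, True],
                kind="mergesort",
            )
            .drop_duplicates("barcode", keep="first")
            .set_index("barcode")
        )

    heavy = best_per_barcode(igh[igh["barcode"].isin(paired_bcs)])
    light = best_per_barcode(prod_lights[prod_lights["barcode"].isin(paired_bcs)])

    idx = pd.Index(sorted(paired_bcs))
    nl = n_light.reindex(idx)
    np_ = n_prod.reindex(idx)
    note = pd.Series("unique", index=idx)
    note[(nl > 1) & (np_ < nl)] = "productive_selected"
    note[(note == "unique") & (np_ > 1)] = "umi_selected"

    cells = pd.DataFrame(
        {
            "barcode": idx,
            "heavy_v": heavy.loc[idx, "v_call"].to_numpy(),
            "heavy_d": heavy.loc[idx, "d_call"].to_numpy(),
            "heavy_j": heavy.loc[idx, "j_call"].to_numpy(),
            "heavy_cdr3_aa": heavy.loc[idx, "cdr3_aa"].to_numpy(),
            "heavy_umi": heavy.loc[idx, "umi_count"].astype(int).to_numpy(),
            "heavy_v_sequence_nt": heavy.loc[idx, "v_sequence_nt"].to_numpy(),
            "heavy_germline_v_nt": heavy.loc[idx, "germline_v_nt"].to_numpy(),
            "light_locus": light.loc[idx, "locus"].to_numpy(),
            "light_v": light.loc[idx, "v_call"].to_numpy(),
            "light_j": light.loc[idx, "j_call"].to_numpy(),
            "light_cdr3_aa": light.loc[idx, "cdr3_aa"].to_numpy(),
            "light_umi": light.loc[idx, "umi_count"].astype(int).to_numpy(),
            "resolution_note": note.to_numpy(),
        },
        columns=CELL_COLUMNS,
    ).reset_index(drop=True)
    logger.info("pair_cell_chains: %s", qc)
    return PairedCells(cells=cells, qc=qc)


def read_expression(path: str | Path, format: str = "mtx_dir") -> AnnData:
    """Load a cell x gene count matrix.

    ``mtx_dir`` expects a CellRanger-style triplet (``matrix.mtx`` in genes x
    cells orientation, ``barcodes.tsv``, ``features.tsv``); ``dense_tsv`` a
    genes-as-rows TSV with barcode columns. Duplicate barcodes and dimension
    mismatches raise a format error; all-zero cells are permitted but counted
    in the log.
    """
    path = Path(path)
    if format == "mtx_dir":
        mat = sio.mmread(str(path / "matrix.mtx"))
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
        features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].astype(str)
        if mat.shape != (len(features), len(barcodes)):
            raise ContigFormatError(
                f"matrix shape {mat.shape} inconsistent with "
                f"{len(features)} features x {len(barcodes)} barcodes"
            )
        X = sp.csr_matrix(mat.T)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        barcodes = pd.Series(df.columns.astype(str))
        features = pd.Series(df.index.astype(str))
        X = sp.csr_matrix(df.to_numpy().T)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if barcodes.duplicated().any():
        dups = barcodes[barcodes.duplicated()].tolist()
        raise ContigFormatError(f"duplicate barcodes in barcodes file: {dups[:5]}")
    adata = AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    zero_cells = int((np.asarray(X.sum(axis=1)).ravel() == 0).sum())
    if zero_cells:
        logger.warning("read_expression: %d all-zero cells", zero_cells)
    return adata


def log_normalize(adata: AnnData, target: float | None = None) -> np.ndarray:
    """Return log2(1 + count-per-cell-normalized) as a dense array.

    Library sizes are scaled to ``target`` (default: the median library size of
    the dataset), matching the log2-scaled counts used for centroid
    classification.
    """
    X = adata.X
    counts = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    lib = counts.sum(axis=1)
    lib[lib == 0] = 1.0
    if target is None:
        target = float(np.median(lib))
    return np.log2(1.0 + counts / lib[:, None] * target)
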