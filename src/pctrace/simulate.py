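"""Synthetic paired repertoire + expression data with full ground truth.

The generator emulates the statistical structure of a CD138+ splenocyte /
bone-marrow plasma-cell (PC) compartment profiled by coupled 5'-end scRNA-seq
and BCR-seq during a germinal-center (GC) response to a hapten-carrier antigen
(NP-KLH):

* nine genomic states (marginal-zone and follicular B-cell clusters, light- and
  dark-zone GC B cells, a transitional PC progenitor, and three PC clusters
  marked by *Tigit*, *Slpi* and *Lag3*), each with a block of elevated marker
  genes;
* clonal repertoires dominated by a small set of IGHV genes (an IGHV1-72*01
  analogue leads, as in NP responses where V_h186.2 = IGHV1-72 dominates);
* per-timepoint somatic-hypermutation accumulation on heavy V segments, with a
  designated high-affinity codon substitution (the W33L analogue) acquired by a
  configurable fraction of clonal lineages;
* clones spanning genomic states and the two anatomical compartments, with
  bone-marrow seeding restricted to PC-state clones and biased toward the
  clone's splenic state.

Every emitted cell is recorded in a truth table (clone, specificity, state,
compartment, timepoint, mutation count, affinity flag) so that downstream
operations can be scored exactly.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData
from Bio.Seq import Seq

__all__ = [
    "SimConfig",
    "GermlineRecord",
    "GermlineSet",
    "SimulationConfigError",
    "default_germline_set",
    "simulate_repertoire",
    "simulate_expression",
    "write_fixture_bundle",
    "B_STATES",
    "PC_STATES",
    "PROGENITOR_STATE",
]


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# Genomic-state names used throughout the package (splenic reference clusters).
B_STATES = (
    "MZ B",
    "B cells-C1",
    "B cells-C2",
    "LZ GC",
    "DZ GC",
)
PROGENITOR_STATE = "PC progenitor"
PC_STATES = ("PC-Tigit", "PC-Slpi", "PC-Lag3")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOP_CODONS
]
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVY"  # W reserved for the CDR3 anchor
_LEU_CODON = "CTG"


def _default_state_proportions() -> dict[str, float]:
    return {
        "MZ B": 0.06,
        "B cells-C1": 0.10,
        "B cells-C2": 0.08,
        "LZ GC": 0.16,
        "DZ GC": 0.14,
        "PC progenitor": 0.16,
        "PC-Tigit": 0.14,
        "PC-Slpi": 0.09,
        "PC-Lag3": 0.07,
    }


def _default_ighv_usage() -> dict[str, float]:
    # NP-dominant genes lead the repertoire; a second shared tier plays the
    # carrier (KLH) role; the tail is sporadic.
    return {
        "IGHV1-72*01": 30.0,
        "IGHV1-53*01": 12.0,
        "IGHV9-3*01": 8.0,
        "IGHV5-17*01": 6.0,
        "IGHV1-82*01": 5.0,
        "IGHV14-3*01": 4.0,
        "IGHV2-2*01": 1.5,
        "IGHV3-6*01": 1.2,
        "IGHV6-3*01": 1.0,
        "IGHV8-8*01": 0.8,
        "IGHV10-1*01": 0.6,
        "IGHV4-1*01": 0.5,
    }


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Proportion maps must each sum to 1; probabilities live in [0, 1].
    ``timepoint_index`` maps a timepoint label to the multiplier applied to
    ``mutation_rate_per_timepoint`` (21 d.p.i. -> 1, 35 d.p.i. -> 2).
    """

    n_cells: int = 2000
    n_clones: int = 150
    state_proportions: dict[str, float] = field(default_factory=_default_state_proportions)
    compartment_proportions: dict[str, float] = field(
        default_factory=lambda: {"spleen": 0.8, "bone_marrow": 0.2}
    )
    ighv_usage: dict[str, float] = field(default_factory=_default_ighv_usage)
    mutation_rate_per_timepoint: float = 3.0
    affinity_mutation_prob: float = 0.4
    n_genes: int = 2000
    n_marker_genes_per_state: int = 20
    marker_fold: float = 8.0
    library_size_mean: float = 2000.0
    seed: int = 0

    # Specificity truth: clones are NP/KLH/other according to their heavy V gene.
    np_ighv_genes: tuple[str, ...] = ("IGHV1-72*01", "IGHV1-53*01")
    klh_ighv_genes: tuple[str, ...] = (
        "IGHV9-3*01",
        "IGHV5-17*01",
        "IGHV1-82*01",
        "IGHV14-3*01",
    )

    timepoint_proportions: dict[str, float] = field(default_factory=lambda: {"35": 1.0})
    timepoint_index: dict[str, int] = field(default_factory=lambda: {"21": 1, "35": 2})

    decoy_light_prob: float = 0.1
    clone_size_exponent: float = 1.0
    clone_size_state_factor: dict[str, float] = field(
        default_factory=lambda: {s: 3.0 for s in PC_STATES}
    )
    state_spread: float = 0.2
    bm_diagonal_weight: float = 3.0
    # Per-primary-state multiplier on the bone-marrow seeding probability,
    # encoding the precursor-activity gradient PC-Tigit > PC-Slpi > PC-Lag3.
    bm_seeding_rate: dict[str, float] = field(
        default_factory=lambda: {"PC-Tigit": 3.0, "PC-Slpi": 2.0, "PC-Lag3": 1.0}
    )
    pc_states: tuple[str, ...] = PC_STATES
    progenitor_state: str = PROGENITOR_STATE
    cdr3_length_range: tuple[int, int] = (10, 16)
    expression_model: str = "nb"  # "nb" or "poisson"
    nb_dispersion: float = 0.1
    # The baseline per-gene expression profile is a property of the
    # transcriptome, shared across samples of one study; it gets its own seed
    # so that samples simulated with different seeds remain comparable
    # (label transfer, DEG) while per-cell noise still follows `seed`.
    expression_profile_seed: int = 1234

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_clones < 1:
            raise SimulationConfigError("n_cells and n_clones must be positive")
        if self.n_clones > self.n_cells:
            raise SimulationConfigError(
                f"requested n_clones={self.n_clones} > n_cells={self.n_cells}"
            )
        for name, mapping in (
            ("state_proportions", self.state_proportions),
            ("compartment_proportions", self.compartment_proportions),
            ("timepoint_proportions", self.timepoint_proportions),
        ):
            if not mapping:
                raise SimulationConfigError(f"{name} is empty")
            total = float(sum(mapping.values()))
            if abs(total - 1.0) > 1e-9:
                raise SimulationConfigError(f"{name} sums to {total}, expected 1")
        if not self.ighv_usage:
            raise SimulationConfigError("ighv_usage is empty")
        for p_name, p in (
            ("affinity_mutation_prob", self.affinity_mutation_prob),
            ("decoy_light_prob", self.decoy_light_prob),
            ("state_spread", self.state_spread),
        ):
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"{p_name}={p} outside [0, 1]")
        if self.mutation_rate_per_timepoint < 0:
            raise SimulationConfigError("mutation_rate_per_timepoint must be >= 0")
        if self.marker_fold <= 0:
            raise SimulationConfigError("marker_fold must be > 0")
        n_states = len(self.state_proportions)
        if self.n_marker_genes_per_state * n_states > self.n_genes:
            raise SimulationConfigError(
                "n_marker_genes_per_state * n_states exceeds n_genes"
            )
        for tp in self.timepoint_proportions:
            if tp not in self.timepoint_index:
                raise SimulationConfigError(f"timepoint {tp!r} missing from timepoint_index")


@dataclass(frozen=True)
class GermlineRecord:
    """One germline heavy V segment with its designated high-affinity codon."""

    name: str
    nt: str
    aa: str
    affinity_position: int  # 1-based residue index
    affinity_from: str
    affinity_to: str

    def __post_init__(self) -> None:
        if len(self.nt) % 3 != 0:
            raise ValueError(f"{self.name}: nt length {len(self.nt)} not divisible by 3")
        if str(Seq(self.nt).translate()) != self.aa:
            raise ValueError(f"{self.name}: aa is not the translation of nt")
        if self.aa[self.affinity_position - 1] != self.affinity_from:
            raise ValueError(
                f"{self.name}: germline residue at {self.affinity_position} is "
                f"{self.aa[self.affinity_position - 1]}, expected {self.affinity_from}"
            )


@dataclass
class GermlineSet:
    """A germline V-segment reference (nucleotide + translated amino acid)."""

    records: list[GermlineRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("germline set is empty")
        self._by_name = {r.name: r for r in self.records}

    def __getitem__(self, name: str) -> GermlineRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    f">{r.name} affinity_position={r.affinity_position} "
                    f"from={r.affinity_from} to={r.affinity_to}\n{r.nt}\n"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GermlineSet":
        records: list[GermlineRecord] = []
        name, desc, seq_parts = None, {}, []

        def flush() -> None:
            if name is None:
                return
            nt = "".join(seq_parts)
            records.append(
                GermlineRecord(
                    name=name,
                    nt=nt,
                    aa=str(Seq(nt).translate()),
                    affinity_position=int(desc.get("affinity_position", 1)),
                    affinity_from=desc.get("from", str(Seq(nt).translate())[0]),
                    affinity_to=desc.get("to", "L"),
                )
            )

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    header = line[1:].split()
                    name = header[0]
                    desc = dict(kv.split("=", 1) for kv in header[1:] if "=" in kv)
                    seq_parts = []
                else:
                    seq_parts.append(line)
            flush()
        return cls(records)


def default_germline_set(
    gene_names: tuple[str, ...] | list[str] | None = None,
    seed: int = 7,
    n_codons: int = 98,
    affinity_position: int = 33,
) -> GermlineSet:
    """Build a synthetic germline V reference.

    Each gene is a random in-frame sequence of sense codons with tryptophan
    fixed at ``affinity_position`` so that the designated high-affinity
    substitution (W -> L, the W33L analogue) is well defined.
    """
    if gene_names is None:
        gene_names = tuple(_default_ighv_usage())
    records = []
    for i, name in enumerate(gene_names):
        rng = np.random.default_rng([seed, i])
        codons = list(rng.choice(_SENSE_CODONS, size=n_codons))
        codons[affinity_position - 1] = "TGG"
        nt = "".join(codons)
        records.append(
            GermlineRecord(
                name=name,
                nt=nt,
                aa=str(Seq(nt).translate()),
                affinity_position=affinity_position,
                affinity_from="W",
                affinity_to="L",
            )
        )
    return GermlineSet(records)


_CONTIG_COLUMNS = [
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

_LIGHT_V_POOL = [f"IGKV{i}-{j}*01" for i in (1, 3, 4, 6, 8) for j in (110, 117, 125)] + [
    f"IGLV{i}*01" for i in (1, 2, 3)
]
_IGHD_POOL = [f"IGHD{i}-{j}*01" for i in (1, 2, 3, 4) for j in (1, 2)]
_IGHJ_POOL = [f"IGHJ{i}*01" for i in (1, 2, 3, 4)]
_IGKJ_POOL = [f"IGKJ{i}*01" for i in (1, 2, 4, 5)]
_IGLJ_POOL = [f"IGLJ{i}*01" for i in (1, 2, 3)]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_repertoire(
    config: SimConfig, germline: GermlineSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a single-cell BCR repertoire with recorded ground truth.

    Returns ``(contigs, truth)``: one contig row per sequenced chain (each cell
    has one heavy and at least one light chain; a fraction gains a second,
    nonproductive decoy light chain) and one truth row per barcode.

    Clone sizes follow a shuffled power-law weight sequence (highly uneven, as
    immune repertoires are), scaled up for PC-state clones whose progeny expand
    after fate specification. All cells of a clone share heavy V/D/J calls,
    the heavy CDR3 amino-acid sequence, and light V/J calls. Somatic
    substitution counts are Poisson(rate x timepoint index), placed uniformly
    at random over the V segment but never on the affinity codon, which is
    rewritten to encode the high-affinity residue only in flagged lineages.
    """
    config.validate()
    for gene in config.ighv_usage:
        if gene not in germline:
            raise SimulationConfigError(f"ighv_usage gene {gene!r} missing from germline set")

    rng = np.random.default_rng(config.seed)
    states = list(config.state_proportions)
    state_p = np.asarray(list(config.state_proportions.values()), dtype=float)
    pc_states = list(config.pc_states)
    b_states = [
        s for s in states if s not in pc_states and s != config.progenitor_state
    ]
    bm_frac = config.compartment_proportions.get("bone_marrow", 0.0)
    w_diag = config.bm_diagonal_weight
    n_other_pc = max(len(pc_states) - 1, 1)
    p_diag = w_diag / (w_diag + n_other_pc) if len(pc_states) > 1 else 1.0

    tp_labels = list(config.timepoint_proportions)
    tp_p = np.asarray(list(config.timepoint_proportions.values()), dtype=float)

    # --- clone-level draws -------------------------------------------------
    n_clones, n_cells = config.n_clones, config.n_cells
    primary_state = rng.choice(states, size=n_clones, p=state_p)
    base_w = np.arange(1, n_clones + 1, dtype=float) ** (-config.clone_size_exponent)
    rng.shuffle(base_w)
    factor = np.asarray(
        [config.clone_size_state_factor.get(s, 1.0) for s in primary_state], dtype=float
    )
    weights = base_w * factor
    weights /= weights.sum()
    sizes = rng.multinomial(n_cells - n_clones, weights) + 1

    ighv_genes = list(config.ighv_usage)
    ighv_w = np.asarray(list(config.ighv_usage.values()), dtype=float)
    ighv_w = ighv_w / ighv_w.sum()
    np_set = set(config.np_ighv_genes)
    klh_set = set(config.klh_ighv_genes)

    clones = []
    for k in range(n_clones):
        heavy_v = str(rng.choice(ighv_genes, p=ighv_w))
        lo, hi = config.cdr3_length_range
        cdr3_len = int(rng.integers(lo, hi + 1))
        cdr3_aa = "C" + "".join(rng.choice(list(_AA_ALPHABET), size=cdr3_len - 2)) + "W"
        cdr3_nt = "".join(rng.choice(list("ACGT"), size=3 * cdr3_len))
        light_locus = "IGK" if rng.random() < 0.7 else "IGL"
        light_pool = [v for v in _LIGHT_V_POOL if v.startswith(light_locus)]
        clones.append(
            {
                "clone_id": k,
                "primary_state": primary_state[k],
                "heavy_v": heavy_v,
                "heavy_d": str(rng.choice(_IGHD_POOL)),
                "heavy_j": str(rng.choice(_IGHJ_POOL)),
                "cdr3_aa": cdr3_aa,
                "cdr3_nt": cdr3_nt,
                "light_locus": light_locus,
                "light_v": str(rng.choice(light_pool)),
                "light_j": str(
                    rng.choice(_IGKJ_POOL if light_locus == "IGK" else _IGLJ_POOL)
                ),
                "light_cdr3_aa": "C"
                + "".join(rng.choice(list(_AA_ALPHABET), size=7))
                + "W",
                "affinity": bool(rng.random() < config.affinity_mutation_prob),
                # clone-level BM destination: progeny in the marrow
                # predominantly retain the splenic precursor state
                "bm_state": None,
                "specificity": (
                    "NP" if heavy_v in np_set else "KLH" if heavy_v in klh_set else "other"
                ),
            }
        )

    for clone in clones:
        primary = clone["primary_state"]
        if primary in pc_states:
            if len(pc_states) > 1 and rng.random() >= p_diag:
                others = [s for s in pc_states if s != primary]
                clone["bm_state"] = str(rng.choice(others))
            else:
                clone["bm_state"] = primary
        # splenic spread is clone-level: each B/GC clone has at most one
        # secondary state. PC-state clones are splenically coherent (their
        # cross-state heterogeneity lives in the BM destination draw above)
        # and progenitor lineages stay put.
        if primary in pc_states or primary == config.progenitor_state:
            pool = []
        else:
            pool = [s for s in b_states if s != primary]
        clone["secondary_state"] = str(rng.choice(pool)) if pool else primary

    # --- cell-level emission ----------------------------------------------
    contig_rows: list[dict] = []
    truth_rows: list[dict] = []
    cell_idx = 0
    for clone, size in zip(clones, sizes):
        germ = germline[clone["heavy_v"]]
        germ_nt = germ.nt
        L = len(germ_nt)
        prot_start = 3 * (germ.affinity_position - 1)
        protected = {prot_start, prot_start + 1, prot_start + 2}
        mutable = np.asarray([i for i in range(L) if i not in protected])
        is_pc_clone = clone["primary_state"] in pc_states

        for _ in range(size):
            barcode = f"CB{cell_idx:06d}-1"
            cell_idx += 1
            timepoint = str(rng.choice(tp_labels, p=tp_p))
            tp_index = config.timepoint_index[timepoint]

            # compartment + state: only PC-state clones seed the bone marrow,
            # and a clone's BM progeny share its clone-level destination state.
            p_bm = (
                min(bm_frac * config.bm_seeding_rate.get(clone["primary_state"], 1.0), 0.95)
                if is_pc_clone
                else 0.0
            )
            if is_pc_clone and rng.random() < p_bm:
                compartment = "bone_marrow"
                state = clone["bm_state"]
            else:
                compartment = "spleen"
                if rng.random() >= config.state_spread:
                    state = clone["primary_state"]
                else:
                    state = clone["secondary_state"]

            # somatic hypermutation on the heavy V segment
            k_mut = int(rng.poisson(config.mutation_rate_per_timepoint * tp_index))
            k_mut = min(k_mut, len(mutable))
            seq = list(germ_nt)
            if k_mut:
                for pos in rng.choice(mutable, size=k_mut, replace=False):
                    alternatives = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = str(rng.choice(alternatives))
            if clone["affinity"]:
                seq[prot_start : prot_start + 3] = list(_LEU_CODON)
            observed = "".join(seq)
            n_mut = _hamming(observed, germ_nt)

            heavy_umi = int(1 + rng.poisson(30))
            contig_rows.append(
                {
                    "barcode": barcode,
                    "locus": "IGH",
                    "v_call": clone["heavy_v"],
                    "d_call": clone["heavy_d"],
                    "j_call": clone["heavy_j"],
                    "cdr3_aa": clone["cdr3_aa"],
                    "cdr3_nt": clone["cdr3_nt"],
                    "productive": True,
                    "umi_count": heavy_umi,
                    "v_sequence_nt": observed,
                    "germline_v_nt": germ_nt,
                }
            )
            contig_rows.append(
                {
                    "barcode": barcode,
                    "locus": clone["light_locus"],
                    "v_call": clone["light_v"],
                    "d_call": "",
                    "j_call": clone["light_j"],
                    "cdr3_aa": clone["light_cdr3_aa"],
                    "cdr3_nt": "",
                    "productive": True,
                    "umi_count": int(1 + rng.poisson(20)),
                    "v_sequence_nt": "",
                    "germline_v_nt": "",
                }
            )
            if rng.random() < config.decoy_light_prob:
                decoy_pool = [v for v in _LIGHT_V_POOL if v != clone["light_v"]]
                contig_rows.append(
                    {
                        "barcode": barcode,
                        "locus": str(rng.choice(["IGK", "IGL"])),
                        "v_call": str(rng.choice(decoy_pool)),
                        "d_call": "",
                        "j_call": str(rng.choice(_IGKJ_POOL)),
                        "cdr3_aa": "C" + "".join(rng.choice(list(_AA_ALPHABET), size=6)) + "W",
                        "cdr3_nt": "",
                        "productive": False,
                        "umi_count": int(1 + rng.poisson(3)),
                        "v_sequence_nt": "",
                        "germline_v_nt": "",
                    }
                )
            truth_rows.append(
                {
                    "barcode": barcode,
                    "clone_id": clone["clone_id"],
                    "specificity": clone["specificity"],
                    "state": state,
                    "compartment": compartment,
                    "timepoint": timepoint,
                    "n_v_mutations": n_mut,
                    "has_affinity_mutation": bool(clone["affinity"]),
                }
            )

    contigs = pd.DataFrame(contig_rows, columns=_CONTIG_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return contigs, truth


def simulate_expression(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[AnnData, dict[str, list[str]]]:
    """Simulate a cell x gene count matrix with state-specific marker blocks.

    Counts follow a gamma-Poisson (negative binomial) model, or a pure Poisson
    when ``config.expression_model == "poisson"``. Each state owns a disjoint
    block of ``n_marker_genes_per_state`` marker genes whose expected expression
    is elevated ``marker_fold``-fold in cells of that state. Rows are ordered
    exactly as ``truth.barcode``; deterministic for a fixed seed.
    """
    if truth.empty:
        raise SimulationConfigError("truth table is empty")
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    states = list(config.state_proportions)
    m = config.n_marker_genes_per_state
    genes = [f"Gene{i:05d}" for i in range(config.n_genes)]
    marker_map = {s: genes[i * m : (i + 1) * m] for i, s in enumerate(states)}

    profile_rng = np.random.default_rng([config.expression_profile_seed, config.n_genes])
    base = profile_rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    base /= base.sum()

    n = len(truth)
    lib = rng.gamma(shape=5.0, scale=config.library_size_mean / 5.0, size=n)
    X = np.zeros((n, config.n_genes), dtype=np.int64)
    cell_states = truth["state"].to_numpy()

    for i, s in enumerate(states):
        idx = np.flatnonzero(cell_states == s)
        if idx.size == 0:
            continue
        profile = base.copy()
        lo, hi = i * m, (i + 1) * m
        profile[lo:hi] *= config.marker_fold
        profile /= profile.sum()
        mean = lib[idx, None] * profile[None, :]
        if config.expression_model == "nb":
            phi = config.nb_dispersion
            lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
            X[idx] = rng.poisson(lam)
        else:
            X[idx] = rng.poisson(mean)

    adata = AnnData(
        X=sp.csr_matrix(X, dtype=np.int64),
        obs=pd.DataFrame(index=pd.Index(truth["barcode"], name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs["state"] = cell_states
    return adata, marker_map


def simulate_specificity_cohort(
    seed: int = 0,
    n_cells_reference: int = 600,
    n_cells_sample: int = 1500,
    germline: GermlineSet | None = None,
) -> dict[str, tuple[SimConfig, pd.DataFrame, pd.DataFrame]]:
    """Simulate the three-sample design behind specificity inference.

    * ``reference`` -- the antigen-sorted NP-specific compartment at the peak
      of the GC response (14 d.p.i.); its IGHV usage is restricted to the NP
      genes, emulating tetramer/antigen sorting.
    * ``sample_21`` / ``sample_35`` -- the CD138+ compartments tracked at 21
      and 35 d.p.i., drawing from the full IGHV usage.

    Returns ``name -> (config, contigs, truth)``.
    """
    if germline is None:
        germline = default_germline_set()
    base = SimConfig(seed=seed)
    np_usage = {g: w for g, w in base.ighv_usage.items() if g in base.np_ighv_genes}

    cohort: dict[str, tuple[SimConfig, pd.DataFrame, pd.DataFrame]] = {}
    specs = {
        "reference": SimConfig(
            n_cells=n_cells_reference,
            n_clones=max(n_cells_reference // 12, 1),
            ighv_usage=np_usage,
            timepoint_proportions={"14": 1.0},
            timepoint_index={"14": 1, "21": 1, "35": 2},
            seed=seed,
        ),
        "sample_21": SimConfig(
            n_cells=n_cells_sample,
            n_clones=max(n_cells_sample // 12, 1),
            timepoint_proportions={"21": 1.0},
            seed=seed + 1,
        ),
        "sample_35": SimConfig(
            n_cells=n_cells_sample,
            n_clones=max(n_cells_sample // 12, 1),
            timepoint_proportions={"35": 1.0},
            seed=seed + 2,
        ),
    }
    for name, cfg in specs.items():
        contigs, truth = simulate_repertoire(cfg, germline)
        cohort[name] = (cfg, contigs, truth)
    return cohort


def simulate_deg_groups(
    n_cells_per_group: int = 100,
    n_genes: int = 2000,
    n_planted: int = 20,
    fold: float = 2.0,
    seed: int = 0,
    library_size: float = 2000.0,
    nb_dispersion: float = 0.1,
    planted_mean_range: tuple[float, float] = (5.0, 50.0),
) -> tuple[AnnData, AnnData, list[str]]:
    """Two cell groups from one negative-binomial model with planted fold changes.

    ``n_planted`` genes receive a ``fold``-fold elevation, planted in balanced
    fashion (half elevated in group A, half in group B) so that per-cell
    total-count normalization is not compositionally distorted by the planted
    set itself; with ``n_planted=0`` the two groups are exchangeable draws from
    the same null. Planted genes are sampled among genes whose baseline
    expected count lies in ``planted_mean_range``: a fold change on a
    never-expressed gene is not a meaningful benchmark, and planting into the
    most abundant genes would turn the benchmark into a test of normalization
    rather than of the statistic.
    """
    rng = np.random.default_rng(seed)
    genes = [f"Gene{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    base = base / base.sum() * library_size

    lo, hi = planted_mean_range
    eligible = np.flatnonzero((base >= lo) & (base <= hi))
    if n_planted > eligible.size:
        raise SimulationConfigError(
            f"only {eligible.size} genes have baseline mean in {planted_mean_range}"
        )
    planted_idx = (
        np.sort(rng.choice(eligible, size=n_planted, replace=False)) if n_planted else np.array([], int)
    )
    mean_a = base.copy()
    mean_b = base.copy()
    up_in_a = planted_idx[: n_planted // 2]
    up_in_b = planted_idx[n_planted // 2 :]
    mean_a[up_in_a] *= fold
    mean_b[up_in_b] *= fold

    def draw(mean: np.ndarray) -> np.ndarray:
        lam = rng.gamma(
            shape=1.0 / nb_dispersion,
            scale=mean * nb_dispersion,
            size=(n_cells_per_group, n_genes),
        )
        return rng.poisson(lam)

    def to_adata(X: np.ndarray, prefix: str) -> AnnData:
        return AnnData(
            X=sp.csr_matrix(X.astype(np.int64)),
            obs=pd.DataFrame(
                index=pd.Index([f"{prefix}{i:05d}" for i in range(n_cells_per_group)], name="barcode")
            ),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )

    A = to_adata(draw(mean_a), "A")
    B = to_adata(draw(mean_b), "B")
    return A, B, [genes[i] for i in planted_idx]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    contigs: pd.DataFrame,
    adata: AnnData,
    truth: pd.DataFrame,
    germline: GermlineSet,
    out_dir: str | Path,
) -> dict:
    """Write one simulation run to disk in the field's standard formats.

    Emits exactly seven files -- the 10x-dialect contig CSV, an AIRR
    Rearrangement TSV, the MatrixMarket triplet, the germline nt FASTA (amino
    acids are recovered by translation) and the truth TSV -- plus a
    ``manifest.json`` listing their SHA-256 checksums.
    """
    from . import io as _io  # local import: io depends on nothing here

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths = {
        "tenx_csv": out / "filtered_contig_annotations.csv",
        "airr_tsv": out / "airr_rearrangement.tsv",
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "germline": out / "germline_v.fasta",
        "truth": out / "truth.tsv",
    }

    _io.write_contigs_tenx(contigs, paths["tenx_csv"])
    _io.write_contigs_airr(contigs, paths["airr_tsv"])

    # CellRanger orientation: genes x cells, canonically sorted triplets.
    mat = sp.coo_matrix(adata.X.T.astype(np.int64))
    order = np.lexsort((mat.row, mat.col))
    mat = sp.coo_matrix(
        (mat.data[order], (mat.row[order], mat.col[order])), shape=mat.shape
    )
    sio.mmwrite(str(paths["matrix"]), mat, field="integer")
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], index=False, header=False)
    pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    ).to_csv(paths["features"], sep="\t", index=False, header=False)

    germline.to_fasta(paths["germline"])
    truth.to_csv(paths["truth"], sep="\t", index=False)

    manifest = {
        "files": {name: p.name for name, p in paths.items()},
        "checksums": {p.name: _sha256(p) for p in paths.values()},
        "n_cells": int(len(truth)),
        "n_genes": int(adata.n_vars),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
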