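"""Genomic-state label transfer, signature scoring, and group comparisons.

Reference cluster labels are transferred to query cells by Pearson correlation
against per-state centroids of log2-scaled marker-gene expression, with a
minimum correlation of 0.7 below which a cell stays unassigned. The module
also implements an expression-matched-background gene signature score, the
subtraction-based decomposition of sorted-subset state frequencies, a
moderated-t differential expression test with a fold filter, and the Pearson
chi-square test of state-frequency differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import log_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "StateReference",
    "SignatureSpec",
    "DEGConfig",
    "build_centroids",
    "classify_cells",
    "signature_score",
    "subset_frequency_decomposition",
    "differential_expression",
    "state_frequency_test",
]


@dataclass
class StateReference:
    """Per-state centroids over marker genes, on the log2 scale."""

    marker_genes: list[str]
    centroids: pd.DataFrame  # states x marker_genes
    min_correlation: float = 0.7
    norm_target: float | None = None  # None: per-dataset median library


@dataclass
class SignatureSpec:
    """A gene signature with its background-matching parameters."""

    name: str
    genes: list[str]
    n_background_bins: int = 25
    background_size_per_gene: int = 50
    seed: int = 0


@dataclass
class DEGConfig:
    """Thresholds of the differential-expression filter."""

    fold_threshold: float = 1.2  # absolute fold, linear scale
    alpha: float = 0.05
    correction: str = "fdr_bh"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def build_centroids(
    reference: AnnData,
    labels: pd.Series,
    marker_genes: list[str],
    min_correlation: float = 0.7,
    norm_target: float | None = None,
) -> StateReference:
    """Average log2-normalized marker expression per reference state.

    Each state needs at least 2 cells. ``norm_target`` scales each cell's
    counts to a common library size before the log2 transform; the default
    (per-dataset median library) follows common single-cell practice, while an
    explicit fixed target makes centroids exactly invariant to uniform
    library-size scaling.
    """
    missing = [g for g in marker_genes if g not in reference.var_names]
    if missing:
        raise ValueError(f"marker genes absent from reference matrix: {missing[:5]}")
    lab = pd.Series(labels).reindex(reference.obs_names)
    logX = log_normalize(reference, target=norm_target)
    gene_idx = [reference.var_names.get_loc(g) for g in marker_genes]
    logX = logX[:, gene_idx]
    rows = {}
    for state, grp in pd.Series(lab).groupby(lab, sort=True):
        idx = [reference.obs_names.get_loc(b) for b in grp.index]
        if len(idx) < 2:
            raise ValueError(f"state {state!r} has fewer than 2 reference cells")
        rows[state] = logX[idx].mean(axis=0)
    centroids = pd.DataFrame.from_dict(rows, orient="index", columns=marker_genes)
    return StateReference(
        marker_genes=list(marker_genes),
        centroids=centroids,
        min_correlation=min_correlation,
        norm_target=norm_target,
    )


def classify_cells(query: AnnData, reference: StateReference) -> pd.DataFrame:
    """Assign each query cell the state of its best-correlated centroid.

    Pearson r is computed on the log2-scaled marker vector; a cell whose best
    r falls below ``reference.min_correlation`` (low-quality alignment) is
    unassigned, as is a zero-variance cell. Centroid ties break by state name.
    Returns a barcode-indexed frame with columns ``label`` and ``best_r``.
    """
    missing = [g for g in reference.marker_genes if g not in query.var_names]
    if missing:
        logger.warning("classify_cells: %d marker genes absent, imputed as 0", len(missing))
    logX_all = log_normalize(query, target=reference.norm_target)
    X = np.zeros((query.n_obs, len(reference.marker_genes)))
    for j, g in enumerate(reference.marker_genes):
        if g in query.var_names:
            X[:, j] = logX_all[:, query.var_names.get_loc(g)]

    C = reference.centroids.to_numpy(dtype=float)
    state_names = list(reference.centroids.index)  # sorted at build time

    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(Xc, axis=1)
    c_norm = np.linalg.norm(Cc, axis=1)
    zero_var = x_norm == 0
    x_norm_safe = np.where(zero_var, 1.0, x_norm)
    R = (Xc @ Cc.T) / (x_norm_safe[:, None] * c_norm[None, :])

    best_idx = R.argmax(axis=1)  # argmax keeps the first (name-sorted) state on ties
    best_r = R[np.arange(len(R)), best_idx]
    labels = np.asarray(state_names, dtype=object)[best_idx]
    unassigned = zero_var | (best_r < reference.min_correlation)
    labels[unassigned] = "unassigned"
    best_r = np.where(zero_var, np.nan, best_r)
    return pd.DataFrame({"label": labels, "best_r": best_r}, index=query.obs_names)


def signature_score(adata: AnnData, spec: SignatureSpec) -> pd.Series:
    """Expression-matched-background signature score per cell.

    Genes are binned by dataset-wide mean log-normalized expression into
    ``n_background_bins`` bins; for every signature gene,
    ``background_size_per_gene`` genes are drawn (seeded) from its bin. The
    score is the mean signature expression minus the mean background
    expression, controlling for library quality/complexity. Used
    comparatively (contrasts between cell groups), not as an absolute value.
    """
    genes = [g for g in spec.genes if g in adata.var_names]
    dropped = len(spec.genes) - len(genes)
    if dropped:
        logger.warning("signature_score(%s): %d genes absent, dropped", spec.name, dropped)
    if not genes:
        raise ValueError(f"no signature genes of {spec.name!r} present in the matrix")

    logX = log_normalize(adata)
    gene_means = logX.mean(axis=0)
    bins = pd.qcut(gene_means, q=spec.n_background_bins, labels=False, duplicates="drop")
    rng = np.random.default_rng(spec.seed)

    sig_idx = np.asarray([adata.var_names.get_loc(g) for g in genes])
    background: list[int] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[pool != gi]
        if pool.size == 0:
            continue
        take = min(spec.background_size_per_gene, pool.size)
        background.extend(rng.choice(pool, size=take, replace=False))
    bg_idx = np.asarray(sorted(set(background)))
    score = logX[:, sig_idx].mean(axis=1) - logX[:, bg_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=spec.name)


def subset_frequency_decomposition(
    f_mixed, f_pure, alpha: float = 1.0
):
    """Correct a mixed sorted subset's state fractions for contamination.

    ``corrected_i = max(f_mixed_i - alpha * f_pure_i, 0)``, renormalized to sum
    to 1. ``alpha=1`` is the literal subtraction of the contaminating (pure)
    subset's cluster proportions, clipped at zero; ``alpha<1`` models partial
    contamination. On exact mixtures ``f_mixed = (1-a) f_target + a f_pure``
    the target composition is recovered exactly for any ``a < 1``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    fm = pd.Series(f_mixed, dtype=float)
    fp = pd.Series(f_pure, dtype=float).reindex(fm.index)
    if fp.isna().any():
        raise ValueError("f_mixed and f_pure must cover the same states")
    for name, v in (("f_mixed", fm), ("f_pure", fp)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} sums to {v.sum()}, expected 1")
    corrected = (fm - alpha * fp).clip(lower=0.0)
    total = corrected.sum()
    if total == 0:
        raise ValueError("degenerate decomposition: all corrected fractions are 0")
    return corrected / total


def _estimate_prior_df(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for variance shrinkage.

    Under the hierarchical model, s2 ~ s0^2 * F(d, d0); the squared coefficient
    of variation of s2 across genes identifies d0 through the F moments.
    """
    s2 = s2[s2 > 0]
    m1 = float(np.mean(s2))
    if len(s2) < 3 or m1 == 0:
        return np.inf, m1
    cv2 = float(np.var(s2, ddof=1)) / m1**2
    limit = 2.0 / d  # cv2 of F(d, d0) as d0 -> inf

    def g(d0: float) -> float:
        mean_f = d0 / (d0 - 2.0)
        var_f = 2.0 * d0**2 * (d + d0 - 2.0) / (d * (d0 - 2.0) ** 2 * (d0 - 4.0))
        return var_f / mean_f**2 - cv2

    if cv2 <= limit * 1.001:
        return np.inf, m1
    lo, hi = 4.001, 1e8
    if g(lo) < 0:  # heavier-tailed than any admissible d0 > 4: weak prior floor
        return lo, m1 * (lo - 2.0) / lo
    d0 = optimize.brentq(g, lo, hi)
    s0_2 = m1 * (d0 - 2.0) / d0
    return d0, s0_2


def differential_expression(
    matrix_a: AnnData, matrix_b: AnnData, config: DEGConfig | None = None, shrink: bool = True
) -> pd.DataFrame:
    """Moderated two-sample t-test per gene with a linear-scale fold filter.

    Fold is the ratio of group means on the linear normalized scale (absolute
    fold = max(fold, 1/fold)); the t statistic is computed on log2-normalized
    values with per-gene variances shrunk toward a common prior variance via a
    method-of-moments prior-df estimate (``shrink=False`` gives the ordinary
    pooled two-sample t). P-values are Benjamini-Hochberg adjusted; a gene is a
    DEG iff absolute fold > ``fold_threshold`` and adjusted p < ``alpha``.
    """
    if config is None:
        config = DEGConfig()
    if matrix_a.n_obs < 3 or matrix_b.n_obs < 3:
        raise ValueError("each group needs at least 3 cells")
    if list(matrix_a.var_names) != list(matrix_b.var_names):
        raise ValueError("groups must share an identical gene axis")

    import scipy.sparse as sp

    def dense(ad: AnnData) -> np.ndarray:
        X = ad.X
        return np.asarray(X.todense(), dtype=float) if sp.issparse(X) else np.asarray(X, dtype=float)

    Xa_raw, Xb_raw = dense(matrix_a), dense(matrix_b)
    lib = np.concatenate([Xa_raw.sum(axis=1), Xb_raw.sum(axis=1)])
    lib[lib == 0] = 1.0
    target = float(np.median(lib))

    def norm(X: np.ndarray) -> np.ndarray:
        l = X.sum(axis=1)
        l[l == 0] = 1.0
        return X / l[:, None] * target

    Na, Nb = norm(Xa_raw), norm(Xb_raw)
    mean_a, mean_b = Na.mean(axis=0), Nb.mean(axis=0)
    eps = 1e-9
    fold = (mean_a + eps) / (mean_b + eps)
    abs_fold = np.maximum(fold, 1.0 / fold)

    La, Lb = np.log2(1.0 + Na), np.log2(1.0 + Nb)
    n1, n2 = La.shape[0], Lb.shape[0]
    d = n1 + n2 - 2
    m1, m2 = La.mean(axis=0), Lb.mean(axis=0)
    ss = La.var(axis=0, ddof=1) * (n1 - 1) + Lb.var(axis=0, ddof=1) * (n2 - 1)
    s2 = ss / d

    if shrink:
        d0, s0_2 = _estimate_prior_df(s2, d)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = d0 + d
    else:
        s2_tilde = s2
        df_total = d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    if np.isinf(df_total):
        raw_p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        raw_p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj_p = multipletests(raw_p, method=config.correction)[1]

    out = pd.DataFrame(
        {
            "gene": list(matrix_a.var_names),
            "fold": fold,
            "abs_fold": abs_fold,
            "t": t,
            "raw_p": raw_p,
            "adj_p": adj_p,
        }
    )
    out["is_deg"] = (out["abs_fold"] > config.fold_threshold) & (out["adj_p"] < config.alpha)
    return out


def state_frequency_test(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-square test of state-frequency differences (df = k - 1).

    ``counts_a`` / ``counts_b`` are per-state cell counts over the same state
    set; states with zero total count are dropped with a warning, reducing df.
    """
    ca = pd.Series(counts_a, dtype=float)
    cb = pd.Series(counts_b, dtype=float).reindex(ca.index)
    if cb.isna().any():
        raise ValueError("count vectors must cover the same states")
    totals = ca + cb
    if (totals == 0).any():
        dropped = list(totals.index[totals == 0])
        logger.warning("state_frequency_test: dropping zero-count states %s", dropped)
        ca, cb = ca[totals > 0], cb[totals > 0]
    if len(ca) < 2:
        raise ValueError("need at least 2 states with nonzero counts")
    table = np.vstack([ca.to_numpy(), cb.to_numpy()])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
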