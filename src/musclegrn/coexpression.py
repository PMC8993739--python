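"""Weighted gene co-expression network analysis, implemented from scratch.

The pipeline follows the classical WGCNA recipe: exclude outlying samples by
standardised sample connectivity, pick a soft-thresholding power by the
approximate scale-free topology criterion, raise |Pearson correlation| to
that power to obtain an adjacency, transform it into the topological overlap
matrix (TOM), cluster genes by average-linkage hierarchical clustering on
1 - TOM with a static tree cut, summarise each module by its eigengene
(first principal component of the standardised module submatrix) and merge
modules whose eigengenes are highly correlated.

The network is unsigned (|cor|^beta) by default; pass ``signed=True`` to
:func:`adjacency` to use ((1 + cor)/2)^beta instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .io import ExpressionMatrix

__all__ = [
    "CoexpressionParams",
    "detect_sample_outliers",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigengenes",
    "merge_modules",
    "detect_modules",
]


@dataclass
class CoexpressionParams:
    """Tunable parameters of the co-expression pipeline.

    ``beta`` is the soft-thresholding power; leave ``None`` to have
    :func:`pick_soft_threshold` choose the smallest candidate power whose
    signed scale-free fit R^2 reaches ``target_r2``.
    """

    candidate_powers: Sequence[int] = tuple(range(1, 21))
    target_r2: float = 0.8
    beta: int | None = None
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    n_bins: int = 10
    cut_height_frac: float = 0.99
    min_mean_connectivity: float = 1.0

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0 < self.merge_cut_height < 1):
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def _gene_correlation(matrix: ExpressionMatrix) -> np.ndarray:
    x = matrix.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    # relative tolerance so a constant row is caught despite mean round-off
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(x).max(axis=1))
    if const.any():
        bad = matrix.gene_ids[int(np.flatnonzero(const)[0])]
        raise ValueError(f"constant gene {bad!r}; run good_samples_genes first")
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0)


# ---------------------------------------------------------------------------
# sample outliers
# ---------------------------------------------------------------------------

def detect_sample_outliers(matrix: ExpressionMatrix, z_cut: float = -2.5
                           ) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose standardised connectivity falls below ``z_cut``.

    A sample's connectivity is the sum of its Pearson correlations (over
    genes) to every other sample; connectivities are z-scored and samples
    with z < z_cut are removed in a single pass.
    """
    if matrix.shape[1] < 4:
        raise ValueError("need >= 4 samples for outlier detection")
    x = matrix.values.to_numpy(dtype=float)
    c = np.corrcoef(x.T)
    conn = c.sum(axis=1) - 1.0  # exclude self-correlation
    sd = conn.std(ddof=0)
    z = np.zeros_like(conn) if sd == 0 else (conn - conn.mean()) / sd
    excluded = [s for s, zi in zip(matrix.sample_ids, z) if zi < z_cut]
    kept = matrix.values.drop(columns=excluded)
    return matrix.with_values(kept), excluded


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed scale-free fit index of a connectivity vector.

    Connectivities are discretised into ``n_bins`` equal-width bins;
    log10(bin frequency) is regressed on log10(mean bin connectivity) and
    the R^2 is signed by the negated slope sign, so topologies where
    frequency rises with connectivity (the opposite of scale-free) score
    negatively.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k.max(), k.min()):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        dk.append(mean_k)
        freq.append(mask.sum() / k.size)
    if len(dk) < 3:
        return 0.0
    fit = linregress(np.log10(dk), np.log10(freq))
    return float(-np.sign(fit.slope) * fit.rvalue ** 2)


def pick_soft_threshold(matrix: ExpressionMatrix, params: CoexpressionParams | None = None
                        ) -> tuple[int, pd.DataFrame, bool]:
    """Choose the soft-thresholding power by the scale-free topology criterion.

    Returns ``(beta, fit_table, reached)`` where the table lists, per
    candidate power, the signed R^2 of the scale-free fit and the mean
    connectivity.  ``beta`` is the smallest power whose signed R^2 reaches
    ``params.target_r2`` while keeping mean connectivity at or above
    ``params.min_mean_connectivity`` (a power that leaves the network
    essentially empty can mimic a power law spuriously); if none qualifies,
    the power with maximal signed R^2 is returned with ``reached=False``.
    """
    params = params or CoexpressionParams()
    if matrix.shape[0] < 10:
        raise ValueError("need >= 10 genes to assess scale-free topology")
    c = np.abs(_gene_correlation(matrix))
    rows = []
    for p in params.candidate_powers:
        a = c ** p
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"power": int(p), "signed_r2": _scale_free_fit(k, params.n_bins),
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    qualifying = table.loc[(table["signed_r2"] >= params.target_r2) &
                           (table["mean_connectivity"] >= params.min_mean_connectivity),
                           "power"]
    if len(qualifying):
        return int(qualifying.iloc[0]), table, True
    best = int(table.loc[table["signed_r2"].idxmax(), "power"])
    return best, table, False


# ---------------------------------------------------------------------------
# adjacency and TOM
# ---------------------------------------------------------------------------

def adjacency(matrix: ExpressionMatrix, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency: |cor|^beta (unsigned) with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = _gene_correlation(matrix)
    a = ((1.0 + c) / 2.0) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=matrix.gene_ids, columns=matrix.gene_ids)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j where
    l_ij = sum_u a_iu a_uj and k_i is node connectivity; TOM_ii = 1.
    Shared-neighbour strength damps spurious one-off correlations.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _relabel_by_size(labels: pd.Series, min_module_size: int) -> pd.Series:
    """Drop undersized clusters to label 0 and relabel 1..M by decreasing size.

    Ties in size are broken by the lowest gene index in the cluster, so the
    labelling is deterministic.
    """
    out = pd.Series(0, index=labels.index, dtype=int)
    sizes = labels.value_counts()
    order = []
    for lab, size in sizes.items():
        if lab == 0 or size < min_module_size:
            continue
        first_idx = int(np.flatnonzero(labels.to_numpy() == lab)[0])
        order.append((-size, first_idx, lab))
    for new, (_, _, lab) in enumerate(sorted(order), start=1):
        out[labels == lab] = new
    return out


def cluster_modules(tom: pd.DataFrame, params: CoexpressionParams | None = None
                    ) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    The tree is cut at ``cut_height_frac`` (default 0.99) of the maximum
    merge height; clusters smaller than ``min_module_size`` are labelled 0
    (unassigned) and surviving modules are labelled 1..M in decreasing size
    order.  Returns the labels and the scipy linkage matrix.
    """
    params = params or CoexpressionParams()
    genes = list(tom.index)
    n = len(genes)
    if n < params.min_module_size:
        warnings.warn(f"only {n} genes (< min_module_size); all genes unassigned")
        return pd.Series(0, index=genes, dtype=int), np.empty((0, 4))
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrise away float noise
    z = linkage(squareform(d, checks=False), method="average")
    cut = params.cut_height_frac * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")
    labels = _relabel_by_size(pd.Series(raw, index=genes), params.min_module_size)
    return labels, z


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def module_eigengenes(matrix: ExpressionMatrix, assignment: pd.Series
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes: first principal component of each module.

    Genes are standardised across samples; the eigengene of a module is the
    leading right singular vector of its standardised submatrix, unit-norm
    over samples, with its sign oriented so the correlation with the
    module's mean standardised profile is non-negative.  Also returns the
    fraction of module variance each eigengene explains.
    """
    x = matrix.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    modules = sorted(m for m in assignment.unique() if m != 0)
    eig_rows, var_expl = [], []
    for m in modules:
        idx = np.flatnonzero(assignment.reindex(matrix.gene_ids).to_numpy() == m)
        if len(idx) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        if (sd[idx] == 0).any():
            bad = matrix.gene_ids[int(idx[np.flatnonzero(sd[idx] == 0)[0]])]
            raise ValueError(f"zero-variance gene {bad!r} in module {m}")
        sub = (x[idx] - x[idx].mean(axis=1, keepdims=True)) / sd[idx, None]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        eig = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        eig_rows.append(eig)
        var_expl.append(s[0] ** 2 / (s ** 2).sum())
    eig_df = pd.DataFrame(eig_rows, index=modules, columns=matrix.sample_ids)
    return eig_df, pd.Series(var_expl, index=modules, name="variance_explained")


# ---------------------------------------------------------------------------
# module merging
# ---------------------------------------------------------------------------

def merge_modules(matrix: ExpressionMatrix, assignment: pd.Series,
                  merge_cut_height: float = 0.25) -> pd.Series:
    """Merge modules whose eigengenes are nearly collinear.

    Iteratively merges the pair with the smallest eigengene dissimilarity
    1 - cor while that dissimilarity is below ``merge_cut_height``,
    recomputing eigengenes after every merge.  On exit all surviving
    pairwise eigengene correlations are <= 1 - merge_cut_height, and a
    second invocation is a no-op.
    """
    labels = assignment.copy()
    while True:
        modules = sorted(m for m in labels.unique() if m != 0)
        if len(modules) < 2:
            break
        eig, _ = module_eigengenes(matrix, labels)
        c = np.corrcoef(eig.to_numpy())
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if 1.0 - c[i, j] >= merge_cut_height:
            break
        keep, absorb = sorted((modules[i], modules[j]))
        labels[labels == absorb] = keep
    # renumber 1..M by decreasing size for a canonical labelling
    return _relabel_by_size(labels.where(labels != 0, 0), 2)


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def detect_modules(matrix: ExpressionMatrix, params: CoexpressionParams | None = None
                   ) -> tuple[pd.Series, dict]:
    """Full module-detection pipeline on a clean expression matrix.

    Soft-threshold selection (unless ``params.beta`` is set), adjacency,
    TOM, static-cut clustering and eigengene merging.  Returns the final
    labels and a diagnostics dict (chosen beta, fit table, pre-merge labels).
    """
    params = params or CoexpressionParams()
    if params.beta is not None:
        beta, fit_table, reached = params.beta, None, True
    else:
        beta, fit_table, reached = pick_soft_threshold(matrix, params)
    adj = adjacency(matrix, beta)
    tom = tom_similarity(adj)
    labels, z = cluster_modules(tom, params)
    merged = labels
    if (labels != 0).any():
        merged = merge_modules(matrix, labels, params.merge_cut_height)
    info = {"beta": beta, "scale_free_reached": reached, "fit_table": fit_table,
            "pre_merge_labels": labels, "linkage": z}
    return merged, info
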