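"""Single-cell preprocessing: cell calling, QC, normalization, imputation,
marker partitioning and rank-sum marker tests.

Matrices are dense pandas DataFrames with genes as rows (index) and cell
barcodes as columns, the orientation of a Drop-seq digital-gene-expression
table.  Stages mirror a droplet scRNA-seq workflow:

1. :func:`call_cells` — knee-point selection of real cells on the barcode
   rank curve; barcodes past the knee are ambient-RNA background.
2. :func:`qc_filter` — threshold filters on genes-per-cell, mitochondrial
   fraction and per-gene cell support.
3. :func:`normalize_log` — median-library-size scaling and log1p.
4. :func:`impute` — k-NN Markov diffusion smoothing of the expression graph
   (t diffusion steps of a row-stochastic transition built from the k-NN
   affinity), applied before thresholding marker expression.
5. :func:`partition_by_marker_pair` — splits cells on the midpoint of each
   marker's imputed expression range, e.g. SCARA5-enriched/DIO2-reduced
   versus DIO2-enriched/SCARA5-reduced stromal cells.
6. :func:`wilcoxon_markers` — two-sided rank-sum tests per gene with
   Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QcThresholds",
    "ImputeConfig",
    "KneeCellCaller",
    "QCFilter",
    "LogNormalizer",
    "KNNDiffusionImputer",
    "MarkerPairPartitioner",
    "call_cells",
    "qc_filter",
    "normalize_log",
    "impute",
    "partition_by_marker_pair",
    "wilcoxon_markers",
]


# ---------------------------------------------------------------------------
# knee-point cell calling
# ---------------------------------------------------------------------------

class KneeCellCaller(BaseEstimator):
    """Selects real-cell barcodes at the knee of the barcode rank curve.

    Barcodes are ordered by descending read count and the cumulative read
    fraction is plotted against barcode rank; the knee is the point of
    maximum perpendicular distance between that curve and the chord joining
    its endpoints.  Barcodes past the knee are treated as ambient RNA.

    Parameters
    ----------
    curvature_tol : float, default 1e-3
        If the maximum distance is below this fraction of the chord length
        the curve is deemed knee-less (e.g. all counts equal); all barcodes
        are then returned and ``no_knee_`` is set.

    Attributes
    ----------
    knee_index_ : int         0-based rank of the knee barcode
    n_cells_ : int            number of selected barcodes
    selected_barcodes_ : list
    no_knee_ : bool
    """

    def __init__(self, curvature_tol: float = 1e-3):
        self.curvature_tol = curvature_tol

    def fit(self, read_counts: pd.Series, y=None) -> "KneeCellCaller":
        reads = pd.Series(read_counts).astype(float)
        reads = reads[reads > 0]
        if len(reads) < 10:
            raise ValueError(
                f"need >= 10 barcodes with positive counts, got {len(reads)}")
        # stable deterministic order: descending count, barcode id as tiebreak
        order = reads.sort_values(ascending=False, kind="mergesort")
        order = order.iloc[np.lexsort((order.index, -order.to_numpy()))]
        y_cum = np.cumsum(order.to_numpy()) / order.sum()
        x = np.arange(1, len(order) + 1, dtype=float) / len(order)

        p0 = np.array([x[0], y_cum[0]])
        p1 = np.array([x[-1], y_cum[-1]])
        chord = p1 - p0
        chord_len = float(np.hypot(*chord))
        # perpendicular distance of each point from the chord
        d = np.abs(chord[0] * (p0[1] - y_cum) - chord[1] * (p0[0] - x)) / chord_len

        self.ranked_barcodes_ = list(order.index)
        if d.max() < self.curvature_tol * chord_len:
            self.no_knee_ = True
            self.knee_index_ = len(order) - 1
        else:
            self.no_knee_ = False
            self.knee_index_ = int(np.argmax(d))
        self.selected_barcodes_ = self.ranked_barcodes_[: self.knee_index_ + 1]
        self.n_cells_ = len(self.selected_barcodes_)
        return self


def call_cells(read_counts: pd.Series,
               curvature_tol: float = 1e-3) -> tuple[list, bool]:
    """Knee-point cell calling; returns ``(selected_barcodes, no_knee_flag)``."""
    caller = KneeCellCaller(curvature_tol=curvature_tol).fit(read_counts)
    return caller.selected_barcodes_, caller.no_knee_


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds (defaults: 200/4500 genes, 3 cells, 5% mito)."""

    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 4500
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


class QCFilter(BaseEstimator, TransformerMixin):
    """Threshold QC on a genes x cells count matrix.

    Filter order is fixed: (1) drop cells whose detected-gene count is
    outside ``[min_genes, max_genes]``, (2) drop cells whose mitochondrial
    read fraction exceeds ``max_mito``, (3) drop genes detected in fewer
    than ``min_cells`` *surviving* cells.  Cells keeping exactly
    ``max_genes`` genes or exactly ``max_mito`` mito fraction survive
    ("more than" is exclusive in both printed rules).

    Mitochondrial genes are recognized by identifier prefix
    (case-insensitive; default ``MT-``).

    Attributes (after ``transform``)
    --------------------------------
    report_ : dict with counts removed per rule.
    """

    def __init__(self, min_genes: int = 200, max_genes: int = 4500,
                 min_cells: int = 3, max_mito: float = 0.05,
                 mito_prefixes: tuple = ("MT-",)):
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.min_cells = min_cells
        self.max_mito = max_mito
        self.mito_prefixes = mito_prefixes

    def fit(self, X: pd.DataFrame, y=None) -> "QCFilter":
        QcThresholds(self.min_genes, self.max_genes, self.min_cells,
                     self.max_mito)  # validates
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        counts = X.to_numpy()
        if (counts < 0).any():
            raise ValueError("count matrix must be non-negative")
        detected = (counts > 0).sum(axis=0)
        keep_cells = (detected >= self.min_genes) & (detected <= self.max_genes)
        n_gene_bound = int((~keep_cells).sum())

        prefixes = tuple(p.upper() for p in self.mito_prefixes)
        is_mito = np.array([str(g).upper().startswith(prefixes)
                            for g in X.index])
        totals = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0,
                                 counts[is_mito].sum(axis=0) / totals, 0.0)
        mito_fail = keep_cells & (mito_frac > self.max_mito)
        n_mito = int(mito_fail.sum())
        keep_cells &= ~mito_fail

        surviving = X.loc[:, keep_cells]
        support = (surviving.to_numpy() > 0).sum(axis=1)
        keep_genes = support >= self.min_cells
        n_gene_support = int((~keep_genes).sum())

        out = surviving.loc[keep_genes]
        self.report_ = {
            "cells_removed_gene_bounds": n_gene_bound,
            "cells_removed_mito": n_mito,
            "genes_removed_support": n_gene_support,
            "cells_kept": out.shape[1],
            "genes_kept": out.shape[0],
        }
        if out.size == 0:
            warnings.warn("QC filtering removed everything", stacklevel=2)
        return out


def qc_filter(m: pd.DataFrame, t: QcThresholds = QcThresholds(),
              mito_prefixes: tuple = ("MT-",)) -> tuple[pd.DataFrame, dict]:
    """Apply QC thresholds; returns ``(filtered_matrix, removal_report)``."""
    f = QCFilter(t.min_genes_per_cell, t.max_genes_per_cell,
                 t.min_cells_per_gene, t.max_mito_fraction, mito_prefixes)
    out = f.transform(m)
    return out, f.report_


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class LogNormalizer(BaseEstimator, TransformerMixin):
    """Median-library-size scaling followed by log(1 + x).

    Each cell's counts are rescaled so its library size equals the median
    library size of the matrix, then log1p-transformed.  Proportional cells
    therefore map to identical profiles.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "LogNormalizer":
        lib = X.sum(axis=0)
        zero = lib[lib == 0]
        if len(zero):
            raise ValueError(
                f"all-zero cell(s): {list(zero.index[:5])}")
        self.target_library_size_ = float(np.median(lib.to_numpy()))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        lib = X.sum(axis=0)
        if (lib == 0).any():
            raise ValueError(
                f"all-zero cell(s): {list(lib.index[lib == 0][:5])}")
        scaled = X * (self.target_library_size_ / lib)
        return np.log1p(scaled)


def normalize_log(m: pd.DataFrame) -> pd.DataFrame:
    """Scale every cell to the median library size, then log1p."""
    return LogNormalizer().fit(m).transform(m)


# ---------------------------------------------------------------------------
# k-NN Markov diffusion imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImputeConfig:
    """k-NN diffusion imputation settings (k neighbours, t diffusion steps)."""

    k_neighbors: int = 15
    diffusion_steps: int = 3
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.diffusion_steps < 0:
            raise ValueError("diffusion_steps must be >= 0")


class KNNDiffusionImputer(BaseEstimator, TransformerMixin):
    """Graph-diffusion smoothing of expression across similar cells.

    A symmetric k-NN affinity over cells (union of directed k-NN edges plus
    self loops) is row-normalized into a Markov transition matrix ``T``;
    expression is then diffused ``t`` steps: ``X <- X @ (T.T)**t``.  ``t=0``
    is the identity and constant genes are fixed points for any ``t``.
    """

    def __init__(self, k_neighbors: int = 15, diffusion_steps: int = 3,
                 metric: str = "euclidean"):
        self.k_neighbors = k_neighbors
        self.diffusion_steps = diffusion_steps
        self.metric = metric

    def fit(self, X: pd.DataFrame, y=None) -> "KNNDiffusionImputer":
        ImputeConfig(self.k_neighbors, self.diffusion_steps, self.metric)
        n_cells = X.shape[1]
        if self.k_neighbors >= n_cells:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} must be < n_cells={n_cells}")
        cells = X.to_numpy().T  # cells x genes
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1,
                              metric=self.metric).fit(cells)
        idx = nn.kneighbors(cells, return_distance=False)
        A = np.zeros((n_cells, n_cells))
        rows = np.repeat(np.arange(n_cells), idx.shape[1])
        A[rows, idx.ravel()] = 1.0
        np.fill_diagonal(A, 1.0)
        A = np.maximum(A, A.T)  # symmetrize (union of edges)
        self.transition_ = A / A.sum(axis=1, keepdims=True)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.to_numpy(dtype=float)
        Tt = self.transition_.T
        for _ in range(self.diffusion_steps):
            out = out @ Tt
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def impute(m: pd.DataFrame, c: ImputeConfig = ImputeConfig()) -> pd.DataFrame:
    """k-NN Markov diffusion imputation of a normalized genes x cells matrix."""
    imp = KNNDiffusionImputer(c.k_neighbors, c.diffusion_steps, c.distance)
    return imp.fit(m).transform(m)


# ---------------------------------------------------------------------------
# marker-pair partitioning
# ---------------------------------------------------------------------------

class MarkerPairPartitioner(BaseEstimator):
    """Splits cells on the midpoint of two markers' imputed expression ranges.

    A cell is ``a_enriched_b_reduced`` when it lies strictly above gene A's
    range midpoint and strictly below gene B's; the mirror class swaps the
    roles; everything else is ``intermediate``.
    """

    def __init__(self, gene_a: str, gene_b: str):
        self.gene_a = gene_a
        self.gene_b = gene_b

    def fit(self, X: pd.DataFrame, y=None) -> "MarkerPairPartitioner":
        for gene in (self.gene_a, self.gene_b):
            if gene not in X.index:
                raise KeyError(f"gene {gene!r} not in matrix")
            vals = X.loc[gene]
            if float(vals.max()) == float(vals.min()):
                raise ValueError(
                    f"gene {gene!r} has zero expression range; midpoint undefined")
        self.midpoints_ = {
            g: (float(X.loc[g].max()) + float(X.loc[g].min())) / 2.0
            for g in (self.gene_a, self.gene_b)}
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        a = X.loc[self.gene_a].to_numpy(float)
        b = X.loc[self.gene_b].to_numpy(float)
        ma, mb = self.midpoints_[self.gene_a], self.midpoints_[self.gene_b]
        labels = np.full(X.shape[1], "intermediate", dtype=object)
        labels[(a > ma) & (b < mb)] = "a_enriched_b_reduced"
        labels[(b > mb) & (a < ma)] = "b_enriched_a_reduced"
        return pd.Series(labels, index=X.columns, name="partition")


def partition_by_marker_pair(m: pd.DataFrame, gene_a: str,
                             gene_b: str) -> pd.Series:
    """Label cells by midpoint thresholds on two (imputed) marker genes."""
    return MarkerPairPartitioner(gene_a, gene_b).fit(m).predict(m)


# ---------------------------------------------------------------------------
# rank-sum marker tests
# ---------------------------------------------------------------------------

def _ranksum_p(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, float]:
    """Two-sided Mann-Whitney U and p-value.

    ``method='exact'`` uses full-null enumeration (tie-free data only);
    the asymptotic path is a tie-corrected normal approximation *without*
    continuity correction, so identical groups give p = 1 exactly.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return u1, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (not has_ties and max(n1, n2) <= 25) else "asymptotic"
    if method == "exact":
        return u1, float(stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact").pvalue)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u1 - mu) / np.sqrt(sigma2)
    return u1, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_markers(m: pd.DataFrame, group_a, group_b,
                     alpha: float = 0.05, method: str = "auto") -> pd.DataFrame:
    """Two-sided rank-sum marker test per gene with Bonferroni correction.

    ``group_a`` / ``group_b`` are disjoint barcode collections (each with at
    least 3 cells).  Returns a per-gene DataFrame with the U statistic, raw
    and Bonferroni-adjusted p-values, a significance flag at adjusted
    p <= alpha, the direction of change and the log2 fold change of group
    means (pseudocount 1e-9).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need >= 3 cells")

    A = m[group_a].to_numpy(float)
    B = m[group_b].to_numpy(float)
    n_genes = m.shape[0]
    rows = []
    for g in range(n_genes):
        u, p = _ranksum_p(A[g], B[g], method)
        mean_a, mean_b = A[g].mean(), B[g].mean()
        # fold change is only meaningful for non-negative expression values
        lfc = (float(np.log2((mean_a + 1e-9) / (mean_b + 1e-9)))
               if mean_a >= 0 and mean_b >= 0 else float("nan"))
        rows.append({
            "statistic": u,
            "p_value": p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": lfc,
            "direction": "up_in_a" if u > len(group_a) * len(group_b) / 2
                         else ("down_in_a" if u < len(group_a) * len(group_b) / 2
                               else "none"),
        })
    out = pd.DataFrame(rows, index=m.index)
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * n_genes)
    out["significant"] = out["p_adjusted"] <= alpha
    return out
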