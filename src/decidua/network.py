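"""Co-expression modules, the gene-pair congruency statistic, and the
marker-candidate filter.

``CorrelationKMeans`` clusters gene expression profiles with a Pearson
correlation metric (equivalently, spherical k-means on row-standardized
profiles), the cluster count being guided by a leave-one-condition-out
figure of merit (FOM).  ``pairwise_congruency`` quantifies conservation of
gene-pair co-regulation between two single-cell datasets (e.g. an in vitro
decidualization time course and in vivo biopsies): for each unordered gene
pair the Pearson coefficients from the two datasets are summed, giving a
score in [-2, +2]; a pair is *congruent* when the sum exceeds +1 (conserved
positive co-regulation) or falls below -1 (conserved negative
co-regulation).  Enrichment of congruent pairs over chance is assessed by
permuting gene identities in the second dataset (default) or by an
explicitly parameterized hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .preprocess import wilcoxon_markers

__all__ = [
    "NetworkConfig",
    "MarkerCriteria",
    "CorrelationKMeans",
    "fom_curve",
    "kmeans_modules",
    "pairwise_congruency",
    "congruency_enrichment",
    "select_candidate_markers",
    "rank_branch_genes",
]

FLAT_MODULE = -1  # label for constant-profile genes (correlation undefined)


@dataclass(frozen=True)
class NetworkConfig:
    """k-means / FOM settings (defaults: k in 1..20, 50 Lloyd iterations)."""

    k_range: tuple[int, int] = (1, 20)
    metric: str = "pearson"
    max_iterations: int = 50
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError(f"invalid k_range {self.k_range}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.metric != "pearson":
            raise ValueError("only the Pearson correlation metric is supported")


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; returns (unit_rows, flat_mask).

    On unit rows the correlation distance 1 - r(x, y) equals
    1 - <u_x, u_y>, so Lloyd iterations on the sphere minimize the
    within-module sum of correlation distances.
    """
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms < 1e-12
    safe = np.where(flat, 1.0, norms)
    return centered / safe[:, None], flat


class CorrelationKMeans(BaseEstimator):
    """k-means over gene profiles with distance = 1 - Pearson correlation.

    Implemented as spherical k-means on row-standardized profiles: the
    centroid update (normalized member mean) and max-correlation assignment
    both monotonically decrease the within-module correlation-distance sum.
    Constant-profile genes, whose correlation is undefined, are assigned the
    reserved ``flat`` module (-1) and excluded from the objective.

    Parameters
    ----------
    n_clusters : int
    max_iter : int, default 50
    n_restarts : int, default 5
        Best restart by objective kept; deterministic given random_state.
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray of int, -1 for flat genes
    inertia_ : float, sum of (1 - r) over clustered genes
    objective_path_ : list of float, per-iteration objective of the winning
        restart (non-increasing)
    """

    def __init__(self, n_clusters: int, max_iter: int = 50,
                 n_restarts: int = 5, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _normalize(C: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(C, axis=1, keepdims=True)
        return C / np.where(norms < 1e-12, 1.0, norms)

    @staticmethod
    def _plusplus_init(U: np.ndarray, k: int,
                       rng: np.random.Generator) -> np.ndarray:
        """k-means++-style seeding with correlation distance."""
        n = U.shape[0]
        centroids = np.empty((k, U.shape[1]))
        centroids[0] = U[rng.integers(n)]
        d = 1.0 - U @ centroids[0]
        for c in range(1, k):
            w = np.clip(d, 0.0, None)
            if w.sum() <= 0:
                centroids[c] = U[rng.integers(n)]
                continue
            centroids[c] = U[rng.choice(n, p=w / w.sum())]
            d = np.minimum(d, 1.0 - U @ centroids[c])
        return centroids

    def _single_run(self, U: np.ndarray, k: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, float, list[float]]:
        n = U.shape[0]
        centroids = self._plusplus_init(U, k, rng)
        labels = np.full(n, -2)
        path: list[float] = []
        for _ in range(self.max_iter):
            sim = U @ centroids.T
            new_labels = np.argmax(sim, axis=1)
            # refill empty clusters with the worst-fitting gene (this can
            # only lower that gene's distance, preserving monotonicity)
            for c in range(k):
                if not np.any(new_labels == c):
                    worst = int(np.argmin(sim[np.arange(n), new_labels]))
                    centroids[c] = U[worst]
                    new_labels[worst] = c
            obj = float(np.sum(1.0 - (U * centroids[new_labels]).sum(axis=1)))
            path.append(obj)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = U[labels == c]
                if len(members):
                    centroids[c] = members.mean(axis=0)
            centroids = self._normalize(centroids)
        self._final_centroids = centroids
        return labels, path[-1], path

    def fit(self, X, y=None) -> "CorrelationKMeans":
        X = pd.DataFrame(X)
        vals = X.to_numpy(dtype=float)
        n = vals.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        U, flat = _standardize_rows(vals)
        active = np.where(~flat)[0]
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} constant-profile gene(s) assigned to the "
                "flat module", stacklevel=2)
        labels = np.full(n, FLAT_MODULE, dtype=int)
        if len(active) == 0:
            self.labels_, self.inertia_, self.objective_path_ = labels, 0.0, []
        else:
            k = min(self.n_clusters, len(active))
            self.n_clusters_effective_ = k
            ss = np.random.SeedSequence(self.random_state)
            best = None
            for child in ss.spawn(self.n_restarts):
                rng = np.random.default_rng(child)
                run = self._single_run(U[active], k, rng)
                if best is None or run[1] < best[1]:
                    best = run
                    centers = self._final_centroids
            labels[active] = best[0]
            self.labels_ = labels
            self.inertia_ = best[1]
            self.objective_path_ = best[2]
            self.cluster_centers_ = centers
        self.flat_genes_ = list(X.index[flat])
        self.genes_ = list(X.index)
        return self

    def module_series(self) -> pd.Series:
        return pd.Series(self.labels_, index=self.genes_, name="module")


def kmeans_modules(p: pd.DataFrame, k: int,
                   c: NetworkConfig = NetworkConfig()) -> pd.Series:
    """Gene -> module assignment by correlation-metric k-means (flat = -1)."""
    km = CorrelationKMeans(n_clusters=k, max_iter=c.max_iterations,
                           n_restarts=c.n_restarts, random_state=c.seed)
    return km.fit(p).module_series()


def fom_curve(p: pd.DataFrame, c: NetworkConfig = NetworkConfig()
              ) -> tuple[pd.DataFrame, int]:
    """Leave-one-condition-out figure of merit over a k range.

    For each k and each left-out condition, genes are clustered on the
    remaining conditions and the FOM is the root-mean-square deviation of
    the left-out condition's values from their cluster means.  Per-k values
    are aggregated over all folds and divided by sqrt((n - k) / n) (the
    standard cluster-count correction), then the suggested k is the elbow:
    the interior k with the largest second difference of the curve.

    Returns ``(curve, suggested_k)`` where ``curve`` has columns ``k`` and
    ``fom``.
    """
    n_genes, n_cond = p.shape
    if n_cond < 3:
        raise ValueError("need >= 3 conditions for leave-one-out FOM")
    vals = p.to_numpy(dtype=float)
    ks = []
    for k in range(c.k_range[0], c.k_range[1] + 1):
        if k > n_genes - 1:
            warnings.warn(f"k={k} capped: exceeds n_genes-1={n_genes - 1}",
                          stacklevel=2)
            break
        ks.append(k)

    ss = np.random.SeedSequence(c.seed)
    foms = []
    for k in ks:
        agg = 0.0
        for left_out in range(n_cond):
            keep = [j for j in range(n_cond) if j != left_out]
            seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            km = CorrelationKMeans(
                n_clusters=k, max_iter=c.max_iterations,
                n_restarts=c.n_restarts, random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels = km.fit(p.iloc[:, keep]).labels_
            dev2 = 0.0
            col = vals[:, left_out]
            for lab in np.unique(labels):
                members = col[labels == lab]
                dev2 += float(((members - members.mean()) ** 2).sum())
            agg += np.sqrt(dev2 / n_genes)
        adj = np.sqrt((n_genes - k) / n_genes)
        foms.append(agg / n_cond / adj)

    curve = pd.DataFrame({"k": ks, "fom": foms})
    if len(ks) >= 3:
        second_diff = np.diff(foms, 2)  # indexed by interior ks[1..-2]
        suggested = int(curve["k"].iloc[1 + int(np.argmax(second_diff))])
    else:
        suggested = int(curve["k"].iloc[int(np.argmin(foms))])
    return curve, suggested


# ---------------------------------------------------------------------------
# gene-pair congruency
# ---------------------------------------------------------------------------

def _gene_correlations(dataset: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """Pearson correlation matrix of the named gene columns (cells x genes)."""
    missing = [g for g in genes if g not in dataset.columns]
    if missing:
        raise KeyError(f"genes missing from dataset: {missing[:10]}")
    X = dataset[genes].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 observations per dataset")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, np.where(sd == 0, np.nan, 1.0))
    return R


def pairwise_congruency(top_genes, dataset_a: pd.DataFrame,
                        dataset_b: pd.DataFrame,
                        threshold: float = 1.0
                        ) -> tuple[pd.DataFrame, dict]:
    """Sum-of-correlations congruency score for every unordered gene pair.

    ``dataset_a`` and ``dataset_b`` are cells x genes expression matrices
    (imputed).  For each pair (g, h): ``sum = r_a(g,h) + r_b(g,h)`` with
    ``sum`` in [-2, 2]; the pair is congruent when ``|sum| > threshold``.
    Self-pairs are reported (sum exactly 2) but flagged, and pairs involving
    a zero-variance gene are undefined and excluded; both are tallied in the
    report.

    Returns ``(scores, report)``.
    """
    genes = list(top_genes)
    Ra = _gene_correlations(dataset_a, genes)
    Rb = _gene_correlations(dataset_b, genes)
    rows = []
    n_undefined = 0
    for i, g in enumerate(genes):
        for j in range(i, len(genes)):
            h = genes[j]
            ra, rb = Ra[i, j], Rb[i, j]
            self_pair = i == j
            defined = bool(np.isfinite(ra) and np.isfinite(rb))
            s = ra + rb if defined else np.nan
            if not defined and not self_pair:
                n_undefined += 1
            rows.append({
                "gene_a": g, "gene_b": h,
                "r_a": ra, "r_b": rb, "sum": s,
                "congruent": bool(defined and abs(s) > threshold),
                "self_pair": self_pair, "defined": defined,
            })
    scores = pd.DataFrame(rows)
    evaluable = scores[~scores["self_pair"] & scores["defined"]]
    report = {
        "n_genes": len(genes),
        "n_pairs": len(evaluable),
        "n_undefined_pairs": n_undefined,
        "zero_variance_genes": [g for g, bad in
                                zip(genes, ~np.isfinite(np.diag(Ra))
                                    | ~np.isfinite(np.diag(Rb))) if bad],
        "congruent_fraction": (float(evaluable["congruent"].mean())
                               if len(evaluable) else np.nan),
    }
    return scores, report


def congruency_enrichment(top_genes, dataset_a: pd.DataFrame,
                          dataset_b: pd.DataFrame,
                          null: str = "permutation",
                          n_perm: int = 999, seed: int = 0,
                          threshold: float = 1.0,
                          hypergeom_params: dict | None = None) -> dict:
    """Is the congruent-pair fraction larger than expected by chance?

    Permutation null (default): gene identities of ``dataset_b`` are
    shuffled ``n_perm`` times (equivalently, its correlation matrix is
    symmetrically permuted), the congruent fraction recomputed each time,
    and ``p = (1 + #{null >= observed}) / (1 + n_perm)``.

    Hypergeometric variant: requires explicit urn parameters
    ``{"population": N, "successes": K, "draws": n}``; the upper-tail
    probability of the observed congruent count is returned.  The urn
    parameterization is an interpretation and must be supplied by the
    caller.
    """
    genes = list(top_genes)
    Ra = _gene_correlations(dataset_a, genes)
    Rb = _gene_correlations(dataset_b, genes)
    iu = np.triu_indices(len(genes), k=1)

    def _fraction(Rb_perm: np.ndarray) -> tuple[float, int, int]:
        s = (Ra + Rb_perm)[iu]
        ok = np.isfinite(s)
        n_pairs = int(ok.sum())
        n_congruent = int((np.abs(s[ok]) > threshold).sum())
        return (n_congruent / n_pairs if n_pairs else np.nan,
                n_congruent, n_pairs)

    observed, n_congruent, n_pairs = _fraction(Rb)
    if n_pairs < 10:
        raise ValueError(f"need >= 10 defined pairs, got {n_pairs}")
    out = {"observed_fraction": observed, "n_congruent": n_congruent,
           "n_pairs": n_pairs, "null": null}

    if null == "permutation":
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; p-value resolution is "
                          f"{1 / (1 + n_perm):.3f}", stacklevel=2)
        rng = np.random.default_rng(seed)
        null_fracs = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(len(genes))
            null_fracs[b] = _fraction(Rb[np.ix_(perm, perm)])[0]
        out["null_fractions"] = null_fracs
        out["null_mean"] = float(np.nanmean(null_fracs))
        out["p_value"] = float(
            (1 + np.sum(null_fracs >= observed)) / (1 + n_perm))
    elif null == "hypergeometric":
        if not hypergeom_params:
            raise ValueError(
                "hypergeometric null requires explicit urn parameters "
                "{'population': N, 'successes': K, 'draws': n}")
        N = hypergeom_params["population"]
        K = hypergeom_params["successes"]
        n = hypergeom_params["draws"]
        out["p_value"] = float(stats.hypergeom.sf(n_congruent - 1, N, K, n))
        out["params"] = dict(hypergeom_params)
    else:
        raise ValueError(f"unknown null {null!r}")
    return out


# ---------------------------------------------------------------------------
# marker-candidate selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerCriteria:
    """Filters a candidate marker must pass.

    A marker of diverging decidual states should be (1) enriched in stromal
    cells versus every other endometrial cell type, (2) essentially
    unregulated in glandular epithelium across the luteal phase, and
    (3) show the expected direction of late-luteal change in stroma.
    """

    stromal_enrichment_min_lfc: float = 1.0     # log2 fold change
    stromal_enrichment_alpha: float = 0.05      # Bonferroni-adjusted p bound
    epithelial_regulation_max_fc: float = 1.5   # linear max/min fold change
    temporal_profile_rule: str = "increase"     # increase | decrease | any

    def __post_init__(self) -> None:
        if self.stromal_enrichment_min_lfc <= 0 \
                or self.epithelial_regulation_max_fc <= 0:
            raise ValueError("bounds must be positive")
        if self.temporal_profile_rule not in ("increase", "decrease", "any"):
            raise ValueError(
                f"unknown temporal_profile_rule {self.temporal_profile_rule!r}")


def select_candidate_markers(branch_genes, celltype_expression: dict,
                             epithelial_timecourse: pd.DataFrame,
                             stromal_timecourse: pd.DataFrame,
                             crit: MarkerCriteria = MarkerCriteria(),
                             stromal_key: str = "EnSC"
                             ) -> tuple[list[str], pd.DataFrame]:
    """Sequential marker filters with a per-gene audit.

    ``celltype_expression`` maps cell-type name -> genes x cells matrix (the
    stromal entry is ``stromal_key``); the time courses are genes x
    condition matrices of positive expression values.

    Filter 1 keeps genes significantly enriched (rank-sum, Bonferroni) in
    stroma versus *every* other cell type with log2 fold change >= the
    bound; filter 2 keeps genes whose epithelial max/min temporal fold
    change stays <= the bound; filter 3 keeps genes whose stromal profile
    changes in the required direction (last vs first condition).

    Returns ``(survivors, audit)``: survivors ranked by their weakest
    stromal log2 fold change (descending); audit records per gene the filter
    that removed it (or ``passed``).
    """
    genes = list(branch_genes)
    if not genes:
        return [], pd.DataFrame(columns=["gene", "removed_by", "min_stromal_lfc"])
    if stromal_key not in celltype_expression:
        raise KeyError(f"celltype_expression lacks stromal key {stromal_key!r}")
    for name, mat in celltype_expression.items():
        missing = set(genes) - set(mat.index)
        if missing:
            raise KeyError(f"{name}: missing genes {sorted(missing)[:10]}")
    for name, tc in (("epithelial_timecourse", epithelial_timecourse),
                     ("stromal_timecourse", stromal_timecourse)):
        missing = set(genes) - set(tc.index)
        if missing:
            raise KeyError(f"{name}: missing genes {sorted(missing)[:10]}")

    stromal = celltype_expression[stromal_key]
    min_lfc = pd.Series(np.inf, index=genes)
    enriched = pd.Series(True, index=genes)
    for name, other in celltype_expression.items():
        if name == stromal_key:
            continue
        combined = pd.concat(
            [stromal.loc[genes], other.loc[genes]], axis=1)
        res = wilcoxon_markers(combined, list(stromal.columns),
                               list(other.columns),
                               alpha=crit.stromal_enrichment_alpha)
        ok = res["significant"] & (res["log2_fc"]
                                   >= crit.stromal_enrichment_min_lfc)
        enriched &= ok.reindex(genes)
        min_lfc = np.minimum(min_lfc, res["log2_fc"].reindex(genes))

    epi = epithelial_timecourse.loc[genes].to_numpy(float)
    eps = 1e-9
    epi_fc = (epi.max(axis=1) + eps) / (epi.min(axis=1) + eps)
    unregulated = pd.Series(epi_fc <= crit.epithelial_regulation_max_fc,
                            index=genes)

    st = stromal_timecourse.loc[genes].to_numpy(float)
    delta = st[:, -1] - st[:, 0]
    if crit.temporal_profile_rule == "increase":
        temporal = pd.Series(delta > 0, index=genes)
    elif crit.temporal_profile_rule == "decrease":
        temporal = pd.Series(delta < 0, index=genes)
    else:
        temporal = pd.Series(True, index=genes)

    removed_by = []
    for g in genes:
        if not enriched[g]:
            removed_by.append("stromal_enrichment")
        elif not unregulated[g]:
            removed_by.append("epithelial_regulation")
        elif not temporal[g]:
            removed_by.append("temporal_profile")
        else:
            removed_by.append("passed")
    audit = pd.DataFrame({"gene": genes, "removed_by": removed_by,
                          "min_stromal_lfc": min_lfc.to_numpy()})
    survivors = audit[audit["removed_by"] == "passed"].sort_values(
        "min_stromal_lfc", ascending=False)["gene"].tolist()
    return survivors, audit


def rank_branch_genes(counts: pd.DataFrame, states: pd.Series,
                      n_top: int = 50, state_a: str = "DC",
                      state_b: str = "snDC") -> list[str]:
    """Convenience branch-gene ranking for synthetic data.

    Orders genes by the absolute difference of their mean expression between
    the two branch states (the trajectory-model ranking itself is an input
    elsewhere, not reproduced here).
    """
    a = counts.loc[:, states[states == state_a].index].mean(axis=1)
    b = counts.loc[:, states[states == state_b].index].mean(axis=1)
    return list((a - b).abs().sort_values(ascending=False).index[:n_top])
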