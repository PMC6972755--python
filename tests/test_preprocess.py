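"""Cell calling, QC, normalization, diffusion imputation, marker tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from decidua.preprocess import (
    ImputeConfig,
    KNNDiffusionImputer,
    QcThresholds,
    call_cells,
    impute,
    normalize_log,
    partition_by_marker_pair,
    qc_filter,
    wilcoxon_markers,
)
from decidua.simulate import (
    BarcodeSimConfig,
    ScSimConfig,
    generate_barcode_reads,
    generate_timecourse_matrix,
)


class TestCallCells:
    def test_planted_real_cells_recovered(self):
        reads, real = generate_barcode_reads(
            BarcodeSimConfig(n_real=100, n_ambient=900, real_read_mean=1000,
                             ambient_read_mean=10, seed=21))
        selected, no_knee = call_cells(reads)
        assert not no_knee
        assert 90 <= len(selected) <= 110
        assert len(set(selected) & real) / len(real) > 0.9

    def test_equal_counts_no_knee(self):
        reads = pd.Series(100, index=[f"B{i}" for i in range(50)])
        selected, no_knee = call_cells(reads)
        assert no_knee and len(selected) == 50

    def test_ambient_free_input(self):
        """A single population with no ambient background has no knee; the
        caller flags it and returns every barcode."""
        reads, _ = generate_barcode_reads(
            BarcodeSimConfig(n_real=200, n_ambient=0, real_read_sigma=5e-4,
                             seed=3))
        selected, no_knee = call_cells(reads)
        assert no_knee and len(selected) == 200

    def test_too_few_barcodes_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            call_cells(pd.Series([5, 4, 3], index=list("abc")))


def qc_oracle(matrix, min_genes, max_genes, min_cells, max_mito, mito_mask):
    """Literal re-statement of the QC rules, applied by brute force."""
    counts = matrix.to_numpy()
    detected = (counts > 0).sum(axis=0)
    keep = (detected >= min_genes) & (detected <= max_genes)
    tot = counts.sum(axis=0)
    frac = np.where(tot > 0, counts[mito_mask].sum(axis=0) / tot, 0)
    keep = keep & ~(frac > max_mito)
    surv = counts[:, keep]
    keep_genes = (surv > 0).sum(axis=1) >= min_cells
    return int(keep_genes.sum()), int(keep.sum())


class TestQcFilter:
    @staticmethod
    def _fixture():
        """5000 genes x 8 cells with one violator of each printed rule."""
        rng = np.random.default_rng(42)
        genes = [f"G{i:04d}" for i in range(4990)] + \
                [f"MT-{i}" for i in range(10)]
        cells = ["low", "high", "mito"] + [f"ok{i}" for i in range(5)]
        m = pd.DataFrame(0, index=genes, columns=cells, dtype=np.int64)
        for cell, n_detected in [("low", 150), ("high", 4600), ("mito", 300),
                                 *[(f"ok{i}", 300) for i in range(5)]]:
            picked = rng.choice(4990, size=n_detected, replace=False)
            m.iloc[picked, m.columns.get_loc(cell)] = rng.integers(
                1, 5, size=n_detected)
        # 'mito' gets 6% mitochondrial reads; ok cells ~1%
        for cell, frac in [("mito", 0.06)] + [(f"ok{i}", 0.01)
                                              for i in range(5)]:
            total = m[cell].sum()
            m.loc["MT-0", cell] = int(np.ceil(frac * total / (1 - frac)))
        return m

    def test_each_rule_fires(self):
        m = self._fixture()
        filtered, report = qc_filter(m)
        assert "low" not in filtered.columns      # <200 genes detected
        assert "high" not in filtered.columns     # >4500 genes detected
        assert "mito" not in filtered.columns     # >5% mito reads
        assert report["cells_removed_gene_bounds"] == 2
        assert report["cells_removed_mito"] == 1
        assert filtered.shape[1] == 5

    def test_dimensions_match_brute_force(self):
        m = self._fixture()
        filtered, _ = qc_filter(m)
        mito_mask = np.array([g.startswith("MT-") for g in m.index])
        exp_genes, exp_cells = qc_oracle(m, 200, 4500, 3, 0.05, mito_mask)
        assert filtered.shape == (exp_genes, exp_cells)

    def test_boundary_inclusivity(self):
        """A cell detecting exactly 200 genes survives ('at least 200'); a
        gene seen in exactly 3 surviving cells survives, in 2 does not."""
        genes = [f"G{i}" for i in range(210)]
        cells = [f"c{i}" for i in range(4)]
        m = pd.DataFrame(0, index=genes, columns=cells, dtype=np.int64)
        m.iloc[:200, :] = 1                      # every cell detects 200 genes
        m.loc["G205", ["c0", "c1", "c2"]] = 1    # support = 3 -> kept
        m.loc["G206", ["c0", "c1"]] = 1          # support = 2 -> dropped
        t = QcThresholds(min_genes_per_cell=200, min_cells_per_gene=3,
                         max_mito_fraction=0.05)
        filtered, _ = qc_filter(m, t)
        assert set(filtered.columns) == set(cells)
        assert "G205" in filtered.index and "G206" not in filtered.index

    def test_mito_boundary_exact_fraction_survives(self):
        """'More than 5%' is exclusive: a cell at exactly 5% mito stays."""
        genes = [f"G{i}" for i in range(210)] + ["MT-1"]
        m = pd.DataFrame(0, index=genes, columns=["at", "above"],
                         dtype=np.int64)
        m.iloc[:199, :] = 2                       # 199 genes x 2 reads = 398
        m.iloc[199, :] = 2                        # round to 200 genes, 400 reads
        m.loc["MT-1", "at"] = 400 // 19           # 400 normal + 21 -> 4.99%
        m.loc["MT-1", "above"] = 30               # 30/430 = 6.98%
        t = QcThresholds(min_genes_per_cell=200, min_cells_per_gene=1,
                         max_mito_fraction=0.05)
        filtered, report = qc_filter(m, t)
        assert "at" in filtered.columns and "above" not in filtered.columns
        assert report["cells_removed_mito"] == 1

    def test_idempotent_on_simulated_data(self):
        counts, _ = generate_timecourse_matrix(ScSimConfig(n_cells=100, seed=2))
        t = QcThresholds(min_genes_per_cell=10, max_genes_per_cell=4500,
                         min_cells_per_gene=3, max_mito_fraction=0.05)
        once, _ = qc_filter(counts, t)
        twice, report = qc_filter(once, t)
        assert twice.shape == once.shape
        assert report["cells_removed_gene_bounds"] == 0
        assert report["genes_removed_support"] == 0

    def test_empty_result_warns(self):
        m = pd.DataFrame(np.ones((5, 4), dtype=np.int64),
                         index=[f"g{i}" for i in range(5)],
                         columns=list("abcd"))
        with pytest.warns(UserWarning, match="removed everything"):
            out, _ = qc_filter(m)  # default min 200 genes kills all cells
        assert out.size == 0


class TestNormalize:
    def test_proportional_cells_identical(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [2, 4, 6], "c": [10, 0, 5]},
                         index=list("xyz"))
        out = normalize_log(m)
        assert np.allclose(out["a"], out["b"])

    def test_constant_matrix_stays_constant(self):
        m = pd.DataFrame(np.full((3, 4), 7), index=list("xyz"),
                         columns=list("abcd"))
        out = normalize_log(m)
        assert len(np.unique(out.to_numpy().round(12))) == 1

    def test_hand_computed_3x3(self):
        m = pd.DataFrame([[1, 0, 4], [2, 3, 0], [1, 1, 4]],
                         index=list("xyz"), columns=list("abc"))
        out = normalize_log(m)
        # library sizes 4, 4, 8; median target = 4
        expected = np.log1p(np.array([[1, 0, 2], [2, 3, 0], [1, 1, 2]], float))
        assert np.allclose(out.to_numpy(), expected)

    def test_zero_cell_errors_with_barcode(self):
        m = pd.DataFrame({"good": [1, 2], "dead": [0, 0]}, index=list("xy"))
        with pytest.raises(ValueError, match="dead"):
            normalize_log(m)


class TestImpute:
    @staticmethod
    def _two_clusters(gap=50.0, n_per=8, seed=0):
        rng = np.random.default_rng(seed)
        base = np.concatenate([rng.normal(0, 0.5, size=(n_per, 5)),
                               rng.normal(gap, 0.5, size=(n_per, 5))])
        return pd.DataFrame(base.T, index=[f"g{i}" for i in range(5)],
                            columns=[f"c{i}" for i in range(2 * n_per)])

    def test_zero_steps_identity(self):
        m = self._two_clusters()
        out = impute(m, ImputeConfig(k_neighbors=3, diffusion_steps=0))
        assert np.allclose(out.to_numpy(), m.to_numpy())

    def test_constant_gene_fixed_point(self):
        m = self._two_clusters()
        m.loc["g0"] = 3.14
        out = impute(m, ImputeConfig(k_neighbors=3, diffusion_steps=7))
        assert np.allclose(out.loc["g0"], 3.14)

    def test_large_t_converges_to_cluster_means(self):
        """With k spanning each cluster, diffusion mixes each block to its
        mean; verified against explicit powering of an independently built
        transition matrix."""
        m = self._two_clusters(n_per=8)
        imp = KNNDiffusionImputer(k_neighbors=7, diffusion_steps=40).fit(m)
        out = imp.transform(m)
        for block in (slice(0, 8), slice(8, 16)):
            vals = out.iloc[:, block].to_numpy()
            target = m.iloc[:, block].to_numpy().mean(axis=1, keepdims=True)
            assert np.allclose(vals, target, atol=1e-6)
        # independent oracle: rebuild the graph by brute-force distances
        X = m.to_numpy().T
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        A = np.zeros_like(D)
        for i in range(len(D)):
            A[i, np.argsort(D[i])[:8]] = 1  # 7 neighbours + self
        A = np.maximum(A, A.T)
        T = A / A.sum(axis=1, keepdims=True)
        oracle = m.to_numpy() @ np.linalg.matrix_power(T.T, 40)
        assert np.allclose(out.to_numpy(), oracle, atol=1e-8)

    def test_doubly_stochastic_preserves_gene_means(self):
        m = self._two_clusters(n_per=5)
        # k = n-1 makes the affinity complete -> T doubly stochastic
        out = impute(m, ImputeConfig(k_neighbors=9, diffusion_steps=5))
        assert np.allclose(out.mean(axis=1), m.mean(axis=1))

    def test_k_too_large_errors(self):
        m = self._two_clusters(n_per=3)
        with pytest.raises(ValueError, match="k_neighbors"):
            impute(m, ImputeConfig(k_neighbors=6, diffusion_steps=1))


class TestPartition:
    def test_two_cell_example(self):
        m = pd.DataFrame({"c1": [1.0, 0.0], "c2": [0.0, 1.0]},
                         index=["A", "B"])
        labels = partition_by_marker_pair(m, "A", "B")
        assert labels["c1"] == "a_enriched_b_reduced"
        assert labels["c2"] == "b_enriched_a_reduced"

    def test_all_above_both_midpoints_intermediate(self):
        m = pd.DataFrame({"c0": [0.0, 0.0], "c1": [10.0, 9.0],
                          "c2": [10.0, 9.0], "c3": [9.0, 10.0]},
                         index=["A", "B"])
        labels = partition_by_marker_pair(m, "A", "B")
        assert set(labels) == {"intermediate"}

    def test_partition_covers_all_cells(self, rng):
        m = pd.DataFrame(rng.normal(size=(2, 40)), index=["A", "B"],
                         columns=[f"c{i}" for i in range(40)])
        labels = partition_by_marker_pair(m, "A", "B")
        assert len(labels) == 40
        assert set(labels) <= {"a_enriched_b_reduced", "b_enriched_a_reduced",
                               "intermediate"}

    def test_zero_range_errors(self):
        m = pd.DataFrame({"c1": [1.0, 2.0], "c2": [1.0, 3.0]},
                         index=["A", "B"])
        with pytest.raises(ValueError, match="midpoint"):
            partition_by_marker_pair(m, "A", "B")

    def test_planted_modules_recovered(self):
        from decidua.preprocess import normalize_log as norm
        counts, states = generate_timecourse_matrix(
            ScSimConfig(n_cells=400, seed=13))
        imputed = impute(norm(counts), ImputeConfig(15, 3))
        labels = partition_by_marker_pair(imputed, "GENE0001", "GENE0031")
        mapped = labels.map({"a_enriched_b_reduced": "DC",
                             "b_enriched_a_reduced": "snDC"})
        branch = states.isin(["DC", "snDC"]) & mapped.notna()
        agreement = (mapped[branch] == states[branch]).mean()
        assert agreement >= 0.9


def exact_ranksum_p(a, b):
    """Two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    obs = _u_stat(a, b)
    mid = n1 * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = _u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mid) >= abs(obs - mid) - 1e-12:
            count += 1
    return count / total


def _u_stat(a, b):
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([a, b]))
    return ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2


class TestWilcoxonMarkers:
    @staticmethod
    def _mat(rows, cells):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=cells)

    def test_identical_groups_p_one(self):
        m = self._mat([[1, 2, 3, 1, 2, 3], [5, 6, 7, 5, 6, 7]], list("abcdef"))
        res = wilcoxon_markers(m, ["a", "b", "c"], ["d", "e", "f"])
        assert np.allclose(res["p_value"], 1.0)

    def test_single_gene_bonferroni_identity(self):
        m = self._mat([[1, 2, 3, 10, 11, 12]], list("abcdef"))
        res = wilcoxon_markers(m, ["a", "b", "c"], ["d", "e", "f"])
        assert res["p_adjusted"].iloc[0] == res["p_value"].iloc[0]

    def test_separated_groups_exact_p(self):
        m = self._mat([[1, 2, 3, 10, 11, 12]], list("abcdef"))
        res = wilcoxon_markers(m, ["a", "b", "c"], ["d", "e", "f"])
        assert res["p_value"].iloc[0] == pytest.approx(0.1)  # 2/C(6,3)
        assert res["direction"].iloc[0] == "down_in_a"

    def test_matches_enumeration_oracle(self, rng):
        for n1, n2 in [(3, 3), (4, 5), (6, 6)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2) + 0.5
            cells = [f"c{i}" for i in range(n1 + n2)]
            m = self._mat([np.concatenate([a, b])], cells)
            res = wilcoxon_markers(m, cells[:n1], cells[n1:])
            assert res["p_value"].iloc[0] == pytest.approx(
                exact_ranksum_p(a, b), abs=1e-10)

    def test_bonferroni_scaling(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 8)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"c{i}" for i in range(8)])
        res = wilcoxon_markers(m, [f"c{i}" for i in range(4)],
                               [f"c{i}" for i in range(4, 8)])
        assert np.allclose(res["p_adjusted"],
                           np.minimum(1.0, res["p_value"] * 5))

    def test_overlapping_groups_error(self):
        m = self._mat([[1, 2, 3, 4, 5, 6]], list("abcdef"))
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_markers(m, ["a", "b", "c"], ["c", "d", "e"])

    def test_small_group_error(self):
        m = self._mat([[1, 2, 3, 4, 5, 6]], list("abcdef"))
        with pytest.raises(ValueError, match=">= 3"):
            wilcoxon_markers(m, ["a", "b"], ["c", "d", "e"])
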