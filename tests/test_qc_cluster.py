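"""Coverage matrices, trimmed Gaussian clustering, alpha selection, filtering."""

import itertools
import math

import numpy as np
import pytest

from skewc.coverage import CoverageVector, write_store_tsv
from skewc.errors import DegenerateDataError, FormatError, InputError, ParameterError
from skewc.fixtures import make_coverage_cohort
from skewc.qc_cluster import (
    SKEWED,
    TYPICAL,
    assemble_coverage_matrix,
    classify_cells,
    decile_means,
    filter_cells,
    select_alpha,
    tclust_k1,
    write_annotation_tables,
)


def random_vectors(n, seed=0, degenerate_ids=()):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cid = f"c{i}"
        if cid in degenerate_ids:
            vals = np.zeros(100)
            raw = np.zeros(100, dtype=np.int64)
        else:
            vals = rng.dirichlet(np.ones(100))
            raw = np.ones(100, dtype=np.int64)
        out.append(CoverageVector(cid, vals, raw))
    return out


class TestAssembleAndDecileMeans:
    def test_census_and_101_logical_columns(self):
        cov = assemble_coverage_matrix(random_vectors(20))
        assert cov.values.shape == (20, 100)
        assert len(cov.cell_ids) == 20
        # identifier column + 100 bins = 101 columns
        assert cov.to_frame().shape == (20, 101)

    def test_duplicate_ids_rejected(self):
        vecs = random_vectors(3) + random_vectors(1)
        with pytest.raises(FormatError, match="duplicate"):
            assemble_coverage_matrix(vecs)

    def test_constant_row(self):
        vec = CoverageVector("c0", np.full(100, 0.01), np.ones(100, dtype=np.int64))
        mm = decile_means(assemble_coverage_matrix([vec]))
        assert np.allclose(mm.means[0], 0.01)

    def test_linear_ramp_row(self):
        # values[i] = (i+1)/5050 -> pmean10 = 5.5/5050, pmean100 = 95.5/5050
        vals = np.arange(1, 101) / 5050.0
        mm = decile_means(assemble_coverage_matrix(
            [CoverageVector("ramp", vals, np.ones(100, dtype=np.int64))]))
        assert mm.means[0, 0] == pytest.approx(5.5 / 5050)
        assert mm.means[0, -1] == pytest.approx(95.5 / 5050)

    def test_mean_matrix_has_ten_named_columns(self):
        mm = decile_means(assemble_coverage_matrix(random_vectors(5)))
        assert mm.columns == [f"pmean{j}" for j in range(10, 101, 10)]
        assert mm.to_frame().shape == (5, 11)  # cell_id + 10 numeric

    def test_brute_force_means(self):
        cov = assemble_coverage_matrix(random_vectors(30, seed=3))
        mm = decile_means(cov)
        for i in range(30):
            for j in range(10):
                expected = sum(cov.values[i, 10 * j + k] for k in range(10)) / 10
                assert mm.means[i, j] == pytest.approx(expected, abs=1e-15)

    def test_degenerate_rows_dropped_and_reported(self):
        vecs = random_vectors(6, degenerate_ids={"c2", "c4"})
        mm = decile_means(assemble_coverage_matrix(vecs))
        assert len(mm) == 4
        assert mm.dropped_degenerate == ["c2", "c4"]

    def test_all_degenerate_error(self):
        vecs = random_vectors(3, degenerate_ids={"c0", "c1", "c2"})
        with pytest.raises(DegenerateDataError, match="no usable cells"):
            decile_means(assemble_coverage_matrix(vecs))


def exhaustive_trimmed_mle(X: np.ndarray, alpha: float, c: float = 50.0) -> float:
    """Independent oracle: enumerate every retained subset, fit the
    ratio-constrained Gaussian MLE, return the best trimmed log-likelihood."""
    n, d = X.shape
    h = math.floor(n * (1 - alpha))
    best = -np.inf
    for S in itertools.combinations(range(n), h):
        sub = X[list(S)]
        mu = sub.mean(axis=0)
        xc = sub - mu
        cov = (xc.T @ xc) / h
        vals, vecs = np.linalg.eigh((cov + cov.T) / 2)
        vals = np.maximum(vals, 0.0)
        if vals.max() <= 0:
            continue
        cands = np.unique(np.concatenate([vals, vals / c]))
        cands = cands[cands > 0]
        best_f, best_vals = np.inf, None
        for m in cands:
            dd = np.clip(vals, m, c * m)
            f = float(np.sum(np.log(dd) + vals / dd))
            if f < best_f:
                best_f, best_vals = f, dd
        cc = (vecs * best_vals) @ vecs.T
        chol = np.linalg.cholesky(cc)
        sol = np.linalg.solve(chol, xc.T)
        obj = -0.5 * (h * d * math.log(2 * math.pi)
                      + 2 * h * float(np.log(np.diag(chol)).sum())
                      + float((sol ** 2).sum()))
        best = max(best, obj)
    return best


class TestTclustK1:
    def test_alpha_zero_is_clipped_mle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        res = tclust_k1(X, 0.0, seed=1)
        assert res.n_skewed == 0
        assert set(res.labels) == {TYPICAL}
        assert np.allclose(res.center, X.mean(axis=0))
        cov = (X - X.mean(0)).T @ (X - X.mean(0)) / 40
        assert np.allclose(res.covariance, cov, atol=1e-10)  # ratio already fine

    def test_single_far_outlier_is_trimmed(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [0.5], [0.6], [0.7],
                      [0.8], [100.0]])
        res = tclust_k1(X, 0.1, seed=3)
        assert res.labels[-1] == SKEWED
        assert res.n_skewed == 1
        assert res.center[0] == pytest.approx(np.mean(X[:-1]))
        assert res.objective == pytest.approx(exhaustive_trimmed_mle(X, 0.1),
                                              abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        d = int(rng.integers(1, 3))
        alpha = float(rng.choice([0.0, 0.1, 0.2, 0.3]))
        if math.floor(n * (1 - alpha)) < d + 1:
            alpha = 0.0
        X = rng.normal(size=(n, d))
        if seed % 2:
            X[: max(1, n // 5)] += 6.0
        res = tclust_k1(X, alpha, seed=seed + 1)
        assert res.objective == pytest.approx(exhaustive_trimmed_mle(X, alpha),
                                              abs=1e-8)

    @pytest.mark.parametrize("n,alpha", [(20, 0.0), (20, 0.1), (50, 0.04),
                                         (50, 0.25), (100, 0.1), (930, 0.04)])
    def test_trim_count_law(self, n, alpha):
        rng = np.random.default_rng(n)
        X = rng.normal(size=(n, 2))
        res = tclust_k1(X, alpha, seed=1, n_starts=8)
        assert res.n_typical == math.floor(n * (1 - alpha))
        assert res.n_skewed == n - math.floor(n * (1 - alpha))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        X[:3] += 8.0
        res = tclust_k1(X, 0.1, seed=2)
        perm = rng.permutation(30)
        res_p = tclust_k1(X[perm], 0.1, seed=2)
        assert [res.labels[i] for i in perm] == res_p.labels
        assert res_p.objective == pytest.approx(res.objective, abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 3))
        X[:2] += 10.0
        res = tclust_k1(X, 0.1, seed=2)
        res_s = tclust_k1(3.7 * X + 1.2, 0.1, seed=2)
        assert res.labels == res_s.labels

    def test_parameter_errors(self):
        X = np.zeros((10, 3)) + np.arange(10)[:, None]
        with pytest.raises(ParameterError):
            tclust_k1(X, 1.0, seed=1)
        with pytest.raises(ParameterError):
            tclust_k1(X, 0.7, seed=1)  # floor(3) < d+1 = 4
        with pytest.raises(ParameterError):
            tclust_k1(X, 0.1, restr_factor=0.5, seed=1)

    def test_identical_points_degenerate(self):
        X = np.ones((12, 2))
        with pytest.raises(DegenerateDataError):
            tclust_k1(X, 0.0, seed=1)


class TestSelectAlpha:
    def test_single_point_grid(self, planted_cohort):
        vecs, _ = planted_cohort
        mm = decile_means(assemble_coverage_matrix(vecs))
        curve = select_alpha(mm.means, [0.1], seed=1)
        assert curve.selected_alpha == 0.1
        assert len(curve.objectives) == 1

    def test_empty_grid_error(self):
        with pytest.raises(ParameterError):
            select_alpha(np.zeros((20, 2)), [], seed=1)

    def test_planted_outlier_recovery_and_band(self):
        """With 10 planted skewed cells in 100, the elbow of the trimmed
        likelihood curve should land near the true contamination level and
        the run at the selected alpha should trim the planted cells."""
        hits, all_trimmed = 0, 0
        n_seeds = 8
        for seed in range(1, n_seeds + 1):
            vecs, truth = make_coverage_cohort(90, 10, seed=seed)
            mm = decile_means(assemble_coverage_matrix(vecs))
            curve = select_alpha(mm.means, seed=seed)
            if 0.05 <= curve.selected_alpha <= 0.15:
                hits += 1
            res = tclust_k1(mm.means, curve.selected_alpha, seed=seed,
                            cell_ids=mm.cell_ids)
            planted = {c for c, lab in truth.items() if lab == "skewed"}
            if planted <= set(res.skewed_ids()):
                all_trimmed += 1
        assert hits >= n_seeds - 1
        assert all_trimmed >= n_seeds - 1

    def test_selection_rule_recorded(self, planted_cohort):
        vecs, _ = planted_cohort
        mm = decile_means(assemble_coverage_matrix(vecs))
        curve = select_alpha(mm.means, seed=1)
        assert curve.selection_rule_id == "curvature-elbow-v1"
        assert len(curve.alphas) == len(curve.objectives)


class TestClassifyCells:
    def test_single_alpha_trim_count(self, planted_cohort):
        vecs, _ = planted_cohort
        mm = decile_means(assemble_coverage_matrix(vecs[:50]))
        results = classify_cells(mm, [0.1], seed=1)
        assert len(results) == 1
        alpha, res = results[0]
        assert alpha == 0.1
        assert res.n_skewed == 50 - math.floor(50 * 0.9)

    def test_multi_alpha_nestedness(self):
        """On well-separated cohorts the skewed set grows with alpha."""
        ok = 0
        n_seeds = 8
        for seed in range(1, n_seeds + 1):
            vecs, _ = make_coverage_cohort(90, 10, seed=seed)
            mm = decile_means(assemble_coverage_matrix(vecs))
            results = classify_cells(mm, [0.1, 0.2], seed=seed)
            (a1, r1), (a2, r2) = results
            assert (r1.n_skewed, r2.n_skewed) == (10, 20)
            if set(r1.skewed_ids()) <= set(r2.skewed_ids()):
                ok += 1
        assert ok >= n_seeds - 1

    def test_auto_mode_matches_select_alpha(self, planted_cohort):
        vecs, truth = planted_cohort
        mm = decile_means(assemble_coverage_matrix(vecs))
        results = classify_cells(mm, [], seed=7)
        assert len(results) == 1
        alpha, res = results[0]
        curve = select_alpha(mm.means, seed=7)
        assert alpha == curve.selected_alpha
        planted = {c for c, lab in truth.items() if lab == "skewed"}
        assert planted <= set(res.skewed_ids())

    def test_inadmissible_alpha_rejected_before_any_run(self, planted_cohort):
        vecs, _ = planted_cohort
        mm = decile_means(assemble_coverage_matrix(vecs))
        with pytest.raises(ParameterError):
            classify_cells(mm, [0.1, 0.99], seed=1)

    def test_annotation_tables(self, tmp_path, planted_cohort):
        vecs, _ = planted_cohort
        mm = decile_means(assemble_coverage_matrix(vecs))
        _, res = classify_cells(mm, [0.1], seed=1)[0]
        paths = write_annotation_tables(res, tmp_path, "TESTPRJ")
        import json

        import pandas as pd

        typ = pd.read_csv(paths[TYPICAL], sep="\t")
        skw = pd.read_csv(paths[SKEWED], sep="\t")
        assert list(typ.columns) == ["cell_id", "annotation", "alpha"]
        assert len(typ) == res.n_typical and len(skw) == res.n_skewed
        ann = json.loads(paths["json"].read_text())
        assert ann["n_typical"] == res.n_typical
        assert sorted(ann["skewed_cells"]) == sorted(res.skewed_ids())


class TestFilterCells:
    def write_store(self, tmp_path, n=10):
        vecs = random_vectors(n, seed=2)
        store = tmp_path / "coverage.tsv"
        write_store_tsv(vecs, store)
        return store, [v.cell_id for v in vecs]

    def test_three_matched_seven_unmatched(self, tmp_path):
        store, ids = self.write_store(tmp_path)
        flt = tmp_path / "filter.txt"
        flt.write_text("\n".join(ids[:3]) + "\n")
        n_match, n_unmatch = filter_cells(store, flt, tmp_path / "match",
                                          tmp_path / "unmatch")
        assert (n_match, n_unmatch) == (3, 7)

    def test_unknown_id_warns_and_matches_nothing(self, tmp_path, caplog):
        store, _ = self.write_store(tmp_path)
        flt = tmp_path / "filter.txt"
        flt.write_text("not-a-cell\n")
        with caplog.at_level("WARNING"):
            n_match, n_unmatch = filter_cells(store, flt, tmp_path / "m",
                                              tmp_path / "u")
        assert (n_match, n_unmatch) == (0, 10)
        assert any("not-a-cell" in r.message for r in caplog.records)

    def test_partition_disjoint_and_complete(self, tmp_path):
        from skewc.coverage import read_store

        store, ids = self.write_store(tmp_path)
        flt = tmp_path / "filter.txt"
        flt.write_text("\n".join(ids[::2]) + "\n")
        filter_cells(store, flt, tmp_path / "m", tmp_path / "u")
        matched = {v.cell_id for v in read_store(tmp_path / "m" / "coverage.tsv")}
        unmatched = {v.cell_id for v in read_store(tmp_path / "u" / "coverage.tsv")}
        assert matched | unmatched == set(ids)
        assert matched & unmatched == set()

    def test_empty_filter_error(self, tmp_path):
        store, _ = self.write_store(tmp_path)
        flt = tmp_path / "filter.txt"
        flt.write_text("\n")
        with pytest.raises(FormatError, match="empty"):
            filter_cells(store, flt, tmp_path / "m", tmp_path / "u")

    def test_missing_filter_file(self, tmp_path):
        store, _ = self.write_store(tmp_path)
        with pytest.raises(InputError):
            filter_cells(store, tmp_path / "nope.txt", tmp_path / "m",
                         tmp_path / "u")
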