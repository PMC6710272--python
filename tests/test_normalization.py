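import numpy as np
import pandas as pd
import pytest

from phenoseq import normalization as norm
from phenoseq.synthetic_data import simulate_calibration_pairs, simulate_depth_matrix


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(30, 6))
    return pd.DataFrame(
        counts,
        index=[f"gene{i}" for i in range(30)],
        columns=[f"sph{j}" for j in range(6)],
    )


class TestQCFilter:
    def _matrix(self, totals, detected_genes, mito_fracs, n_genes=6000):
        """Build libraries with prescribed totals, detected genes and mito share."""
        columns = {}
        genes = [f"MT-{i}" for i in range(5)] + [f"G{i}" for i in range(n_genes - 5)]
        for j, (total, det, mf) in enumerate(zip(totals, detected_genes, mito_fracs)):
            col = np.zeros(n_genes, dtype=np.int64)
            mito_counts = int(round(total * mf))
            col[0] = mito_counts
            body = total - mito_counts
            det_body = det - (1 if mito_counts > 0 else 0)
            col[5 : 5 + det_body - 1] = 1
            col[5 + det_body - 1] = body - (det_body - 1)
            columns[f"lib{j}"] = col
        return pd.DataFrame(columns, index=genes)

    def test_low_reads_removed_with_reason(self):
        matrix = self._matrix([150_000, 250_000], [4000, 4000], [0.05, 0.05])
        kept, report = norm.qc_filter_libraries(matrix, norm.QCThresholds())
        assert list(kept.columns) == ["lib1"]
        assert report.iloc[0].tolist() == ["lib0", "reads"]

    def test_three_rules_toy_example(self):
        # totals (250k, 150k, 300k), detected (4000, 5000, 2000), mito 5%
        matrix = self._matrix(
            [250_000, 150_000, 300_000], [4000, 5000, 2000], [0.05, 0.05, 0.05]
        )
        kept, report = norm.qc_filter_libraries(matrix, norm.QCThresholds())
        assert list(kept.columns) == ["lib0"]
        reasons = dict(zip(report["spheroid_id"], report["reason"]))
        assert reasons == {"lib1": "reads", "lib2": "genes"}

    def test_mito_rule(self):
        matrix = self._matrix([250_000, 250_000], [4000, 4000], [0.20, 0.05])
        kept, report = norm.qc_filter_libraries(matrix, norm.QCThresholds())
        assert list(kept.columns) == ["lib1"]
        assert report.iloc[0]["reason"] == "mito"

    def test_identity_thresholds(self, toy_matrix):
        kept, report = norm.qc_filter_libraries(
            toy_matrix, norm.QCThresholds(min_reads=0, min_genes_detected=0, max_mito_fraction=1.0)
        )
        pd.testing.assert_frame_equal(kept, toy_matrix)
        assert report.empty

    def test_idempotent(self):
        matrix = self._matrix([250_000, 150_000], [4000, 4000], [0.05, 0.05])
        once, _ = norm.qc_filter_libraries(matrix, norm.QCThresholds())
        twice, report = norm.qc_filter_libraries(once, norm.QCThresholds())
        pd.testing.assert_frame_equal(once, twice)
        assert report.empty

    def test_all_removed_raises(self, toy_matrix):
        with pytest.raises(ValueError, match="every library"):
            norm.qc_filter_libraries(toy_matrix, norm.QCThresholds(min_reads=10**9))


class TestCalibration:
    def test_noiseless_power_recovery(self):
        areas = np.array([50.0, 100.0, 200.0, 400.0])
        pairs = pd.DataFrame({"area_px": areas, "nuclei_count": 1.0 * areas**1.5})
        model = norm.fit_size_to_cells(pairs, "power")
        assert model.a == pytest.approx(1.0, abs=1e-10)
        assert model.b == pytest.approx(1.5, abs=1e-10)

    def test_noiseless_linear_recovery(self):
        areas = np.array([10.0, 20.0, 30.0])
        pairs = pd.DataFrame({"area_px": areas, "nuclei_count": 2.0 * areas})
        model = norm.fit_size_to_cells(pairs, "linear")
        assert model.a == pytest.approx(2.0, abs=1e-10)
        assert model.b == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_ten_percent(self):
        areas = np.logspace(1, 4, 50)  # wide leverage keeps the intercept stable
        pairs = simulate_calibration_pairs(0.5, 1.5, 0.1, areas, seed=0)
        model = norm.fit_size_to_cells(pairs, "power")
        assert abs(model.a - 0.5) / 0.5 < 0.10
        assert abs(model.b - 1.5) / 1.5 < 0.10

    def test_degenerate_design_rejected(self):
        pairs = pd.DataFrame({"area_px": [10.0, 10.0, 10.0], "nuclei_count": [1, 2, 3]})
        with pytest.raises(ValueError, match="degenerate"):
            norm.fit_size_to_cells(pairs, "power")

    def test_too_few_pairs(self):
        pairs = pd.DataFrame({"area_px": [10.0, 20.0], "nuclei_count": [1, 2]})
        with pytest.raises(ValueError, match="at least 3"):
            norm.fit_size_to_cells(pairs)


class TestEstimateCellNumbers:
    def test_power_prediction(self):
        model = norm.CalibrationModel("power", a=1.0, b=1.5, fit_residual_sd=0.0)
        features = pd.DataFrame({"spheroid_id": ["s1"], "area_px": [100.0]})
        cells = norm.estimate_cell_numbers(features, model)
        assert cells["s1"] == 1000

    def test_floor_at_one(self):
        model = norm.CalibrationModel("power", a=0.04, b=1.0, fit_residual_sd=0.0)
        features = pd.DataFrame({"spheroid_id": ["s1"], "area_px": [10.0]})
        assert norm.estimate_cell_numbers(features, model)["s1"] == 1

    def test_missing_area_raises(self):
        model = norm.CalibrationModel("power", a=1.0, b=1.0, fit_residual_sd=0.0)
        features = pd.DataFrame({"spheroid_id": ["s1", "s2"], "area_px": [10.0, np.nan]})
        with pytest.raises(ValueError, match="s2"):
            norm.estimate_cell_numbers(features, model)

    def test_round_trip_with_generator(self):
        areas = np.linspace(100, 1000, 20)
        pairs = simulate_calibration_pairs(0.5, 1.2, 0.0, areas, seed=0)
        model = norm.fit_size_to_cells(pairs, "power")
        features = pd.DataFrame({"spheroid_id": [f"s{i}" for i in range(20)], "area_px": areas})
        cells = norm.estimate_cell_numbers(features, model)
        truth = np.maximum(1, np.round(0.5 * areas**1.2))
        assert np.all(np.abs(cells.to_numpy() - truth) / truth < 0.05)


class TestMinPerCellCount:
    def test_worked_example(self):
        matrix = pd.DataFrame({"a": [4600, 0], "b": [4500, 4500]}, index=["g1", "g2"])
        cells = pd.Series({"a": 2, "b": 3})
        assert norm.min_per_cell_count(matrix, cells) == 2300.0

    def test_single_spheroid(self):
        matrix = pd.DataFrame({"a": [10]}, index=["g1"])
        assert norm.min_per_cell_count(matrix, pd.Series({"a": 1})) == 10.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.integers(0, 100, size=(20, 8)),
                              columns=[f"s{i}" for i in range(8)])
        cells = pd.Series(rng.integers(1, 10, size=8), index=matrix.columns)
        brute = min(matrix[c].sum() / cells[c] for c in matrix.columns)
        assert norm.min_per_cell_count(matrix, cells) == pytest.approx(brute)

    def test_suggest_target(self):
        assert norm.suggest_target_per_cell(2374.644) == 2300


def _random_count_matrix(seed, n_genes=25, n_spheroids=5, high=200):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.integers(0, high, size=(n_genes, n_spheroids)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_spheroids)],
    )


class TestDownsamplePerCell:
    def test_column_totals_exact(self):
        matrix = simulate_depth_matrix([0.1] * 10, [2, 3], 5000, seed=0)
        df = pd.DataFrame(matrix, columns=["a", "b"])
        cells = pd.Series({"a": 2, "b": 3})
        out = norm.downsample_per_cell(df, cells, 2300, seed=1)
        np.testing.assert_array_equal(out.sum(axis=0), [4600, 6900])

    def test_never_increases_entries(self):
        df = _random_count_matrix(0)
        cells = pd.Series(1, index=df.columns)
        out = norm.downsample_per_cell(df, cells, 50, seed=2)
        assert (out.to_numpy() <= df.to_numpy()).all()

    def test_identity_when_target_equals_total(self):
        df = _random_count_matrix(1)
        for col in df.columns:
            single = df[[col]]
            out = norm.downsample_per_cell(single, pd.Series({col: 1}), int(single[col].sum()), seed=0)
            pd.testing.assert_frame_equal(out, single)

    def test_insufficient_counts_names_spheroid(self):
        df = pd.DataFrame({"poor": [1, 2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="poor"):
            norm.downsample_per_cell(df, pd.Series({"poor": 5}), 100, seed=0)

    def test_seed_reproducible(self):
        df = _random_count_matrix(2)
        cells = pd.Series(1, index=df.columns)
        a = norm.downsample_per_cell(df, cells, 50, seed=9)
        b = norm.downsample_per_cell(df, cells, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_gene_permutation_exchangeable(self):
        # permuting gene order then downsampling == downsampling then permuting
        df = _random_count_matrix(3)
        cells = pd.Series(1, index=df.columns)
        rng = np.random.default_rng(0)
        perm = rng.permutation(df.index)
        direct = norm.downsample_per_cell(df.loc[perm], cells, 50, seed=5)
        indirect = norm.downsample_per_cell(df, cells, 50, seed=5).loc[perm]
        pd.testing.assert_frame_equal(direct, indirect)

    def test_perfect_correlation_with_cell_numbers(self):
        matrix = simulate_depth_matrix([0.05] * 20, [2, 5, 9, 14], 4000, seed=0)
        df = pd.DataFrame(matrix, columns=list("abcd"))
        cells = pd.Series([2, 5, 9, 14], index=list("abcd"))
        out = norm.downsample_per_cell(df, cells, 1000, seed=0)
        r = np.corrcoef(out.sum(axis=0), cells)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_share_preserved_in_expectation(self):
        # one gene holds 50% of the column; hypergeometric expectation keeps it
        df = pd.DataFrame({"s": [500, 250, 250]}, index=["g1", "g2", "g3"])
        cells = pd.Series({"s": 1})
        shares = [
            norm.downsample_per_cell(df, cells, 100, seed=s)["s"]["g1"] / 100
            for s in range(100)
        ]
        # Var of hypergeometric share: p(1-p)/n * (N-n)/(N-1); CI for the mean of 100 draws
        se = np.sqrt(0.5 * 0.5 / 100 * (1000 - 100) / 999 / 100)
        assert abs(np.mean(shares) - 0.5) < 4 * se


class TestDownsampleLibrary:
    def test_identity_at_full_total(self):
        column = np.array([10, 20, 30])
        np.testing.assert_array_equal(norm.downsample_library(column, 60, seed=0), column)

    def test_forced_outcome(self):
        np.testing.assert_array_equal(
            norm.downsample_library(np.array([100, 0]), 50, seed=0), [50, 0]
        )

    def test_insufficient_total(self):
        with pytest.raises(ValueError, match="counts"):
            norm.downsample_library(np.array([10]), 50, seed=0)

    def test_expectation_proportional(self):
        column = np.array([9000, 1000])
        draws = [norm.downsample_library(column, 1000, seed=s)[0] for s in range(100)]
        assert abs(np.mean(draws) - 900) < 30

    def test_series_round_trip(self):
        column = pd.Series([5, 5], index=["g1", "g2"], name="lib")
        out = norm.downsample_library(column, 10, seed=0)
        assert isinstance(out, pd.Series)
        assert out.sum() == 10


class TestGeneFilter:
    def test_kept_gene(self):
        original = pd.DataFrame({"a": [5], "b": [3], "c": [2]}, index=["g"]).astype(float)
        working = pd.DataFrame({"a": [5], "b": [5], "c": [0]}, index=["g"])
        assert list(norm.filter_genes_for_deconvolution(original, working).index) == ["g"]

    def test_removed_no_well_reaches_five(self):
        original = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["g"]).astype(float)
        working = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["g"])
        assert norm.filter_genes_for_deconvolution(original, working).empty

    def test_all_zero_removed(self):
        original = pd.DataFrame({"a": [0], "b": [0]}, index=["g"]).astype(float)
        working = original.astype(int)
        assert norm.filter_genes_for_deconvolution(original, working).empty

    def test_mean_rule_uses_original_matrix(self):
        # high in the working matrix but rare in the original -> removed
        original = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.5]}, index=["g"])
        working = pd.DataFrame({"a": [9], "b": [9], "c": [9]}, index=["g"])
        assert norm.filter_genes_for_deconvolution(original, working).empty

    def test_mismatched_genes_rejected(self):
        original = pd.DataFrame({"a": [1]}, index=["g1"])
        working = pd.DataFrame({"a": [1]}, index=["g2"])
        with pytest.raises(ValueError, match="genes"):
            norm.filter_genes_for_deconvolution(original, working)


class TestReplaceZeros:
    def test_zero_replaced(self):
        out = norm.replace_zeros(np.array([[0.0, 2.0]]))
        np.testing.assert_array_equal(out, [[0.1, 2.0]])

    def test_identity_without_zeros(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        pd.testing.assert_frame_equal(norm.replace_zeros(df), df)

    def test_modified_count_equals_zero_count(self):
        rng = np.random.default_rng(0)
        matrix = rng.integers(0, 3, size=(10, 10)).astype(float)
        out = norm.replace_zeros(matrix)
        assert (out == 0.1).sum() == (matrix == 0).sum()

    def test_positive_value_required(self):
        with pytest.raises(ValueError):
            norm.replace_zeros(np.zeros((2, 2)), value=0.0)
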