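"""Cohort table I/O, missingness filtering and KNN imputation."""

import numpy as np
import pandas as pd
import pytest

from msub.cohort_io import (
    BetaMatrix,
    CohortError,
    MutationTable,
    drop_silent_mutations,
    filter_missing,
    knn_impute,
    load_cohort,
    read_matrix,
    write_matrix,
)
from msub.simulate import generate_cohort


def _mat(values, index=None, columns=None):
    return pd.DataFrame(np.asarray(values, dtype=float), index=index, columns=columns)


class TestFilterMissing:
    @pytest.mark.parametrize(
        "n_missing,threshold,kept",
        [(3, 0.2, False), (2, 0.2, True), (0, 0.0, True)],
    )
    def test_row_threshold_is_strict(self, n_missing, threshold, kept):
        row = [np.nan] * n_missing + [0.5] * (10 - n_missing)
        df = pd.DataFrame([row, [0.5] * 10])
        out = filter_missing(df, threshold)
        assert (0 in out.index) == kept

    def test_complete_matrix_unchanged(self):
        df = _mat(np.random.default_rng(0).random((5, 4)))
        pd.testing.assert_frame_equal(filter_missing(df, 0.1), df)

    def test_rows_filtered_before_columns(self):
        # column 0 is missing only inside a row that the row pass removes,
        # so it must survive the column pass
        df = pd.DataFrame(
            [
                [np.nan, np.nan, np.nan, 0.1],
                [0.2, 0.3, 0.4, 0.5],
                [0.2, 0.3, 0.4, 0.5],
                [0.2, 0.3, 0.4, 0.5],
            ]
        )
        out = filter_missing(df, 0.5)
        assert list(out.index) == [1, 2, 3]
        assert out.shape[1] == 4

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = _mat(rng.random((20, 10)))
        df = df.mask(rng.random(df.shape) < 0.25)
        once = filter_missing(df, 0.2)
        pd.testing.assert_frame_equal(filter_missing(once, 0.2), once)

    def test_all_rows_removed_is_fatal(self):
        df = pd.DataFrame([[np.nan, 1.0], [1.0, np.nan]])
        with pytest.raises(CohortError, match="empty"):
            filter_missing(df, 0.3)


class TestKnnImpute:
    def test_complete_matrix_identity(self):
        df = _mat(np.random.default_rng(0).random((6, 5)))
        pd.testing.assert_frame_equal(knn_impute(df, k=2), df)

    def test_constant_neighbours(self):
        df = _mat([[0.6, 0.1], [0.6, 0.2], [0.6, 0.3], [np.nan, 0.2]])
        out = knn_impute(df, k=3)
        assert out.iloc[3, 0] == pytest.approx(0.6)

    def test_matches_bruteforce_oracle(self):
        # independent oracle: rescaled Euclidean over co-observed columns,
        # neighbour mean over the k nearest rows observing the target column
        rng = np.random.default_rng(42)
        X = rng.random((5, 5))
        X[1, 2] = np.nan
        X[4, 0] = np.nan
        df = _mat(X.copy())
        k = 2
        expected = X.copy()
        for i, j in [(1, 2), (4, 0)]:
            dists = []
            for other in range(5):
                if other == i:
                    continue
                if np.isnan(X[other, j]):
                    continue
                mask = ~np.isnan(X[i]) & ~np.isnan(X[other])
                d2 = ((X[i, mask] - X[other, mask]) ** 2).sum() * X.shape[1] / mask.sum()
                dists.append((np.sqrt(d2), other))
            nn = [o for _, o in sorted(dists)[:k]]
            expected[i, j] = np.mean([X[o, j] for o in nn])
        out = knn_impute(df, k=k)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_observed_cells_untouched_and_within_range(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 8))
        df = _mat(X).mask(rng.random((30, 8)) < 0.1)
        out = knn_impute(df, k=5)
        observed = (~df.isna()).to_numpy()
        assert np.array_equal(out.to_numpy()[observed], df.to_numpy()[observed])
        assert not out.isna().any().any()
        assert (out.to_numpy() >= df.min().min()).all()
        assert (out.to_numpy() <= df.max().max()).all()

    def test_k_exceeding_rows_warns_and_falls_back(self):
        df = _mat([[0.1, 0.2], [0.2, np.nan], [0.3, 0.4]])
        with pytest.warns(UserWarning, match="exceeds available rows"):
            out = knn_impute(df, k=10)
        assert out.iloc[1, 1] == pytest.approx((0.2 + 0.4) / 2)

    def test_fully_missing_row_is_fatal(self):
        df = _mat([[np.nan, np.nan], [0.1, 0.2]])
        with pytest.raises(CohortError):
            knn_impute(df, k=1)


class TestMutations:
    COLS = ["sample_id", "gene", "variant_classification", "is_silent"]

    def _table(self, rows):
        df = pd.DataFrame(rows, columns=self.COLS) if rows else pd.DataFrame(
            {c: [] for c in self.COLS}
        )
        return MutationTable(df)

    def test_silent_rows_removed(self):
        t = self._table(
            [
                ("s1", "NSD1", "Silent", True),
                ("s2", "NSD1", "Silent", True),
                ("s1", "NSD1", "Missense_Mutation", False),
            ]
        )
        out = drop_silent_mutations(t)
        assert len(out.rows) == 1
        assert not out.rows["is_silent"].any()

    def test_no_silent_identity_and_empty(self):
        t = self._table([("s1", "G1", "Missense_Mutation", False)])
        assert len(drop_silent_mutations(t).rows) == 1
        empty = self._table([])
        assert len(drop_silent_mutations(empty).rows) == 0

    def test_nonsilent_counts(self):
        t = self._table(
            [
                ("s1", "NSD1", "Missense_Mutation", False),
                ("s1", "NSD1", "Nonsense_Mutation", False),
                ("s2", "NSD1", "Silent", True),
            ]
        )
        counts = drop_silent_mutations(t).nonsilent_counts("NSD1")
        assert counts.get("s1") == 2
        assert "s2" not in counts


class TestLoadCohort:
    @pytest.fixture()
    def cohort_dir(self, tmp_path, small_config):
        generate_cohort(small_config, outdir=tmp_path)
        return tmp_path

    def test_roundtrip_through_disk(self, cohort_dir, small_cohort):
        cohort_mem, _ = small_cohort
        cohort = load_cohort(cohort_dir / "cohort.yaml")
        pd.testing.assert_frame_equal(
            cohort.beta.values, cohort_mem.beta.values, atol=1e-5, check_exact=False
        )
        assert list(cohort.beta.group) == list(cohort_mem.beta.group)
        assert len(cohort.mutations.rows) == len(cohort_mem.mutations.rows)

    def test_matrix_write_read_roundtrip(self, tmp_path):
        df = _mat(np.random.default_rng(0).random((4, 3)).round(6),
                  index=list("abcd"), columns=["s1", "s2", "s3"])
        write_matrix(df, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back, df)

    def test_expression_only_sample_dropped(self, cohort_dir, caplog):
        expr = read_matrix(cohort_dir / "expression.tsv")
        expr["EXTRA01"] = 5.0
        write_matrix(expr, cohort_dir / "expression.tsv")
        cohort = load_cohort(cohort_dir / "cohort.yaml")
        assert "EXTRA01" in cohort.dropped_samples["expression_only"]
        assert "EXTRA01" not in cohort.expression.values.columns

    def test_out_of_range_beta_names_cell(self, cohort_dir):
        beta = read_matrix(cohort_dir / "beta.tsv")
        probe, sample = beta.index[2], beta.columns[1]
        beta.loc[probe, sample] = 1.7
        write_matrix(beta, cohort_dir / "beta.tsv")
        with pytest.raises(CohortError) as err:
            load_cohort(cohort_dir / "cohort.yaml")
        assert probe in str(err.value) and sample in str(err.value)

    def test_missing_file_fatal(self, cohort_dir):
        (cohort_dir / "mutations.tsv").unlink()
        with pytest.raises(CohortError, match="missing file"):
            load_cohort(cohort_dir / "cohort.yaml")


def test_beta_matrix_rejects_duplicate_ids():
    df = pd.DataFrame([[0.1, 0.2], [0.3, 0.4]], index=["p1", "p1"], columns=["a", "b"])
    group = pd.Series(["tumor", "normal"], index=["a", "b"])
    with pytest.raises(CohortError, match="duplicate probe"):
        BetaMatrix(df, group, pd.Series("both", index=df.index))
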