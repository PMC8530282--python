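"""Preprocessing: CPM, filters, TMM, log2-CPM, quantile normalization, splits."""

import numpy as np
import pandas as pd
import pytest

from isomapnet.preprocess import (
    CountMatrix,
    ExpressionMatrix,
    PreprocessError,
    SampleTable,
    adjust_covariates,
    compute_cpm,
    filter_features,
    log2_cpm,
    quantile_normalize,
    read_counts_tsv,
    restrict_to_panel,
    split_dataset,
    tmm_factors,
    uq_factors,
    write_matrix_tsv,
)
from conftest import tmm_reference


def cm(counts, kind="gene"):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"f{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
        kind,
    )


class TestCpm:
    def test_direct_value(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 10
        counts[1, 0] = 1_000_000 - 10
        assert compute_cpm(cm(counts))[0, 0] == pytest.approx(10.0)

    def test_zero_feature_stays_zero(self):
        counts = np.array([[0, 0], [5, 7]])
        assert np.all(compute_cpm(cm(counts))[0] == 0)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(20, 4)) + 1
        assert np.allclose(compute_cpm(cm(counts)).sum(axis=0), 1e6)

    def test_zero_library_names_sample(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(PreprocessError, match="s1"):
            compute_cpm(cm(counts))


class TestFilter:
    def _counts_with_cpm(self, cpm_rows, lib=10_000_000):
        # build integer counts realizing the requested CPM values exactly
        counts = np.asarray(cpm_rows, dtype=float) * lib / 1e6
        # pad with a filler feature so library sizes hit `lib` exactly
        filler = lib - counts.sum(axis=0)
        return np.vstack([counts, filler]).astype(int)

    def test_low_mean_removed(self):
        rows = np.full((1, 100), 0.1)
        counts = self._counts_with_cpm(rows)
        kept = filter_features(cm(counts))
        assert "f0" not in kept

    def test_prevalent_feature_kept(self):
        row = np.r_[np.full(60, 0.6), np.zeros(40)]
        counts = self._counts_with_cpm(row[None, :])
        kept = filter_features(cm(counts))
        assert "f0" in kept

    def test_extreme_high_removed(self):
        row = np.r_[np.full(3, 60_000.0), np.full(97, 10.0)]
        counts = self._counts_with_cpm(row[None, :])
        kept = filter_features(cm(counts))
        assert "f0" not in kept

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(2, 0.01, size=(500, 60))
        mat = cm(counts)
        kept1 = filter_features(mat, min_samples=10)
        mat2 = mat.subset_features(kept1)
        kept2 = filter_features(mat2, min_samples=10)
        assert kept1 == kept2

    def test_min_samples_above_n_warns(self):
        counts = np.ones((3, 4), dtype=int)
        with pytest.warns(UserWarning, match="min_samples"):
            filter_features(cm(counts), min_samples=50)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 3))
        assert np.allclose(tmm_factors(cm(counts)), 1.0)

    def test_pure_library_size_scaling_cancels(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 100, size=200)
        counts = np.column_stack([a, 2 * a])
        assert np.allclose(tmm_factors(cm(counts)), 1.0)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_independent_transcription(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.negative_binomial(5, 0.1, size=(200, 3))
        ours = tmm_factors(cm(counts))
        ref = tmm_reference(counts)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(3, 0.05, size=(100, 5))
        f = tmm_factors(cm(counts))
        assert abs(np.log(f).sum()) < 1e-10

    def test_scaling_one_sample_leaves_factors_nearly_unchanged(self):
        # M-values and reference choice are exactly invariant to scaling one
        # column; only the precision weights shift, so factors agree closely
        # but not to machine precision
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 0.1, size=(150, 4))
        f1 = tmm_factors(cm(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 3
        f2 = tmm_factors(cm(scaled))
        assert np.allclose(f1, f2, atol=0.05)

    def test_uq_factors_unit_on_identical_columns(self):
        counts = np.tile(np.arange(1, 31)[:, None], (1, 3))
        assert np.allclose(uq_factors(cm(counts)), 1.0)


class TestLog2Cpm:
    def test_zero_count_closed_form(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[1, 0] = 1_000_000
        expr = log2_cpm(cm(counts), np.ones(1))
        assert expr.values[0, 0] == pytest.approx(np.log2(0.5 / 1_000_001 * 1e6))

    def test_doubling_counts_and_library_is_stable(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1000, 5000, size=(30, 2))
        e1 = log2_cpm(cm(counts)).values
        e2 = log2_cpm(cm(counts * 2)).values
        assert np.max(np.abs(e1 - e2)) < 1e-3

    def test_monotone_in_count(self):
        counts = np.array([[1], [10], [100], [1000]])
        vals = log2_cpm(cm(counts)).values[:, 0]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(PreprocessError):
            log2_cpm(cm(np.ones((2, 2), dtype=int)), np.array([1.0, 0.0]))


class TestQuantileNormalize:
    def em(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix(
            [f"f{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
            values,
        )

    def test_two_columns_meet_at_mean(self):
        out = quantile_normalize(self.em([[1, 4], [2, 5], [3, 6]]))
        assert np.allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        x = np.tile([[1.0], [5.0], [9.0]], (1, 3))
        out = quantile_normalize(self.em(x))
        assert np.allclose(out.values, x)

    def test_tie_rule_averages_reference(self):
        out = quantile_normalize(self.em([[1, 0], [1, 2], [2, 4]]))
        assert np.allclose(out.values[:, 0], [1.0, 1.0, 3.0])

    def test_idempotent_and_equalizes_sorted_columns(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(40, 5))
        once = quantile_normalize(self.em(x))
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)
        sorted_cols = np.sort(once.values, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])


class TestAdjustCovariates:
    def _samples(self, n, rng, labels=None):
        labels = rng.integers(0, 2, n) if labels is None else labels
        return SampleTable(
            pd.DataFrame(
                {
                    "label": labels,
                    "age": rng.normal(60, 8, n),
                    "sex": rng.choice(["f", "m"], n),
                },
                index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
            )
        )

    def em_for(self, values, samples):
        return ExpressionMatrix(
            [f"f{i}" for i in range(values.shape[0])], samples.sample_ids, values
        )

    def test_pure_age_effect_flattened(self):
        rng = np.random.default_rng(7)
        n = 200
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        samples = self._samples(n, rng, labels)
        age = samples.frame["age"].to_numpy()
        expr = self.em_for((2 * age)[None, :], samples)
        out = adjust_covariates(expr, samples, ["age"])
        assert np.std(out.values[0]) < 1e-8

    def test_label_effect_retained(self):
        rng = np.random.default_rng(8)
        samples = self._samples(100, rng)
        y = samples.labels.astype(float)
        expr = self.em_for((3 * y)[None, :], samples)
        out = adjust_covariates(expr, samples, ["age", "sex"])
        assert np.allclose(out.values[0], expr.values[0], atol=1e-8)

    def test_projection_idempotent(self):
        rng = np.random.default_rng(9)
        samples = self._samples(80, rng)
        expr = self.em_for(rng.normal(size=(10, 80)), samples)
        once = adjust_covariates(expr, samples, ["age", "sex"])
        twice = adjust_covariates(once, samples, ["age", "sex"])
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(10)
        samples = self._samples(50, rng)
        samples.frame["age2"] = samples.frame["age"]
        expr = self.em_for(rng.normal(size=(3, 50)), samples)
        with pytest.raises(PreprocessError, match="rank deficient"):
            adjust_covariates(expr, samples, ["age", "age2"])


class TestSplitDataset:
    def _samples(self, n, n_pos, seed=0):
        labels = np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)]
        rng = np.random.default_rng(seed)
        rng.shuffle(labels)
        return SampleTable(
            pd.DataFrame(
                {"label": labels},
                index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
            )
        )

    def test_cohort_scale_sizes(self):
        samples = self._samples(2557, 905)
        split = split_dataset(samples, (1637, 407, 513), seed=1)
        sizes = {w: len(split.samples_in(w)) for w in ("train", "validation", "test")}
        assert sizes == {"train": 1637, "validation": 407, "test": 513}

    def test_small_exact_partition(self):
        samples = self._samples(10, 5)
        split = split_dataset(samples, (6, 2, 2), seed=2)
        groups = [set(split.samples_in(w)) for w in ("train", "validation", "test")]
        assert [len(g) for g in groups] == [6, 2, 2]
        assert set.union(*groups) == set(samples.sample_ids)
        assert sum(len(g) for g in groups) == 10

    def test_stratification_within_one_sample(self):
        samples = self._samples(2557, 905)
        split = split_dataset(samples, (1637, 407, 513), seed=3)
        global_rate = 905 / 2557
        for w, n_w in (("train", 1637), ("validation", 407), ("test", 513)):
            ids = split.samples_in(w)
            n_pos = int(samples.labels_for(ids).sum())
            assert abs(n_pos - global_rate * n_w) <= 1.0

    def test_reproducible_and_seed_sensitive(self):
        samples = self._samples(100, 35)
        a = split_dataset(samples, (60, 20, 20), seed=5)
        b = split_dataset(samples, (60, 20, 20), seed=5)
        c = split_dataset(samples, (60, 20, 20), seed=6)
        assert a.split == b.split and a.fold == b.fold
        assert a.split != c.split

    def test_folds_cover_training_evenly(self):
        samples = self._samples(103, 40)
        split = split_dataset(samples, (63, 20, 20), seed=7)
        fold_sizes = [len(split.fold_samples(k)) for k in range(1, 6)]
        assert sum(fold_sizes) == 63
        assert max(fold_sizes) - min(fold_sizes) <= 1
        assert set(split.fold) == set(split.samples_in("train"))

    def test_bad_sizes_rejected(self):
        samples = self._samples(10, 5)
        with pytest.raises(PreprocessError):
            split_dataset(samples, (5, 2, 2), seed=0)


class TestPanelAndIo:
    def test_restrict_to_panel(self):
        counts = cm(np.arange(12).reshape(3, 4))
        mapping = {"f0": "G1", "f1": "G2", "f2": "G1"}
        out = restrict_to_panel(counts, {"G1"}, mapping)
        assert out.feature_ids == ["f0", "f2"]
        out_all = restrict_to_panel(counts, {"G1", "G2"}, mapping)
        assert out_all.feature_ids == counts.feature_ids

    def test_empty_panel_warns(self):
        counts = cm(np.ones((2, 2), dtype=int))
        with pytest.warns(UserWarning):
            out = restrict_to_panel(counts, set(), {"f0": "G", "f1": "G"})
        assert out.feature_ids == []

    def test_unmapped_feature_rejected(self):
        counts = cm(np.ones((2, 2), dtype=int))
        with pytest.raises(PreprocessError):
            restrict_to_panel(counts, {"G"}, {"f0": "G"})

    def test_counts_tsv_round_trip(self, tmp_path):
        counts = cm(np.arange(6).reshape(2, 3), kind="exon")
        path = tmp_path / "c.tsv"
        write_matrix_tsv(counts, str(path))
        back = read_counts_tsv(str(path), feature_kind="exon")
        assert back.feature_ids == counts.feature_ids
        assert back.sample_ids == counts.sample_ids
        assert np.array_equal(back.counts, counts.counts)
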