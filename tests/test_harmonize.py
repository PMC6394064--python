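"""Pooling, quantile normalization, median polish and QC diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urimark import harmonize
from urimark.errors import HarmonizationError, ValidationError

from conftest import make_matrix


class TestIntersect:
    def test_identical_feature_sets_pass_through_sorted(self):
        a = make_matrix(np.ones((3, 2)), gene_ids=["C", "A", "B"])
        out = harmonize.intersect_platform_features([a])
        assert list(out.values.index) == ["A", "B", "C"]

    def test_partial_overlap_keeps_shared_values_unchanged(self):
        a = make_matrix([[1.0], [2.0], [3.0]], gene_ids=["A", "B", "C"],
                        sample_ids=["s1"])
        b = make_matrix([[4.0], [5.0], [6.0]], gene_ids=["B", "C", "D"],
                        sample_ids=["s2"])
        out = harmonize.intersect_platform_features([a, b])
        assert list(out.values.index) == ["B", "C"]
        assert out.values.loc["B", "s1"] == 2.0
        assert out.values.loc["B", "s2"] == 4.0
        assert list(out.values.columns) == ["s1", "s2"]

    def test_random_subsets_match_set_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"F{i}" for i in range(1500)]
        subsets = [
            sorted(rng.choice(universe, size=1000, replace=False))
            for _ in range(3)
        ]
        mats = [
            make_matrix(np.zeros((1000, 1)), gene_ids=s,
                        sample_ids=[f"s{i}"])
            for i, s in enumerate(subsets)
        ]
        out = harmonize.intersect_platform_features(mats)
        oracle = set(subsets[0]) & set(subsets[1]) & set(subsets[2])
        assert out.n_genes == len(oracle)

    def test_empty_intersection_reports_pairwise_overlaps(self):
        a = make_matrix(np.zeros((2, 1)), gene_ids=["A", "B"], sample_ids=["s1"])
        b = make_matrix(np.zeros((2, 1)), gene_ids=["C", "D"], sample_ids=["s2"])
        with pytest.raises(HarmonizationError, match="overlap"):
            harmonize.intersect_platform_features([a, b])


class TestQuantileNormalize:
    def test_identical_samples_are_a_fixed_point(self):
        col = np.array([1.0, 5.0, 3.0, 2.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = harmonize.quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_two_sample_worked_example(self):
        m = make_matrix(np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]]))
        out = harmonize.quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(),
                           np.array([[2.0, 2.0], [3.0, 3.0], [4.0, 4.0]]))

    def test_columns_share_distribution_and_preserve_ranks(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(8, 2, size=(50, 6)))
        out = harmonize.quantile_normalize(m)
        x = out.values.to_numpy()
        ref = np.sort(x[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(x[:, j]), ref)
        for j in range(6):
            rho = stats.spearmanr(m.values.to_numpy()[:, j], x[:, j])[0]
            assert rho == pytest.approx(1.0)

    def test_ties_get_mean_of_reference_quantiles(self):
        m = make_matrix(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
        out = harmonize.quantile_normalize(m)
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        tied = 0.5 * (ref[0] + ref[1])
        assert out.values.iloc[0, 0] == pytest.approx(tied)
        assert out.values.iloc[1, 0] == pytest.approx(tied)

    def test_normalizing_twice_equals_once(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(8, 1, size=(40, 5)))
        once = harmonize.quantile_normalize(m)
        twice = harmonize.quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_missing_values_rejected(self):
        vals = np.ones((3, 2))
        vals[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            harmonize.quantile_normalize(make_matrix(vals))


class TestMedianPolish:
    def test_additive_matrix_gives_exact_column_effects(self):
        row = np.array([0.0, 1.0, 2.0, 3.0])
        col = np.array([10.0, 11.0, 12.0])
        x = row[:, None] + col[None, :]
        probes = pd.DataFrame(x, index=[f"p{i}" for i in range(4)],
                              columns=["s1", "s2", "s3"])
        mapping = pd.Series("g1", index=probes.index)
        out = harmonize.median_polish_summarize(probes, mapping)
        # summaries differ from col by a constant (overall + median row effect)
        diffs = out.loc["g1"].to_numpy() - col
        assert np.allclose(diffs, diffs[0])

    def test_single_probe_gene_passes_through(self):
        probes = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p1"], columns=list("abc"))
        out = harmonize.median_polish_summarize(
            probes, pd.Series("g", index=["p1"])
        )
        assert np.allclose(out.loc["g"].to_numpy(), [1.0, 2.0, 3.0])

    def test_single_outlier_cell_barely_moves_the_summary(self):
        rng = np.random.default_rng(3)
        row = rng.normal(0, 1, 4)
        col = rng.normal(8, 1, 3)
        clean = row[:, None] + col[None, :]
        dirty = clean.copy()
        dirty[1, 1] += 10.0
        frames = {}
        for name, x in (("clean", clean), ("dirty", dirty)):
            probes = pd.DataFrame(x, index=[f"p{i}" for i in range(4)],
                                  columns=["s1", "s2", "s3"])
            frames[name] = harmonize.median_polish_summarize(
                probes, pd.Series("g", index=probes.index), tol=1e-9,
                max_iter=50,
            )
        assert np.allclose(frames["clean"].loc["g"], frames["dirty"].loc["g"],
                           atol=0.05)

    def test_non_finite_input_rejected(self):
        probes = pd.DataFrame([[1.0, np.inf]], index=["p1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="finite"):
            harmonize.median_polish_summarize(
                probes, pd.Series("g", index=["p1"])
            )


class TestRleScreen:
    def test_identical_samples_give_zero_rle_and_no_flags(self):
        col = np.arange(5.0)
        m = make_matrix(np.column_stack([col] * 4),
                        datasets=["d1", "d1", "d2", "d2"])
        rep = harmonize.rle_screen(m)
        assert np.allclose(rep.per_sample["rle_median"], 0.0)
        assert rep.flagged_datasets() == []

    def test_globally_shifted_minority_dataset_is_flagged(self):
        rng = np.random.default_rng(4)
        base = rng.normal(8, 0.3, size=(1000, 20))
        base[:, 16:] += 1.0  # dataset d5 (1 of 5) shifted by +1 log2
        datasets = [f"d{1 + i // 4}" for i in range(20)]
        m = make_matrix(base, datasets=datasets)
        rep = harmonize.rle_screen(m, bias_threshold=0.15)
        assert rep.flagged_datasets() == ["d5"]

    def test_infinite_threshold_flags_nothing(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(8, 1, size=(30, 6)) + np.arange(6),
                        datasets=[f"d{i}" for i in range(6)])
        rep = harmonize.rle_screen(m, bias_threshold=np.inf)
        assert rep.flagged_datasets() == []


class TestArrayQc:
    def test_identical_samples_have_unit_scale_factor(self):
        col = np.linspace(4, 12, 50)
        m = make_matrix(np.column_stack([col] * 5))
        qc = harmonize.array_qc_metrics(m)
        assert np.allclose(qc["scale_factor"], 1.0)

    def test_doubled_sample_has_half_scale_factor(self):
        col = np.linspace(4, 12, 200)
        mats = [col, col, col, col + 1.0]  # +1 log2 = doubled linear scale
        m = make_matrix(np.column_stack(mats))
        qc = harmonize.array_qc_metrics(m)
        assert qc["scale_factor"].iloc[3] == pytest.approx(0.5, rel=1e-6)
        assert qc["scale_factor"].iloc[0] == pytest.approx(1.0, rel=1e-6)

    def test_low_detect_threshold_means_everything_detected(self):
        m = make_matrix(np.full((10, 3), 8.0))
        qc = harmonize.array_qc_metrics(m, detect_threshold=0.0)
        assert np.allclose(qc["fraction_detected"], 1.0)


class TestPcaBatchScore:
    @staticmethod
    def _simulated(batch_sd, seed=6):
        from urimark.containers import CLASS_DKD_GLOM, CLASS_NORMAL_GLOM
        from urimark.simulate import (
            CompendiumConfig, PlantedSignature, simulate_compendium,
        )

        cfg = CompendiumConfig(
            n_genes=300,
            tissue_classes=(CLASS_DKD_GLOM, CLASS_NORMAL_GLOM),
            datasets_per_class=3,
            samples_per_dataset=4,
            batch_shift_sd=batch_sd,
            planted_sets={
                "sig": PlantedSignature(
                    n_genes=40, target_classes=(CLASS_DKD_GLOM,),
                    log2_effect=3.0,
                )
            },
            seed=seed,
        )
        return simulate_compendium(cfg)[0]

    def test_strong_biology_without_batch_is_not_flagged(self):
        rep = harmonize.pca_batch_score(self._simulated(0.0))
        assert rep.batch_flag is False
        assert rep.biology_r2[0] > 0.5

    def test_dominant_batch_shift_is_flagged(self):
        rep = harmonize.pca_batch_score(self._simulated(3.0))
        assert rep.batch_flag is True

    def test_single_dataset_reports_zero_batch_r2(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(8, 1, (50, 6)),
                        classes=["A", "A", "A", "B", "B", "B"])
        rep = harmonize.pca_batch_score(m)
        assert np.allclose(rep.batch_r2, 0.0)
        assert rep.batch_flag is False

    def test_flag_invariant_to_gene_and_sample_reordering(self):
        m = self._simulated(3.0)
        rep = harmonize.pca_batch_score(m)
        rng = np.random.default_rng(8)
        gene_perm = list(rng.permutation(m.values.index))
        sample_perm = list(rng.permutation(m.values.columns))
        shuffled = m.subset_genes(gene_perm).subset_samples(sample_perm)
        rep2 = harmonize.pca_batch_score(shuffled)
        assert rep.batch_flag == rep2.batch_flag
        assert np.allclose(np.sort(rep.batch_r2), np.sort(rep2.batch_r2),
                           atol=1e-8)

    def test_too_many_pcs_rejected(self):
        m = make_matrix(np.random.default_rng(9).normal(size=(20, 4)))
        with pytest.raises(ValidationError, match="n_pcs"):
            harmonize.pca_batch_score(m, n_pcs=5)
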