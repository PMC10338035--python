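"""QC filters, plate correction, truncated-normal imputation, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kidbioage.preprocess import (
    ABOVE_LOQ2,
    BELOW_LOQ1,
    IN_RANGE,
    OmicsBlock,
    PreprocessError,
    filter_quantifiable,
    impute_truncated,
    median_fold_change_normalize,
    plate_center,
    scale_features,
)
from tests.conftest import make_block


class TestFilterQuantifiable:
    def test_protein_with_quarter_in_linear_range_dropped(self):
        # 25% of 20 values inside [LOQ1, LOQ2] -> not >30% -> dropped
        vals = np.concatenate([np.full(5, 5.0), np.full(15, 99.0)])[:, None]
        block = make_block(vals, loq1=[0.0], loq2=[10.0])
        out, report = filter_quantifiable(block, "protein")
        assert out.n_features == 0
        assert report.dropped_features == [("f0", "linear_range_le_30pct")]

    def test_protein_just_above_threshold_kept(self):
        vals = np.concatenate([np.full(7, 5.0), np.full(13, 99.0)])[:, None]  # 35% in range
        block = make_block(vals, loq1=[0.0], loq2=[10.0])
        out, _ = filter_quantifiable(block, "protein")
        assert out.n_features == 1

    def test_metabolite_requires_both_conditions(self):
        # CV 35% but only 10% below LOD -> retained; CV 35% and 40% below LOD -> dropped
        n = 10
        vals = np.column_stack([
            np.concatenate([np.full(1, -1.0), np.full(9, 5.0)]),
            np.concatenate([np.full(4, -1.0), np.full(6, 5.0)]),
        ])
        block = make_block(vals, cv_percent=[35.0, 35.0], lod=[0.0, 0.0])
        out, report = filter_quantifiable(block, "serum_metabolite")
        assert list(out.values.columns) == ["f0"]
        assert report.dropped_features == [("f1", "cv_gt_30_and_below_lod_gt_30pct")]

    def test_all_clean_features_pass_unchanged(self):
        block = make_block(np.random.default_rng(0).normal(5, 1, (8, 3)),
                           cv_percent=[5.0] * 3, lod=[0.0] * 3)
        out, report = filter_quantifiable(block, "serum_metabolite")
        pd.testing.assert_frame_equal(out.values, block.values)
        assert report.dropped_features == []

    def test_transcript_sample_filter_runs_before_feature_filter(self):
        block = make_block(np.zeros((4, 3)) + 1.0, call_rate=[0.5, 0.005, 0.9])
        block.sample_meta = pd.DataFrame({"call_rate": [0.9, 0.2, 0.95, 0.99]}, index=block.values.index)
        out, report = filter_quantifiable(block, "transcript")
        assert ("s1", "sample_call_rate_lt_40pct") in report.dropped_samples
        assert ("f1", "feature_call_rate_lt_1pct") in report.dropped_features
        assert out.values.shape == (3, 2)

    def test_missing_metadata_column_names_rule(self):
        block = make_block(np.ones((4, 2)))
        with pytest.raises(PreprocessError, match="loq1.*protein"):
            filter_quantifiable(block, "protein")

    def test_feature_drops_commute(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(5, 2, (20, 6))
        block = make_block(vals, cv_percent=[5, 40, 40, 10, 50, 5],
                           lod=list(np.quantile(vals, 0.4, axis=0)))
        a, _ = filter_quantifiable(block, "serum_metabolite")
        # applying the rule feature-by-feature yields the same survivors
        survivors = []
        for f in block.values.columns:
            single = block.subset_features([f])
            kept, _ = filter_quantifiable(single, "serum_metabolite")
            survivors.extend(kept.values.columns)
        assert list(a.values.columns) == survivors


class TestPlateCenter:
    def _two_plate_block(self):
        vals = np.array([[5.0], [5.0], [7.0], [7.0]])
        block = make_block(vals)
        block.sample_plates = pd.Series(["A", "A", "B", "B"], index=block.values.index)
        return block

    def test_plate_means_forced_to_grand_mean(self):
        out = plate_center(self._two_plate_block())
        assert np.allclose(out.values.to_numpy().ravel(), 6.0)

    def test_single_plate_is_identity(self):
        block = make_block(np.random.default_rng(1).normal(size=(5, 3)))
        block.sample_plates = pd.Series(["A"] * 5, index=block.values.index)
        out = plate_center(block)
        pd.testing.assert_frame_equal(out.values, block.values)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        block = make_block(rng.normal(size=(12, 4)))
        block.sample_plates = pd.Series(rng.choice(["A", "B", "C"], 12), index=block.values.index)
        once = plate_center(block)
        twice = plate_center(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(3)
        block = make_block(rng.normal(5, 2, size=(30, 4)))
        block.sample_plates = pd.Series(rng.choice(["A", "B", "C"], 30), index=block.values.index)
        out = plate_center(block)
        np.testing.assert_allclose(out.values.mean(axis=0), block.values.mean(axis=0))


class TestImputeTruncated:
    def _censored_block(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        vals = rng.normal(5, 1, (n, 2))
        block = make_block(vals, loq1=[4.0, 3.5], loq2=[6.5, 7.0])
        cens = pd.DataFrame(IN_RANGE, index=block.values.index, columns=block.values.columns)
        for f in block.values.columns:
            lo = block.values[f] < block.feature_meta.at[f, "loq1"]
            hi = block.values[f] > block.feature_meta.at[f, "loq2"]
            cens.loc[lo, f] = BELOW_LOQ1
            cens.loc[hi, f] = ABOVE_LOQ2
        block.values = block.values.mask(cens != IN_RANGE)
        block.censored = cens
        return block

    def test_imputed_values_respect_bounds_and_leave_observed_cells(self):
        block = self._censored_block()
        before = block.values.copy()
        out, report = impute_truncated(block, seed=9)
        assert report.imputed_cell_count == int((block.censored != IN_RANGE).sum().sum())
        for f in out.values.columns:
            lo = block.censored[f] == BELOW_LOQ1
            hi = block.censored[f] == ABOVE_LOQ2
            assert (out.values.loc[lo, f] <= block.feature_meta.at[f, "loq1"]).all()
            assert (out.values.loc[hi, f] >= block.feature_meta.at[f, "loq2"]).all()
            untouched = block.censored[f] == IN_RANGE
            pd.testing.assert_series_equal(out.values.loc[untouched, f], before.loc[untouched, f])

    def test_deterministic_given_seed(self):
        a, _ = impute_truncated(self._censored_block(), seed=4)
        b, _ = impute_truncated(self._censored_block(), seed=4)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_no_censored_cells_is_identity(self):
        block = make_block(np.random.default_rng(0).normal(5, 1, (10, 2)), loq1=[0.0, 0.0], loq2=[99.0, 99.0])
        block.censored = pd.DataFrame(IN_RANGE, index=block.values.index, columns=block.values.columns)
        out, report = impute_truncated(block, seed=0)
        pd.testing.assert_frame_equal(out.values, block.values)
        assert report.imputed_cell_count == 0

    def test_lower_tail_mean_matches_truncated_normal_moment(self):
        """With mu = LOQ1 and sigma = 1, imputed lower-tail values average to
        mu − phi(0)/Phi(0) = mu − 2·phi(0)."""
        rng = np.random.default_rng(11)
        n_obs, n_cens = 4000, 4000
        observed = stats.truncnorm.rvs(0, np.inf, loc=5.0, scale=1.0, size=n_obs, random_state=rng)
        # in-range part of a N(5,1) clipped at LOQ1=5: mu-hat and sigma-hat are
        # biased for the full normal, so plant moments directly instead:
        vals = np.concatenate([observed, np.full(n_cens, np.nan)])[:, None]
        block = make_block(vals, loq1=[5.0], loq2=[999.0])
        cens = pd.DataFrame(IN_RANGE, index=block.values.index, columns=["f0"])
        cens.iloc[n_obs:, 0] = BELOW_LOQ1
        block.censored = cens
        out, _ = impute_truncated(block, seed=21)
        mu_hat = observed.mean()
        sd_hat = observed.std(ddof=1)
        expected = mu_hat - sd_hat * stats.norm.pdf((5.0 - mu_hat) / sd_hat) / stats.norm.cdf((5.0 - mu_hat) / sd_hat)
        got = out.values.iloc[n_obs:, 0].mean()
        assert got == pytest.approx(expected, abs=0.05)

    def test_feature_with_too_few_in_range_values_dropped(self):
        vals = np.array([[1.0], [np.nan], [np.nan], [np.nan], [2.0]])
        block = make_block(vals, loq1=[3.0], loq2=[99.0])
        cens = pd.DataFrame([[IN_RANGE], [BELOW_LOQ1], [BELOW_LOQ1], [BELOW_LOQ1], [IN_RANGE]],
                            index=block.values.index, columns=["f0"])
        block.censored = cens
        out, report = impute_truncated(block, seed=0)
        assert out.n_features == 0
        assert report.dropped_features == [("f0", "lt_3_in_range_values")]


class TestMedianFoldChange:
    def test_sample_at_twice_reference_gets_factor_two(self):
        ref = np.array([1.0, 2.0, 4.0, 8.0])
        vals = np.vstack([ref, ref, ref, 2.0 * ref])
        block = make_block(vals)
        _, factors = median_fold_change_normalize(block, reference=pd.Series(ref, index=block.values.columns))
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 1.0, 1.0, 2.0])

    def test_normalized_doubled_sample_equals_reference_pre_offset(self):
        ref = np.array([1.0, 2.0, 4.0, 8.0])
        vals = np.vstack([ref, 2.0 * ref])
        block = make_block(vals)
        out, factors = median_fold_change_normalize(block, reference=pd.Series(ref, index=block.values.columns))
        # both rows identical after dividing by their dilution factors
        np.testing.assert_allclose(out.values.iloc[0], out.values.iloc[1])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(0, 0.5, (6, 5))
        block = make_block(vals)
        _, f1 = median_fold_change_normalize(block)
        scaled = block.copy()
        scaled.values.iloc[2] *= 3.0
        ref = block.values.median(axis=0)  # hold the reference fixed
        _, f_a = median_fold_change_normalize(block, reference=ref)
        _, f_b = median_fold_change_normalize(scaled, reference=ref)
        assert f_b.iloc[2] == pytest.approx(3.0 * f_a.iloc[2])

    def test_nonpositive_reference_raises(self):
        block = make_block(np.ones((3, 2)))
        with pytest.raises(PreprocessError, match="reference"):
            median_fold_change_normalize(block, reference=pd.Series([1.0, 0.0], index=block.values.columns))

    def test_all_zero_sample_raises_with_sample_name(self):
        vals = np.ones((3, 2))
        vals[1] = 0.0
        block = make_block(vals)
        with pytest.raises(PreprocessError, match="s1"):
            median_fold_change_normalize(block)


class TestScaleFeatures:
    def test_unit_scaling_and_scaler_consistency(self):
        block = make_block(np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]]))
        out, scaler = scale_features(block)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0)
        pd.testing.assert_frame_equal(scaler.transform(block.values), out.values)

    def test_constant_column_dropped(self):
        block = make_block(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        out, scaler = scale_features(block)
        assert list(out.values.columns) == ["f0"]
        assert list(scaler.means.index) == ["f0"]

    def test_remaining_missing_values_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0], [3.0, 4.0]])
        with pytest.raises(PreprocessError, match="imputed"):
            scale_features(make_block(vals))
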