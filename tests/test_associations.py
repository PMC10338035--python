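"""Marker preparation, adjusted regressions, BH FDR, partial correlations."""

import numpy as np
import pandas as pd
import pytest

from kidbioage.associations import (
    AssociationError,
    AssociationSpec,
    fdr_adjust,
    partial_correlation,
    prepare_markers,
    run_association,
    sensitivity_suite,
    transform_outcomes,
)
from tests.oracles import bh_stepup_bruteforce


def simulated_data(n=400, effect=0.5, seed=0, binary_outcome=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age_years": rng.uniform(5, 12, n),
            "sex": rng.choice(["male", "female"], n),
            "ethnicity": rng.choice(["white_european", "other"], n, p=[0.9, 0.1]),
            "centre": rng.choice([f"centre_{i}" for i in range(1, 5)], n),
            "marker": rng.normal(0, 1, n),
        }
    )
    lin = effect * df["marker"] + 0.1 * (df["sex"] == "female")
    if binary_outcome:
        df["outcome"] = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
    else:
        df["outcome"] = lin + rng.normal(0, 1, n)
    return df


class TestPrepareMarkers:
    def _telomere(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"relative_ts": rng.lognormal(0, 0.2, 50)}, index=[f"s{i}" for i in range(50)])

    def test_telomere_flip_and_unit_sd(self):
        tel = self._telomere()
        markers = prepare_markers(tel, deltas={})
        col = markers["telomere_shortening"]
        assert col.std(ddof=1) == pytest.approx(1.0)
        assert np.corrcoef(col, tel["relative_ts"])[0, 1] == pytest.approx(-1.0)

    def test_delta_age_passes_through_in_years(self):
        preds = pd.DataFrame({"delta_age": [0.5, -0.2]}, index=["a", "b"])
        markers = prepare_markers(None, deltas={"clockx": preds})
        pd.testing.assert_series_equal(markers["clockx_delta_age"], preds["delta_age"], check_names=False)

    def test_epigenetic_column_converted_to_delta(self):
        epi = pd.Series([8.5, 7.0], index=["a", "b"])
        chrono = pd.Series([8.0, 7.5], index=["a", "b"])
        markers = prepare_markers(None, deltas={}, epigenetic=epi, chronological=chrono)
        np.testing.assert_allclose(markers["epigenetic_delta_age"], [0.5, -0.5])

    def test_zero_sd_telomere_raises(self):
        tel = pd.DataFrame({"relative_ts": np.ones(10)})
        with pytest.raises(AssociationError, match="zero SD"):
            prepare_markers(tel, deltas={})


class TestTransformOutcomes:
    def test_zscores_pass_through_others_scaled(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"zbmi": rng.normal(0, 1.3, 100), "fat_pct": rng.normal(25, 6, 100)})
        out = transform_outcomes(df, continuous=["zbmi", "fat_pct"])
        pd.testing.assert_series_equal(out["zbmi"], df["zbmi"])
        assert out["fat_pct"].std(ddof=1) == pytest.approx(1.0)
        assert out["fat_pct"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_cbcl_log_transform_maps_zero_to_zero_before_scaling(self):
        df = pd.DataFrame({"cbcl_externalizing": [0, 1, 3, 7, 20]})
        out = transform_outcomes(df, continuous=["cbcl_externalizing"])
        raw_logged = np.log(df["cbcl_externalizing"] + 1.0)
        expected = (raw_logged - raw_logged.mean()) / raw_logged.std(ddof=1)
        pd.testing.assert_series_equal(out["cbcl_externalizing"], expected)
        assert np.log(0 + 1.0) == 0.0


class TestRunAssociation:
    def test_recovers_planted_linear_effect(self):
        data = simulated_data(n=800, effect=0.5, seed=2)
        spec = AssociationSpec(exposure="marker", outcome="outcome")
        res = run_association(spec, data)
        assert res.ci_low < 0.5 < res.ci_high
        assert res.estimate == pytest.approx(0.5, abs=0.12)
        assert res.n == 800

    def test_logistic_reports_odds_ratio(self):
        data = simulated_data(n=1500, effect=0.7, seed=3, binary_outcome=True)
        spec = AssociationSpec(exposure="marker", outcome="outcome", family="logistic")
        res = run_association(spec, data)
        assert res.ci_low < np.exp(0.7) < res.ci_high

    def test_listwise_deletion_counts_complete_cases(self):
        data = simulated_data(n=100, seed=4)
        data.loc[data.index[:10], "marker"] = np.nan
        res = run_association(AssociationSpec(exposure="marker", outcome="outcome"), data)
        assert res.n == 90

    def test_exposure_duplicated_as_covariate_rejected(self):
        with pytest.raises(AssociationError, match="covariates"):
            AssociationSpec(exposure="age_years", outcome="outcome")

    def test_collinear_covariates_named(self):
        data = simulated_data(n=100, seed=5)
        data["marker_copy"] = data["marker"] * 2.0
        spec = AssociationSpec(
            exposure="marker", outcome="outcome", covariates=("age_years", "sex", "marker_copy")
        )
        with pytest.raises(AssociationError, match="marker.*marker_copy"):
            run_association(spec, data)

    def test_marker_as_dependent_direction(self):
        data = simulated_data(n=500, effect=0.0, seed=6)
        data["risk"] = np.random.default_rng(6).normal(size=500)
        data["marker"] = data["marker"] + 0.4 * data["risk"]
        spec = AssociationSpec(exposure="risk", outcome="marker", direction="marker_as_dependent")
        res = run_association(spec, data)
        assert res.ci_low < 0.4 < res.ci_high

    def test_intercept_absorbs_constant_marker_shift(self):
        data = simulated_data(n=300, effect=0.5, seed=7)
        res_a = run_association(AssociationSpec(exposure="marker", outcome="outcome"), data)
        shifted = data.copy()
        shifted["marker"] = shifted["marker"] + 100.0
        res_b = run_association(AssociationSpec(exposure="marker", outcome="outcome"), shifted)
        assert res_a.estimate == pytest.approx(res_b.estimate, rel=1e-9)
        assert res_a.p == pytest.approx(res_b.p, rel=1e-6)


class FakeResult:
    def __init__(self, p):
        self.p = p
        self.q = None


class TestFDR:
    def test_worked_stepup_example(self):
        results = [FakeResult(p) for p in (0.01, 0.02, 0.03, 0.04)]
        fdr_adjust(results)
        assert [r.q for r in results] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_equals_q(self):
        results = [FakeResult(0.037)]
        fdr_adjust(results)
        assert results[0].q == pytest.approx(0.037)

    def test_empty_family_raises(self):
        with pytest.raises(AssociationError, match="empty"):
            fdr_adjust([])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            ps = rng.random(rng.integers(1, 40))
            results = [FakeResult(p) for p in ps]
            fdr_adjust(results)
            expected = bh_stepup_bruteforce(ps)
            np.testing.assert_allclose([r.q for r in results], expected, atol=1e-12)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(13)
        ps = rng.random(100)
        results = [FakeResult(p) for p in ps]
        fdr_adjust(results)
        order = np.argsort(ps)
        qs = np.array([r.q for r in results])[order]
        assert (np.diff(qs) >= -1e-15).all()


class TestPartialCorrelation:
    def test_identity_with_irrelevant_covariate(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=50)
        cov = pd.DataFrame({"z": rng.normal(size=50)})
        r, p = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0)

    def test_confounder_induced_correlation_removed(self):
        rng = np.random.default_rng(21)
        z = rng.normal(size=2000)
        x = z + rng.normal(scale=1.0, size=2000)
        y = z + rng.normal(scale=1.0, size=2000)
        marginal = np.corrcoef(x, y)[0, 1]
        r, _ = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert marginal > 0.3
        assert abs(r) < 0.08

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(22)
        df = pd.DataFrame({"x": rng.normal(size=80), "y": rng.normal(size=80), "z": rng.normal(size=80)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        r, p = partial_correlation(df["x"], df["y"], df[["z"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_categorical_covariate_coded_as_indicators(self):
        rng = np.random.default_rng(23)
        centre = rng.choice(["a", "b", "c"], 600)
        shift = pd.Series({"a": 0.0, "b": 2.0, "c": -1.0})
        x = shift[centre].to_numpy() + rng.normal(size=600)
        y = shift[centre].to_numpy() + rng.normal(size=600)
        r_naive = np.corrcoef(x, y)[0, 1]
        r, _ = partial_correlation(x, y, pd.DataFrame({"centre": centre}))
        assert r_naive > 0.3
        assert abs(r) < 0.12

    def test_zero_residual_variance_raises(self):
        z = np.arange(10.0)
        with pytest.raises(AssociationError, match="residual"):
            partial_correlation(z, np.random.default_rng(0).normal(size=10), pd.DataFrame({"z": z}))


class TestSensitivitySuite:
    def test_empty_extra_covariates_variant_is_noop(self):
        data = simulated_data(n=300, effect=0.4, seed=30)
        spec = AssociationSpec(exposure="marker", outcome="outcome")
        base = run_association(spec, data)
        out = sensitivity_suite([spec], data, cell_columns=(), variants=("cell_adjusted",))
        assert len(out) == 1
        assert out[0].estimate == pytest.approx(base.estimate)
        assert out[0].p == pytest.approx(base.p)

    def test_sex_specific_effect_recovered_in_stratum(self):
        rng = np.random.default_rng(31)
        n = 2000
        data = simulated_data(n=n, effect=0.0, seed=31)
        girls = (data["sex"] == "female").to_numpy()
        data["outcome"] = data["outcome"] + np.where(girls, 0.6, 0.0) * data["marker"]
        spec = AssociationSpec(exposure="marker", outcome="outcome")
        out = sensitivity_suite([spec], data, variants=("sex_stratified",))
        by_stratum = {r.spec.stratum[1]: r for r in out}
        assert by_stratum["female"].ci_low < 0.6 < by_stratum["female"].ci_high
        assert abs(by_stratum["male"].estimate) < 0.15

    def test_homogeneous_effect_consistent_across_centres(self):
        data = simulated_data(n=3000, effect=0.5, seed=32)
        spec = AssociationSpec(exposure="marker", outcome="outcome")
        out = sensitivity_suite([spec], data, variants=("centre_stratified",))
        assert len(out) == 4
        assert all(r.estimate > 0 for r in out)

    def test_too_small_stratum_skipped(self):
        data = simulated_data(n=60, effect=0.5, seed=33)
        data.loc[data.index[:58], "centre"] = "centre_1"
        data.loc[data.index[58:], "centre"] = "centre_tiny"
        spec = AssociationSpec(exposure="marker", outcome="outcome")
        out = sensitivity_suite([spec], data, variants=("centre_stratified",))
        strata = {r.spec.stratum[1] for r in out}
        assert "centre_tiny" not in strata
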