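import numpy as np
import pandas as pd
import pytest

from bolusco import (
    InsufficientDataError,
    StratificationError,
    UndefinedCorrelationError,
    ValidationError,
    classify_r,
    contrast_interval,
    gender_contrast,
    normality_flag,
    ntile_stratify,
    pearson_with_class,
    relative_difference,
    summarize,
    t_interval,
    vif_screen,
)
from bolusco.evaluation import _vif_values


class TestRelativeDifference:
    def test_cohort_means_example(self):
        assert relative_difference(3.24, 5.05) == pytest.approx(-0.3584,
                                                                abs=1e-4)

    def test_identity_and_doubling(self):
        assert relative_difference(4.2, 4.2) == 0.0
        assert relative_difference(8.4, 4.2) == 1.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            relative_difference(5.0, 0.0)


class TestCorrelation:
    @pytest.mark.parametrize("r,label", [
        (0.1, "none"), (0.3, "weak"), (0.45, "weak"), (0.5, "moderate"),
        (0.66, "moderate"), (0.70, "strong"), (0.9, "very_strong"),
        (1.0, "very_strong"), (-0.66, "moderate"),
    ])
    def test_strength_bins_upper_closed(self, r, label):
        assert classify_r(r) == label

    def test_identity_is_very_strong(self):
        x = np.arange(10.0)
        r, label, p = pearson_with_class(x, x)
        assert r == pytest.approx(1.0)
        assert label == "very_strong"
        assert p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_class(np.ones(5), np.arange(5.0))


class TestSummaries:
    """The t-interval machinery reproduces the printed cohort table rows."""

    @pytest.mark.parametrize("mean,sd,n,lo,hi", [
        (84.16, 19.83, 37, 77.55, 90.77),    # weight, kg
        (172.89, 10.28, 37, 169.46, 176.32),  # height, cm
    ])
    def test_t_interval_reproduces_cohort_rows(self, mean, sd, n, lo, hi):
        got_lo, got_hi = t_interval(mean, sd, n)
        assert got_lo == pytest.approx(lo, abs=5e-3)
        assert got_hi == pytest.approx(hi, abs=5e-3)

    @pytest.mark.parametrize("diff,se,df,lo,hi", [
        (15.58, 2.21, 35, 11.09, 20.07),     # height gender difference
        (0.33, 0.07, 35, 0.19, 0.47),        # BSA gender difference
        (-0.25, 0.07, 35, -0.39, -0.11),     # contrast dose per kg difference
    ])
    def test_contrast_interval_reproduces_cohort_rows(self, diff, se, df, lo, hi):
        got_lo, got_hi = contrast_interval(diff, se, df)
        assert got_lo == pytest.approx(lo, abs=5e-3)
        assert got_hi == pytest.approx(hi, abs=5e-3)

    def test_summarize_constant_vector_collapses(self):
        row = summarize(np.full(8, 3.5), variable="x")
        assert row.sd == 0.0
        assert row.ci_low == row.ci_high == row.mean == 3.5

    def test_summarize_needs_two(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])

    def test_gender_contrast_pooled_df(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(10, 2, 20), rng.normal(8, 2, 17)
        gc = gender_contrast(a, b)
        assert gc.df == 35
        assert gc.ci_low <= gc.difference <= gc.ci_high

    def test_gender_contrast_identical_groups(self):
        x = np.arange(10.0)
        gc = gender_contrast(x, x)
        assert gc.difference == pytest.approx(0.0)
        assert gc.ci_low < 0 < gc.ci_high
        assert gc.p_value == pytest.approx(1.0)


class TestNormality:
    def test_frozen_seed_flags(self):
        rng = np.random.default_rng(0)
        assert normality_flag(rng.normal(size=500)) == "normal"
        assert normality_flag(rng.exponential(size=500)) == "non_normal"

    def test_constant_vector_degenerate(self):
        assert normality_flag(np.ones(10)) == "non_normal"

    def test_needs_five(self):
        with pytest.raises(InsufficientDataError):
            normality_flag([1.0, 2.0, 3.0])


class TestNtiles:
    def test_exact_thirds(self):
        np.testing.assert_array_equal(
            ntile_stratify(np.arange(1, 10), 3),
            [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_ceiling_rule_sizes(self):
        labels = ntile_stratify(np.arange(1, 11), 3)
        sizes = [int(np.sum(labels == i)) for i in (1, 2, 3)]
        assert sizes == [3, 3, 4]

    def test_one_per_group_when_k_equals_n(self):
        labels = ntile_stratify(np.array([5.0, 1.0, 3.0]), 3)
        assert sorted(labels) == [1, 2, 3]

    def test_ties_share_label(self):
        labels = ntile_stratify(np.array([1.0, 2.0, 2.0, 9.0]), 2)
        assert labels[1] == labels[2]

    def test_too_many_groups(self):
        with pytest.raises(StratificationError):
            ntile_stratify(np.arange(3.0), 5)


class TestVIFScreen:
    def orthogonal_design(self, n=40):
        rng = np.random.default_rng(2)
        x1 = np.linspace(-1, 1, n)
        x2 = np.sign(np.arange(n) % 2 - 0.5).astype(float)
        x2 -= x2.mean()
        x2 -= x1 * (x2 @ x1) / (x1 @ x1)       # exactly orthogonal to x1
        y = 2.0 * x1 + 1.5 * x2 + rng.normal(0, 0.1, n)
        return y, pd.DataFrame({"x1": x1, "x2": x2})

    def test_orthogonal_predictors_retained_with_unit_vif(self):
        y, x = self.orthogonal_design()
        vifs = _vif_values(x)
        assert vifs["x1"] == pytest.approx(1.0, abs=1e-6)
        result = vif_screen(y, x)
        assert set(result.retained) == {"x1", "x2"}

    def test_duplicated_column_removed_first(self):
        y, x = self.orthogonal_design()
        x = x.assign(x1_copy=x["x1"])
        with pytest.warns(UserWarning):
            result = vif_screen(y, x)
        assert "x2" in result.retained
        assert not {"x1", "x1_copy"} <= set(result.retained)

    def test_vif_closed_form_at_known_correlation(self):
        """Sample correlation exactly 0.9 gives VIF = 1/(1-0.81) = 5.263."""
        n = 30
        z1 = np.linspace(-1, 1, n)
        z1 = (z1 - z1.mean()) / np.std(z1)
        rng = np.random.default_rng(8)
        raw = rng.normal(size=n)
        raw = raw - raw.mean()
        raw -= z1 * (raw @ z1) / (z1 @ z1)      # orthogonalise
        z2 = raw / np.std(raw)
        x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
        vifs = _vif_values(pd.DataFrame({"a": z1, "b": x2}))
        assert vifs["a"] == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-9)

    def test_insignificant_predictor_dropped(self):
        rng = np.random.default_rng(3)
        n = 60
        x = pd.DataFrame({"signal": np.linspace(0, 1, n),
                          "junk": rng.normal(size=n)})
        y = 3.0 * x["signal"].to_numpy() + rng.normal(0, 0.2, n)
        result = vif_screen(y, x)
        assert result.retained == ["signal"]
        assert result.dropped[0][0] == "junk"

    def test_pure_noise_can_empty_the_model(self):
        rng = np.random.default_rng(4)
        n = 50
        x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.normal(size=n)
        result = vif_screen(y, x)
        assert result.retained == [] or all(
            p < 0.05 for p in result.p_values.values())

    def test_needs_enough_observations(self):
        with pytest.raises(InsufficientDataError):
            vif_screen(np.arange(3.0),
                       pd.DataFrame({"a": [1, 2, 3], "b": [3, 1, 2]}))
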