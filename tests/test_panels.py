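"""Metabolite preprocessing: hand-checked examples and chain invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietmwas import (
    drop_overlapping,
    filter_missingness,
    impute_run_day_minimum,
    inverse_normal_panel,
    inverse_normal_transform,
    log_transform_targeted,
    run_day_median_normalize,
)
from conftest import make_panel


class TestRunDayMedianNormalize:
    def test_single_day_divides_by_median(self):
        panel = make_panel([[2.0], [4.0], [6.0]], run_day=["d0"] * 3)
        out = run_day_median_normalize(panel)
        assert out.values.iloc[:, 0].tolist() == [0.5, 1.0, 1.5]

    def test_two_days_use_their_own_medians(self):
        panel = make_panel([[1.0], [3.0], [10.0], [30.0]],
                           run_day=["d0", "d0", "d1", "d1"])
        out = run_day_median_normalize(panel)
        assert out.values.iloc[:, 0].tolist() == [0.5, 1.5, 0.5, 1.5]

    def test_constant_positive_values_become_one(self):
        panel = make_panel(np.full((5, 2), 3.7), run_day=["d0"] * 3 + ["d1"] * 2)
        out = run_day_median_normalize(panel)
        assert (out.values == 1.0).all().all()

    def test_per_day_median_is_one_after_normalization(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.lognormal(1, 0.5, (30, 3)),
                           run_day=[f"d{i % 3}" for i in range(30)])
        out = run_day_median_normalize(panel)
        for _, idx in out.values.groupby(out.run_day).groups.items():
            med = out.values.loc[idx].median()
            assert np.allclose(med, 1.0)

    def test_targeted_panel_rejected(self):
        panel = make_panel([[1.0], [2.0]], platform="targeted", run_day=["d0"] * 2)
        with pytest.raises(ValueError, match="non_targeted"):
            run_day_median_normalize(panel)

    def test_wholly_missing_day_left_missing_with_warning(self):
        panel = make_panel([[np.nan], [np.nan], [4.0], [8.0]],
                           run_day=["d0", "d0", "d1", "d1"])
        out = run_day_median_normalize(panel)
        assert out.values.iloc[:2, 0].isna().all()
        assert any("d0" in w for w in out.warnings)


class TestFilterMissingness:
    def _panel_with_missing(self, n_missing, n=100):
        vals = np.ones((n, 2))
        vals[:n_missing, 0] = np.nan
        return make_panel(vals, run_day=["d0"] * n, steps=["run_day_median_normalize"])

    def test_strictly_more_than_threshold_excluded(self):
        panel, excluded = filter_missingness(self._panel_with_missing(21))
        assert excluded == ["m0"]
        assert list(panel.metabolites) == ["m1"]

    def test_exactly_at_threshold_retained(self):
        panel, excluded = filter_missingness(self._panel_with_missing(20))
        assert excluded == []
        assert list(panel.metabolites) == ["m0", "m1"]

    def test_fully_observed_panel_unchanged(self):
        src = self._panel_with_missing(0)
        panel, excluded = filter_missingness(src)
        assert excluded == []
        pd.testing.assert_frame_equal(panel.values, src.values)

    def test_column_order_preserved(self):
        vals = np.ones((10, 4))
        vals[:5, 1] = np.nan  # 50% missing -> drop m1
        panel, excluded = filter_missingness(make_panel(vals, run_day=["d0"] * 10))
        assert list(panel.metabolites) == ["m0", "m2", "m3"]
        assert excluded == ["m1"]


class TestImputeRunDayMinimum:
    STEPS = ["run_day_median_normalize", "filter_missingness"]

    def test_missing_replaced_by_day_minimum(self):
        panel = make_panel([[np.nan], [5.0], [2.0]], run_day=["d0"] * 3,
                           steps=self.STEPS)
        out = impute_run_day_minimum(panel)
        assert out.values.iloc[:, 0].tolist() == [2.0, 5.0, 2.0]

    def test_wholly_missing_day_falls_back_to_global_minimum(self):
        panel = make_panel([[np.nan], [4.0], [8.0]],
                           run_day=["d0", "d1", "d1"], steps=self.STEPS)
        out = impute_run_day_minimum(panel)
        assert out.values.iloc[0, 0] == 4.0

    def test_no_missing_is_identity(self):
        panel = make_panel([[1.0], [2.0]], run_day=["d0", "d1"], steps=self.STEPS)
        out = impute_run_day_minimum(panel)
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_requires_filter_first(self):
        panel = make_panel([[np.nan], [1.0]], run_day=["d0"] * 2)
        with pytest.raises(ValueError, match="filter_missingness"):
            impute_run_day_minimum(panel)

    def test_never_observed_metabolite_rejected(self):
        panel = make_panel([[np.nan], [np.nan]], run_day=["d0"] * 2,
                           steps=self.STEPS)
        with pytest.raises(ValueError, match="no observed values"):
            impute_run_day_minimum(panel)

    def test_filter_then_impute_leaves_no_missing(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, (40, 5))
        vals[rng.uniform(size=vals.shape) < 0.3] = np.nan
        panel = make_panel(vals, run_day=[f"d{i % 4}" for i in range(40)])
        panel = run_day_median_normalize(panel)
        panel, excluded = filter_missingness(panel)
        if len(panel.metabolites):
            out = impute_run_day_minimum(panel)
            assert not out.values.isna().any().any()
        assert len(panel.metabolites) + len(excluded) == 5


# independent inverse-normal oracle: Wichura's AS241-style rational
# approximation of the standard normal quantile (accurate to ~1e-9)
def _qnorm(p):
    p = np.asarray(p, dtype=float)
    q = p - 0.5
    out = np.empty_like(p)
    central = np.abs(q) <= 0.425
    r = 0.180625 - q[central] ** 2
    num = (((((((2509.0809287301226727 * r + 33430.575583588128105) * r
        + 67265.770927008700853) * r + 45921.953931549871457) * r
        + 13731.693765509461125) * r + 1971.5909503065514427) * r
        + 133.14166789178437745) * r + 3.387132872796366608)
    den = (((((((5226.495278852545703 * r + 28729.085735721942674) * r
        + 39307.89580009271061) * r + 21213.794301586595867) * r
        + 5394.1960214247511077) * r + 687.1870074920579083) * r
        + 42.313330701600911252) * r + 1.0)
    out[central] = q[central] * num / den
    tail = ~central
    pp = np.where(q[tail] < 0, p[tail], 1 - p[tail])
    r = np.sqrt(-np.log(pp))
    inner = r <= 5.0
    rr = np.where(inner, r - 1.6, r - 5.0)
    num = np.where(
        inner,
        (((((((7.7454501427834140764e-4 * rr + 0.0227238449892691845833) * rr
            + 0.24178072517745061177) * rr + 1.27045825245236838258) * rr
            + 3.64784832476320460504) * rr + 5.7694972214606914055) * rr
            + 4.6303378461565452959) * rr + 1.42343711074968357734),
        (((((((2.01033439929228813265e-7 * rr + 2.71155556874348757815e-5) * rr
            + 0.0012426609473880784386) * rr + 0.026532189526576123093) * rr
            + 0.29656057182850489123) * rr + 1.7848265399172913358) * rr
            + 5.4637849111641143699) * rr + 6.6579046435011037772),
    )
    den = np.where(
        inner,
        (((((((1.05075007164441684324e-9 * rr + 5.475938084995344946e-4) * rr
            + 0.0151986665636164571966) * rr + 0.14810397642748007459) * rr
            + 0.68976733498510000455) * rr + 1.6763848301838038494) * rr
            + 2.05319162663775882187) * rr + 1.0),
        (((((((2.04426310338993978564e-15 * rr + 1.4215117583164458887e-7) * rr
            + 1.8463183175100546818e-5) * rr + 7.868691311456132591e-4) * rr
            + 0.0148753612908506148525) * rr + 0.13692988092273580531) * rr
            + 0.59983220655588793769) * rr + 1.0),
    )
    out[tail] = np.sign(q[tail]) * num / den
    return out


class TestInverseNormal:
    def test_three_values_match_blom_hand_calculation(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        assert out == pytest.approx([0.0, -0.8694, 0.8694], abs=5e-5)

    def test_agrees_with_independent_quantile_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, 101)
        from scipy.stats import rankdata
        expected = _qnorm((rankdata(x) - 0.375) / (x.size + 0.25))
        assert np.allclose(inverse_normal_transform(x), expected, atol=1e-8)

    def test_median_of_odd_tie_free_vector_maps_to_zero(self):
        x = np.array([10.0, -3.0, 4.0, 7.0, 0.5])
        out = inverse_normal_transform(x)
        assert out[np.argsort(x)[2]] == pytest.approx(0.0, abs=1e-12)

    def test_mean_near_zero_for_tie_free_input(self):
        rng = np.random.default_rng(3)
        out = inverse_normal_transform(rng.normal(size=200))
        assert abs(out.mean()) < 1e-6

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=3, max_size=40,
                    unique=True),
           st.sampled_from(["exp-scaled", "cube", "affine"]))
    def test_invariant_under_strictly_monotone_transforms(self, xs, kind):
        x = np.array(xs, dtype=float)
        if kind == "exp-scaled":
            y = np.exp(x / 1e6)
        elif kind == "cube":
            y = x**3
        else:
            y = 2.5 * x + 7.0
        assert np.allclose(inverse_normal_transform(x),
                           inverse_normal_transform(y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_panel_transform_requires_imputation_first(self):
        panel = make_panel([[1.0], [2.0]], run_day=["d0"] * 2)
        with pytest.raises(ValueError, match="impute"):
            inverse_normal_panel(panel)


class TestTargetedChain:
    def test_log_of_unit_concentration_is_zero(self):
        panel = make_panel([[1.0], [np.e], [np.e**2]], platform="targeted")
        out = log_transform_targeted(panel)
        assert np.allclose(out.values.iloc[:, 0], [0.0, 1.0, 2.0])

    def test_non_positive_concentration_names_cell(self):
        panel = make_panel([[1.0], [0.0]], platform="targeted")
        with pytest.raises(ValueError, match="S1.*m0"):
            log_transform_targeted(panel)

    def test_non_targeted_panel_rejected(self):
        with pytest.raises(ValueError, match="targeted"):
            log_transform_targeted(make_panel([[1.0]], platform="non_targeted"))

    def test_drop_overlapping_removes_only_listed(self):
        panel = make_panel(np.ones((3, 4)), platform="targeted")
        out = drop_overlapping(panel, ["m1", "m3"])
        assert list(out.metabolites) == ["m0", "m2"]

    def test_drop_overlapping_idempotent(self):
        panel = make_panel(np.ones((3, 4)), platform="targeted")
        once = drop_overlapping(panel, ["m1"])
        twice = drop_overlapping(once, ["m1"])
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_empty_overlap_list_is_identity(self):
        panel = make_panel(np.ones((3, 2)), platform="targeted")
        out = drop_overlapping(panel, [])
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_absent_overlap_id_reported_not_ignored(self):
        panel = make_panel(np.ones((3, 2)), platform="targeted")
        out = drop_overlapping(panel, ["nope"])
        assert any("nope" in w for w in out.warnings)
        assert list(out.metabolites) == ["m0", "m1"]
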