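"""Normalization and filtering behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempomics.omics import (
    MISSING,
    OmicsInputError,
    TimePoint,
    TimeSeriesSet,
    build_omics_object,
)
from tempomics.preprocess import (
    applier,
    boxcox_fit_transform,
    boxcox_transform,
    filter_missing_fraction,
    normalize_to_reference,
    quantile_normalize,
    tag_low_values,
)


def _tss(series, times=None):
    times = times if times is not None else list(range(len(next(iter(series.values())))))
    pts = [TimePoint(str(t), float(t)) for t in times]
    return TimeSeriesSet(pts, {k: np.asarray(v, dtype=float) for k, v in series.items()})


class TestTagLow:
    def test_below_threshold_tagged(self):
        obj = build_omics_object(
            [("s", "a", [0.1], []), ("s", "b", [5.0], [])]
        )
        out, rep = tag_low_values(obj, 0, 1.0)
        assert out.samples["s"]["a"].measurements[0] is MISSING
        assert out.samples["s"]["b"].measurements[0] == 5.0
        assert rep.tagged_low == 1

    def test_vacuous_threshold(self):
        obj = build_omics_object([("s", "a", [0.1], [])])
        out, rep = tag_low_values(obj, 0, -np.inf)
        assert rep.tagged_low == 0
        assert out == obj

    def test_missing_not_double_counted(self):
        obj = build_omics_object([("s", "a", [MISSING], [])])
        out, rep = tag_low_values(obj, 0, 1.0)
        assert rep.tagged_low == 0
        assert out.samples["s"]["a"].measurements[0] is MISSING


class TestMissingFilter:
    def test_removal_above_cutoff(self):
        tss = _tss({"a": [np.nan, np.nan, np.nan, 1.0], "b": [1, 2, 3, 4]})
        out, rep = filter_missing_fraction(tss, 0.5)
        assert "a" not in out.series and "b" in out.series
        assert rep.removed_components[0][0] == "a"

    def test_complete_series_kept_at_zero_cutoff(self):
        tss = _tss({"b": [1, 2, 3, 4]})
        out, _ = filter_missing_fraction(tss, 0.0)
        assert "b" in out.series

    def test_cutoff_one_removes_nothing(self):
        tss = _tss({"a": [np.nan, np.nan, np.nan, np.nan]})
        out, _ = filter_missing_fraction(tss, 1.0)
        assert "a" in out.series

    def test_bad_fraction(self):
        with pytest.raises(OmicsInputError):
            filter_missing_fraction(_tss({"a": [1.0]}), 1.5)


class TestQuantileNormalize:
    def _values(self, obj, sample, comps):
        return [obj.samples[sample][c].measurements[0] for c in comps]

    def test_textbook_rankwise_means(self):
        obj = build_omics_object(
            [("A", c, [v], []) for c, v in zip("xyz", [1.0, 2.0, 3.0])]
            + [("B", c, [v], []) for c, v in zip("xyz", [4.0, 5.0, 6.0])]
        )
        out = quantile_normalize(obj)
        assert self._values(out, "A", "xyz") == [2.5, 3.5, 4.5]
        assert self._values(out, "B", "xyz") == [2.5, 3.5, 4.5]

    def test_identical_samples_fixed_point(self):
        obj = build_omics_object(
            [(s, c, [v], []) for s in "AB" for c, v in zip("xyz", [1.0, 5.0, 9.0])]
        )
        out = quantile_normalize(obj)
        for s in "AB":
            assert self._values(out, s, "xyz") == [1.0, 5.0, 9.0]

    def test_missing_data_variant_hand_oracle(self):
        # A = [1, Missing, 3], B = [2, 4, 6].  Expected values follow from
        # explicit interpolation of the across-sample mean quantile
        # function: Q_A has knots (0.25, 1), (0.75, 3); Q_B has knots
        # (1/6, 2), (1/2, 4), (5/6, 6), both held constant outside.
        # A's positions {0.25, 0.75} -> mean(Q) = {1.75, 4.25};
        # B's positions {1/6, 1/2, 5/6} -> {1.5, 3.0, 4.5}.
        obj = build_omics_object(
            [
                ("A", "x", [1.0], []),
                ("A", "y", [MISSING], []),
                ("A", "z", [3.0], []),
                ("B", "x", [2.0], []),
                ("B", "y", [4.0], []),
                ("B", "z", [6.0], []),
            ]
        )
        out = quantile_normalize(obj)
        assert np.allclose(self._values(out, "A", "xz"), [1.75, 4.25])
        assert out.samples["A"]["y"].measurements[0] is MISSING
        assert np.allclose(self._values(out, "B", "xyz"), [1.5, 3.0, 4.5])

    def test_all_observed_multisets_equal_after(self):
        rng = np.random.default_rng(0)
        comps = [f"g{i}" for i in range(20)]
        obj = build_omics_object(
            [
                (s, c, [float(v)], [])
                for s in "ABC"
                for c, v in zip(comps, rng.normal(float("AB".find(s)), 2, 20))
            ]
        )
        out = quantile_normalize(obj)
        ref = sorted(self._values(out, "A", comps))
        for s in "BC":
            assert np.allclose(sorted(self._values(out, s, comps)), ref)

    def test_empty_sample_error(self):
        obj = build_omics_object(
            [("A", "x", [MISSING], []), ("B", "x", [1.0], [])]
        )
        with pytest.raises(OmicsInputError, match="A"):
            quantile_normalize(obj)

    def test_ties_get_equal_values(self):
        obj = build_omics_object(
            [
                ("A", "x", [2.0], []),
                ("A", "y", [2.0], []),
                ("A", "z", [5.0], []),
                ("B", "x", [1.0], []),
                ("B", "y", [3.0], []),
                ("B", "z", [9.0], []),
            ]
        )
        out = quantile_normalize(obj)
        ax, ay = self._values(out, "A", "xy")
        assert ax == ay

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        vals=st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=12,
        )
    )
    def test_rank_order_preserved(self, vals):
        comps = [f"g{i}" for i in range(len(vals))]
        obj = build_omics_object(
            [("A", c, [a], []) for c, (a, _) in zip(comps, vals)]
            + [("B", c, [b], []) for c, (_, b) in zip(comps, vals)]
        )
        out = quantile_normalize(obj)
        for s, pick in (("A", 0), ("B", 1)):
            before = [v[pick] for v in vals]
            after = [out.samples[s][c].measurements[0] for c in comps]
            order = np.argsort(before, kind="stable")
            assert np.all(np.diff(np.asarray(after)[order]) >= -1e-12)


class TestBoxCox:
    def test_fixed_lambda_one_is_shift(self):
        _, y = boxcox_fit_transform([1.0, 2.0, 3.0], lmbda=1.0)
        assert np.allclose(y, [0, 1, 2])

    def test_fixed_lambda_zero_is_log(self):
        _, y = boxcox_fit_transform([1.0, np.e], lmbda=0.0)
        assert np.allclose(y, [0, 1])

    def test_lognormal_lambda_near_zero(self):
        # profile-likelihood grid oracle: for lognormal data the MLE of
        # the exponent concentrates at 0 (log transform)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit, _ = boxcox_fit_transform(rng.lognormal(0, 1, 1000))
            assert abs(fit.lmbda) < 0.15

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 1.0, 400)
        fit, _ = boxcox_fit_transform(x)
        from scipy.stats import boxcox_llf

        grid = np.linspace(-5, 5, 2001)
        lam_grid = grid[np.argmax([boxcox_llf(l, x) for l in grid])]
        assert abs(fit.lmbda - lam_grid) < 0.01

    def test_nonpositive_values_shifted(self):
        fit, y = boxcox_fit_transform([-1.0, 0.0, 2.0, 5.0])
        assert fit.shift == pytest.approx(1e-3 + 1.0)
        assert np.all(np.isfinite(y))

    def test_constant_input_error(self):
        with pytest.raises(OmicsInputError):
            boxcox_fit_transform([2.0, 2.0, 2.0])

    def test_monotone_and_continuous_at_zero(self):
        x = np.array([0.5, 1.0, 2.0, 4.0])
        for lam in (-1.3, -1e-6, 0.0, 1e-6, 0.7):
            assert np.all(np.diff(boxcox_transform(x, lam)) > 0)
        assert np.allclose(
            boxcox_transform(x, 1e-6), boxcox_transform(x, 0.0), atol=1e-8
        )
        assert np.allclose(
            boxcox_transform(x, -1e-6), boxcox_transform(x, 0.0), atol=1e-8
        )


class TestReferenceNormalization:
    def test_subtraction_at_first_time(self):
        tss = _tss({"a": [1.0, 2.0, 3.0]})
        out, _ = normalize_to_reference(tss, 0)
        assert np.allclose(out.series["a"], [0, 1, 2])

    def test_subtraction_at_last_time(self):
        tss = _tss({"a": [0.0, 0.0, 5.0]})
        out, _ = normalize_to_reference(tss, 2)
        assert np.allclose(out.series["a"], [-5, -5, 0])

    def test_missing_at_reference_removed(self):
        tss = _tss({"a": [np.nan, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        out, rep = normalize_to_reference(tss, 0)
        assert "a" not in out.series
        assert rep.removed_components == [("a", "missing at reference")]

    def test_reference_not_in_grid(self):
        with pytest.raises(OmicsInputError, match="available"):
            normalize_to_reference(_tss({"a": [1.0, 2.0]}), 99)

    def test_invariant_under_constant_shift(self):
        tss1 = _tss({"a": [1.0, 4.0, 2.0]})
        tss2 = _tss({"a": [8.0, 11.0, 9.0]})
        out1, _ = normalize_to_reference(tss1, 1)
        out2, _ = normalize_to_reference(tss2, 1)
        assert np.allclose(out1.series["a"], out2.series["a"])


class TestApplier:
    def test_elementwise_with_missing_passthrough(self):
        obj = build_omics_object([("s", "a", [-1.0, 2.0, MISSING], [])])
        out = applier(obj, abs)
        assert out.samples["s"]["a"].measurements[:2] == [1.0, 2.0]
        assert out.samples["s"]["a"].measurements[2] is MISSING

    def test_identity_and_inverse_composition(self, tiny_object):
        assert applier(tiny_object, lambda x: x) == tiny_object
        shifted = applier(applier(tiny_object, lambda x: x + 1), lambda x: x - 1)
        assert shifted == tiny_object

    def test_raising_function_wrapped_with_coordinates(self, tiny_object):
        def bad(x):
            raise RuntimeError("boom")

        with pytest.raises(OmicsInputError, match="GeneA"):
            applier(tiny_object, bad)
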