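"""Fold normalisation, ON/OFF classification, dose-response, gating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from switchquant import singlecell, synth
from switchquant.singlecell import FoldBins


class TestFold:
    def test_fold_is_intensity_over_background(self):
        cells = pd.DataFrame({"mean_c": [100.0, 400.0]})
        fold = singlecell.fold_over_background(cells, "c", 100.0)
        np.testing.assert_allclose(fold, [1.0, 4.0])

    def test_nonpositive_background_rejected(self):
        cells = pd.DataFrame({"mean_c": [1.0]})
        for bad in (0.0, -3.0, np.nan):
            with pytest.raises(ValueError):
                singlecell.fold_over_background(cells, "c", bad)

    def test_recovered_fold_tracks_generator_truth(self, colony_fixture):
        """Measured fold on noisy images stays within the shot-noise envelope."""
        from switchquant import imaging

        colony, expr, stack, truth = colony_fixture
        gt = synth.ground_truth_labels(truth, colony.image_shape_px)
        cells = imaging.measure_nuclei(gt, stack)
        _, bg = imaging.subtract_background(stack["mCherry"], method="percentile")
        fold = singlecell.fold_over_background(cells, "mCherry", bg)
        true_fold = truth["true_driver_fold"].to_numpy()
        # per-nucleus relative error: Poisson noise averaged over ~250 px is < 5%
        rel = np.abs(fold.to_numpy() - true_fold) / true_fold
        assert np.quantile(rel, 0.95) < 0.1


class TestClassify:
    def test_degenerate_input_flags_single_population(self):
        on, summary = singlecell.classify_on_off(np.full(50, 3.0))
        assert summary["single_population"] and np.isnan(summary["D"])
        assert on.all()

    def test_balanced_mixture_recovers_half_on_and_large_d(self):
        rng = np.random.default_rng(11)
        vals = np.exp(np.concatenate([rng.normal(0, 0.2, 500), rng.normal(2, 0.2, 500)]))
        on, summary = singlecell.classify_on_off(vals, seed=11)
        assert abs(on.mean() - 0.5) <= 0.05
        assert summary["D"] > 4

    def test_threshold_rule_is_inclusive_at_cutoff(self):
        on, _ = singlecell.classify_on_off(
            np.array([1.9, 2.0, 2.1]), method="threshold", threshold=2.0
        )
        np.testing.assert_array_equal(on, [False, True, True])

    def test_gmm_requires_enough_cells(self):
        with pytest.raises(ValueError, match="20"):
            singlecell.classify_on_off(np.ones(10))


class TestDoseResponse:
    def test_first_bin_contains_fold_one(self):
        with pytest.raises(ValueError, match="fold ~ 1"):
            FoldBins(edges=(2.0, 4.0, np.inf), labels=("a", "b"))

    def test_all_on_gives_zero_negative_fraction(self):
        folds = np.array([0.5, 1.0, 2.5, 5.0])
        curve = singlecell.dose_response(folds, np.ones(4, dtype=bool))
        occupied = curve["n_cells"] > 0
        assert (curve.loc[occupied, "fraction_response_negative"] == 0).all()

    def test_bin_counts_partition_the_cells(self):
        rng = np.random.default_rng(3)
        folds = np.exp(rng.normal(0.5, 1.0, 777))
        curve = singlecell.dose_response(folds, rng.random(777) < 0.5)
        assert curve["n_cells"].sum() == 777

    def test_fractions_match_hill_integrated_truth(self):
        expr = synth.ExpressionParams(f_half=2.0, h=6.0, seed=5)
        cells = synth.generate_cell_table(5000, expr)
        folds = cells["true_driver_fold"].to_numpy()
        on = cells["true_response_on"].to_numpy()
        curve = singlecell.dose_response(folds, on)
        bins = FoldBins()
        idx = bins.assign(folds)
        for k in range(len(bins.labels)):
            sel = idx == k
            if sel.sum() == 0:
                continue
            truth = np.mean(1.0 - synth.hill_repression(folds[sel], 2.0, 6.0))
            measured = curve.loc[k, "fraction_response_negative"]
            assert abs(measured - truth) <= 0.05

    def test_monotone_link_gives_monotone_curve(self):
        expr = synth.ExpressionParams(f_half=2.0, h=6.0, seed=6)
        cells = synth.generate_cell_table(3000, expr)
        curve = singlecell.dose_response(
            cells["true_driver_fold"].to_numpy(), cells["true_response_on"].to_numpy()
        )
        fracs = curve["fraction_response_negative"].dropna().to_numpy()
        assert (np.diff(fracs) >= -1e-12).all()

    def test_empty_bin_is_flagged_not_fatal(self):
        curve = singlecell.dose_response(np.array([1.0, 1.1]), np.array([True, True]))
        empty = curve[curve["n_cells"] == 0]
        assert len(empty) > 0
        assert empty["fraction_response_negative"].isna().all()


class TestCorrelate:
    def test_proportional_channels_have_unit_correlation(self):
        cells = pd.DataFrame({"mean_a": [1.0, 2, 3, 4], "mean_b": [2.0, 4, 6, 8]})
        res = singlecell.correlate_channels(cells, "a", "b", log=False)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_anticorrelated_channels(self):
        cells = pd.DataFrame({"mean_a": [1.0, 2, 3], "mean_b": [9.0, 8, 7]})
        res = singlecell.correlate_channels(cells, "a", "b", log=False)
        assert res["r"] == pytest.approx(-1.0)

    def test_zero_variance_is_undefined_not_fatal(self):
        cells = pd.DataFrame({"mean_a": [1.0, 1, 1], "mean_b": [1.0, 2, 3]})
        res = singlecell.correlate_channels(cells, "a", "b", log=False)
        assert np.isnan(res["r"])

    def test_lognormal_correlation_within_fisher_ci(self):
        rng = np.random.default_rng(13)
        rho, n = 0.9, 1000
        cov = [[1, rho], [rho, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=n)
        cells = pd.DataFrame({"mean_a": np.exp(z[:, 0]), "mean_b": np.exp(z[:, 1])})
        res = singlecell.correlate_channels(cells, "a", "b", log=True)
        zr, z0 = np.arctanh(res["r"]), np.arctanh(rho)
        assert abs(zr - z0) <= stats.norm.ppf(0.995) / np.sqrt(n - 3)


class TestFractionPositive:
    def test_extremes(self):
        cells = pd.DataFrame({"mean_c": np.full(30, 10.0)})
        res = singlecell.fraction_positive(cells, "c", method="threshold", threshold=2.0)
        assert res["fraction"] == 1.0
        res = singlecell.fraction_positive(cells, "c", method="threshold", threshold=20.0)
        assert res["fraction"] == 0.0

    def test_generator_on_fraction_within_binomial_ci(self):
        rng = np.random.default_rng(8)
        n, p = 2000, 0.7
        on = rng.random(n) < p
        vals = np.exp(np.where(on, rng.normal(2, 0.2, n), rng.normal(0, 0.2, n)))
        res = singlecell.fraction_positive(pd.DataFrame({"mean_c": vals}), "c", seed=8)
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo / n <= res["fraction"] <= hi / n

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            singlecell.fraction_positive(pd.DataFrame({"mean_c": []}), "c")


class TestGatingProperties:
    """Hypothesis invariants: gating always balances, binning always partitions."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=200,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_gate_sizes_always_differ_by_at_most_one(self, values):
        gates = singlecell.gate_equal_thirds(pd.DataFrame({"mean_c": values}), "c")
        counts = gates.value_counts().reindex(["Low", "Med", "High"]).fillna(0)
        assert counts.sum() == len(values)
        assert counts.max() - counts.min() <= 1

    @given(
        st.lists(
            st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
            min_size=1,
            max_size=300,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_dose_response_bins_partition_any_fold_sample(self, folds):
        folds = np.asarray(folds)
        curve = singlecell.dose_response(folds, np.ones(len(folds), dtype=bool))
        assert curve["n_cells"].sum() == len(folds)


class TestGating:
    @pytest.mark.parametrize(
        "n,expected",
        [(300, (100, 100, 100)), (301, (101, 100, 100)), (302, (101, 101, 100))],
    )
    def test_gate_sizes_balanced_with_extra_in_low(self, n, expected):
        rng = np.random.default_rng(1)
        cells = pd.DataFrame({"mean_c": rng.permutation(n).astype(float)})
        gates = singlecell.gate_equal_thirds(cells, "c")
        counts = gates.value_counts()
        assert (counts["Low"], counts["Med"], counts["High"]) == expected

    def test_gates_are_ordered_by_value(self):
        cells = pd.DataFrame({"mean_c": np.arange(9.0)})
        gates = singlecell.gate_equal_thirds(cells, "c")
        assert list(gates) == ["Low"] * 3 + ["Med"] * 3 + ["High"] * 3

    def test_ties_split_by_stable_input_order(self):
        cells = pd.DataFrame({"mean_c": np.ones(7)})
        gates = singlecell.gate_equal_thirds(cells, "c")
        assert list(gates) == ["Low", "Low", "Low", "Med", "Med", "High", "High"]


def test_end_to_end_bistability_pattern(colony_fixture):
    """Image -> cell table -> dose response reproduces the qualitative switch:

    response mostly positive in driver-negative cells, > 40% negative in the
    2-4x bin, > 90% negative beyond 4x.
    """
    from switchquant import imaging

    colony, expr, stack, truth = colony_fixture
    labels = imaging.segment_nuclei(stack["DAPI"])
    cells = imaging.measure_nuclei(labels, stack)
    _, bg_d = imaging.subtract_background(stack["mCherry"], method="percentile")
    _, bg_r = imaging.subtract_background(stack["NANOG"], method="percentile")
    fold_d = singlecell.fold_over_background(cells, "mCherry", bg_d)
    fold_r = singlecell.fold_over_background(cells, "NANOG", bg_r)
    on, _ = singlecell.classify_on_off(fold_r.to_numpy(), method="threshold", threshold=2.0)
    curve = singlecell.dose_response(fold_d.to_numpy(), on).set_index("bin")
    assert 1 - curve.loc["negative", "fraction_response_negative"] > 0.8
    assert curve.loc["2-4x", "fraction_response_negative"] > 0.4
    assert curve.loc[">=4x", "fraction_response_negative"] > 0.9
    fracs = curve["fraction_response_negative"].dropna()
    assert fracs.is_monotonic_increasing
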