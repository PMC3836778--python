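import warnings

import numpy as np
import pandas as pd
import pytest

from presep import (
    ConfusionCounts,
    FixtureSpec,
    MetricsReport,
    MotifSignal,
    PseAACParams,
    PseAACType,
    beta_gal_validation_table,
    cross_validate,
    cross_validate_dataset,
    generate,
    metrics_from_counts,
    parameter_sweep,
    propensity_correlation,
    ri_coverage_curve,
    roc_auc,
    terminal_scan,
)
from presep.exceptions import PresepError


def brute_force_auc(labels, scores):
    """All-pairs concordance counting: ties worth 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetricsFromCounts:
    def test_perfect_classifier(self):
        r = metrics_from_counts(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert r.mcc == 1.0 and r.q2 == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_imbalanced_profile(self):
        # a 136-positive / 957-negative split with 24 FN and 29 FP
        r = metrics_from_counts(ConfusionCounts(tp=112, fn=24, tn=928, fp=29))
        assert r.sensitivity == pytest.approx(0.82, abs=0.005)
        assert r.specificity == pytest.approx(0.97, abs=0.005)
        assert r.q2 == pytest.approx(0.95, abs=0.005)
        assert r.mcc == pytest.approx(0.78, abs=0.005)

    def test_degenerate_all_positive_convention(self):
        r = metrics_from_counts(ConfusionCounts(tp=25, fn=0, tn=0, fp=25))
        assert r.mcc == 0.0
        assert r.q2 == 0.5

    def test_agrees_with_per_example_tally(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, size=n)
            p = rng.integers(0, 2, size=n)
            c = ConfusionCounts.from_predictions(y, p)
            assert c.total == n
            # independent tally
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            assert (c.tp, c.tn) == (tp, tn)
            r = metrics_from_counts(c)
            assert r.q2 == pytest.approx((tp + tn) / n)


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, _, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_one_discordant_pair(self):
        # 3 pos vs 3 neg: one of the 9 pairs discordant -> AUC = 8/9
        labels = [0, 0, 0, 1, 1, 1]
        scores = [1.0, 2.0, 4.0, 3.0, 5.0, 6.0]
        auc, _, _ = roc_auc(labels, scores)
        assert auc == pytest.approx(8 / 9)
        assert brute_force_auc(labels, scores) == pytest.approx(8 / 9)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=4000)
        s = rng.random(4000)
        auc, _, _ = roc_auc(y, s)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            y = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
            s = rng.choice([0.0, 0.25, 0.5, 0.33, 1.0], size=n)  # heavy ties
            auc, _, _ = roc_auc(y, s)
            assert auc == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(PresepError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestRiCoverageCurve:
    def test_all_confident_correct(self):
        df = ri_coverage_curve([1, 1, 1], [1.0, 1.0, 1.0])
        assert len(df) == 11
        assert (df["fraction"] == 1.0).all()
        assert (df["accuracy"] == 1.0).all()

    def test_threshold_zero_covers_everything_and_fraction_decreases(self, rng):
        y = rng.integers(0, 2, size=200)
        s = rng.random(200)
        df = ri_coverage_curve(y, s)
        assert df.loc[0, "fraction"] == 1.0
        assert (np.diff(df["fraction"]) <= 1e-12).all()
        assert df["ri_threshold"].tolist() == list(range(11))


@pytest.fixture(scope="module")
def small_fixture():
    """Strongly separated 40+40 set; small enough for fast CV tests."""
    return generate(FixtureSpec(n_pos=40, n_neg=40, length_range=(60, 120), seed=9))


@pytest.fixture(scope="module")
def small_params():
    return PseAACParams(mode=PseAACType.TYPE_I, w=0.05, lam=3)


class TestCrossValidate:
    def test_stratified_fold_sizes_differ_by_at_most_one(self, small_fixture, small_params):
        res = cross_validate_dataset(
            small_fixture, small_params, folds=10, seed=0, n_trees=30
        )
        y = res.labels
        for cls in (0, 1):
            sizes = np.bincount(res.fold_assignments[y == cls], minlength=res.folds_used)
            assert sizes.max() - sizes.min() <= 1
        assert res.folds_used == 10
        # count conservation
        assert np.bincount(res.fold_assignments).sum() == len(y)

    def test_folds_reduced_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(13, 4))
        y = np.array([1] * 3 + [0] * 10)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = cross_validate(X, y, folds=20, seed=0, n_trees=10)
        assert res.folds_used == 3

    def test_leave_one_out_and_two_fold_run(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(4, 1, (6, 3))])
        y = np.array([0] * 6 + [1] * 6)
        for folds in (6, 2):
            res = cross_validate(X, y, folds=folds, seed=0, n_trees=10)
            assert not np.isnan(res.oof_scores).any()
            assert res.metrics.counts.total == 12

    def test_single_class_rejected(self):
        with pytest.raises(PresepError):
            cross_validate(np.zeros((5, 2)), np.ones(5), folds=2)

    def test_reproducible_bit_for_bit(self, small_fixture, small_params):
        r1 = cross_validate_dataset(small_fixture, small_params, folds=5, seed=3, n_trees=20)
        r2 = cross_validate_dataset(small_fixture, small_params, folds=5, seed=3, n_trees=20)
        np.testing.assert_array_equal(r1.oof_scores, r2.oof_scores)
        assert r1.metrics.mcc == r2.metrics.mcc


class TestParameterSweep:
    def test_grid_cardinality_and_sort_contract(self, small_fixture):
        df = parameter_sweep(
            small_fixture,
            modes=[PseAACType.TYPE_I],
            w_grid=[0.05],
            lam_grid=[1, 2],
            folds=4,
            seed=0,
            n_trees=20,
        )
        assert len(df) == 2
        assert df["mcc"].is_monotonic_decreasing
        assert set(df.columns) >= {"mode", "w", "lam", "mcc", "q2", "sensitivity", "specificity"}

    def test_empty_grid_rejected(self, small_fixture):
        with pytest.raises(PresepError):
            parameter_sweep(small_fixture, modes=[], folds=2)

    def test_reproducible(self, small_fixture):
        kwargs = dict(
            modes=[PseAACType.TYPE_II], w_grid=[0.5], lam_grid=[2],
            folds=3, seed=7, n_trees=15,
        )
        pd.testing.assert_frame_equal(
            parameter_sweep(small_fixture, **kwargs),
            parameter_sweep(small_fixture, **kwargs),
        )


class TestTerminalScan:
    def test_full_length_windows_identical_for_both_terminals(self, small_fixture, small_params):
        df = terminal_scan(
            small_fixture, small_params, lengths=[500], folds=4, seed=0, n_trees=20
        )
        n_row = df[df["terminal"] == "N"].iloc[0]
        c_row = df[df["terminal"] == "C"].iloc[0]
        assert n_row["mcc"] == c_row["mcc"]
        assert n_row["q2"] == c_row["q2"]

    def test_row_cardinality(self, small_fixture, small_params):
        df = terminal_scan(
            small_fixture, small_params, lengths=[17, 50], folds=3, seed=0, n_trees=10
        )
        assert len(df) == 4
        assert set(zip(df["terminal"], df["k"])) == {
            ("N", 17), ("N", 50), ("C", 17), ("C", 50)
        }

    def test_n_terminal_signal_recovered(self):
        # class signal planted only in the first 20 residues of positives
        spec = FixtureSpec(
            n_pos=60, n_neg=60, delta=0.0, length_range=(60, 120),
            motif=MotifSignal(motif="WPWH", period=7, region=20), seed=11,
        )
        ds = generate(spec)
        params = PseAACParams(mode=PseAACType.TYPE_I, w=0.05, lam=5)
        df = terminal_scan(ds, params, lengths=[20], folds=5, seed=0, n_trees=60)
        mcc = {t: df[df["terminal"] == t]["mcc"].iloc[0] for t in ("N", "C")}
        assert mcc["N"] > mcc["C"]
        assert mcc["N"] > 0.8


class TestPropensityCorrelation:
    def test_collinear_pairs(self):
        slope, intercept, r2 = propensity_correlation([(0.1, 1.0), (0.2, 2.0), (0.3, 3.0)])
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(10.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_bundled_validation_set(self):
        df = beta_gal_validation_table()
        assert len(df) == 6
        _, _, r2 = propensity_correlation(
            list(zip(df["propensity"], df["extracellular_pct"]))
        )
        assert r2 == pytest.approx(0.967, abs=0.005)

    def test_affine_invariance_of_r_squared(self, rng):
        pairs = [(float(x), float(y)) for x, y in rng.random((8, 2))]
        _, _, r2 = propensity_correlation(pairs)
        rescaled = [(3 * x - 1, -0.5 * y + 4) for x, y in pairs]
        _, _, r2b = propensity_correlation(rescaled)
        assert r2b == pytest.approx(r2, abs=1e-12)

    @pytest.mark.parametrize(
        "pairs",
        [
            [(0.5, 1.0), (0.5, 2.0), (0.5, 3.0)],  # zero variance in x
            [(0.1, 2.0), (0.2, 2.0), (0.3, 2.0)],  # zero variance in y
            [(0.1, 1.0), (0.2, 2.0)],  # too few
        ],
    )
    def test_degenerate_inputs_rejected(self, pairs):
        with pytest.raises(PresepError):
            propensity_correlation(pairs)
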