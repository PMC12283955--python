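"""Metric formulas, CV grid search, cross-source table, learning curve."""

import numpy as np
import pandas as pd
import pytest

from afscreen.evaluation import (GridSpec, compute_metrics, confusion_by_label,
                                 cv_grid_search, data_efficiency_study,
                                 evaluate_cross, evaluate_model,
                                 summarize_data_efficiency)
from afscreen.kernel import KernelParams
from afscreen.simulate import ClassModel, gen_rri
from afscreen.svm import DistributionalSVC


class TestComputeMetrics:
    def test_counts_and_formulas(self):
        # TP=2 TN=3 FP=1 FN=0
        y_true = [1, 1, -1, -1, -1, -1]
        y_pred = [1, 1, 1, -1, -1, -1]
        r = compute_metrics(y_true, y_pred)
        assert (r.tp, r.tn, r.fp, r.fn) == (2, 3, 1, 0)
        assert r.sensitivity == 1.0
        assert r.specificity == 0.75
        assert r.f1 == pytest.approx(0.8, abs=1e-12)
        assert r.accuracy == pytest.approx(5 / 6, abs=1e-12)
        assert r.n == 6

    def test_f1_equals_harmonic_mean_of_precision_and_sensitivity(self, rng):
        for _ in range(20):
            y_true = rng.choice([-1, 1], size=40)
            y_pred = rng.choice([-1, 1], size=40)
            r = compute_metrics(y_true, y_pred)
            prec = r.tp / (r.tp + r.fp) if (r.tp + r.fp) else np.nan
            if np.isfinite(prec) and np.isfinite(r.sensitivity) and (prec + r.sensitivity) > 0:
                harmonic = 2 * prec * r.sensitivity / (prec + r.sensitivity)
                assert abs(r.f1 - harmonic) < 1e-12

    def test_perfect_ranking_gives_auroc_one(self):
        y = [-1, -1, 1, 1]
        r = compute_metrics(y, y, scores=[0.1, 0.2, 0.8, 0.9])
        assert r.auroc == 1.0

    def test_constant_scores_give_auroc_half(self):
        y = [-1, 1, -1, 1]
        r = compute_metrics(y, y, scores=[0.5, 0.5, 0.5, 0.5])
        assert r.auroc == 0.5

    def test_auroc_invariant_under_monotone_transforms(self, rng):
        y = np.where(rng.random(60) < 0.3, 1, -1)
        s = rng.normal(size=60)
        base = compute_metrics(y, y, scores=s).auroc
        assert compute_metrics(y, y, scores=np.exp(s)).auroc == pytest.approx(base, abs=1e-12)
        assert compute_metrics(y, y, scores=3 * s + 7).auroc == pytest.approx(base, abs=1e-12)

    def test_one_class_truth_flags_auroc_undefined(self):
        r = compute_metrics([1, 1], [1, -1], scores=[0.2, 0.1])
        assert (r.tp, r.fn) == (1, 1)
        assert np.isnan(r.auroc) and np.isnan(r.specificity)

    def test_roc_points_monotone(self, rng):
        y = np.where(rng.random(50) < 0.4, 1, -1)
        r = compute_metrics(y, y, scores=rng.normal(size=50))
        assert np.all(np.diff(r.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(r.roc_points[:, 1]) >= 0)


class TestConfusionByLabel:
    def test_row_sums_match_label_counts(self):
        raw = ["SR", "SR", "AF", "AFlut", "SR"]
        pred = [-1, 1, 1, 1, -1]
        c = confusion_by_label(raw, pred)
        assert c.row_totals.to_dict() == {"SR": 3, "AF": 1, "AFlut": 1}
        assert c.counts.loc["SR", "pred_AF"] == 1


def _pool(n_per_class=25, seed=0, cvs=(0.05, 0.3)):
    return (gen_rri(ClassModel(label=-1, cv=cvs[0]), n_per_class, seed=seed)
            + gen_rri(ClassModel(label=+1, cv=cvs[1]), n_per_class, seed=seed + 1))


class TestCvGridSearch:
    def test_single_cell_grid(self):
        grid = GridSpec(sigmas=(0.1,), gammas=(0.5,), cost_ratios=(1.0,),
                        n_folds=3, seed=0)
        params, w, table = cv_grid_search(_pool(15), grid)
        assert (params.sigma, params.gamma, w) == (0.1, 0.5, 1.0)
        assert len(table) == 1

    def test_argmax_cell_is_returned(self):
        grid = GridSpec(sigmas=(0.05, 0.5), gammas=(0.5,), cost_ratios=(1.0,),
                        n_folds=3, seed=1)
        params, w, table = cv_grid_search(_pool(15, cvs=(0.1, 0.2), seed=4), grid)
        best_row = table.loc[table["mean_auroc"].idxmax()]
        assert params.sigma == best_row["sigma"]
        # the exhaustive table is itself the oracle
        assert table["mean_auroc"].max() == \
            table.loc[(table["sigma"] == params.sigma)
                      & (table["gamma"] == params.gamma)
                      & (table["cost_ratio"] == w), "mean_auroc"].iloc[0]

    def test_tie_resolves_to_earlier_grid_cell(self):
        # perfectly separable data ties every cell at AUROC 1
        grid = GridSpec(sigmas=(0.05, 0.1), gammas=(0.5, 1.0), cost_ratios=(1.0, 4.0),
                        n_folds=3, seed=0)
        params, w, table = cv_grid_search(_pool(15), grid)
        assert np.allclose(table["mean_auroc"], 1.0)
        assert (params.sigma, params.gamma, w) == (0.05, 0.5, 1.0)

    def test_determinism(self):
        grid = GridSpec(sigmas=(0.05, 0.5), gammas=(0.5, 1.0), cost_ratios=(1.0,),
                        n_folds=3, seed=9)
        a = cv_grid_search(_pool(15), grid)
        b = cv_grid_search(_pool(15), grid)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_small_class_errors(self):
        pool = _pool(3)
        with pytest.raises(ValueError, match="fewer"):
            cv_grid_search(pool, GridSpec(sigmas=(0.1,), gammas=(0.5,),
                                          cost_ratios=(1.0,), n_folds=5))

    def test_table_reports_variance_and_sd(self):
        grid = GridSpec(sigmas=(0.1,), gammas=(0.5,), cost_ratios=(1.0,), n_folds=3)
        _, _, table = cv_grid_search(_pool(15), grid)
        assert {"var_auroc", "sd_auroc"} <= set(table.columns)
        assert table["sd_auroc"].iloc[0] == pytest.approx(
            np.sqrt(table["var_auroc"].iloc[0]), abs=1e-15)


class TestGridSpecValidation:
    def test_rejects_duplicates_and_empties(self):
        with pytest.raises(ValueError):
            GridSpec(sigmas=(0.1, 0.1))
        with pytest.raises(ValueError):
            GridSpec(gammas=())


@pytest.fixture(scope="module")
def models_and_testsets():
    models, testsets = {}, {}
    for i, name in enumerate(["siteA", "siteB"]):
        train = _pool(20, seed=50 + i)
        y = [v.binary_label for v in train]
        models[name] = DistributionalSVC(sigma=0.1, gamma=0.5).fit(train, y)
        testsets[name] = _pool(15, seed=70 + i)
    return models, testsets


class TestEvaluateCross:
    def test_cardinality(self, models_and_testsets):
        table = evaluate_cross(*models_and_testsets)
        assert len(table) == 4
        assert set(zip(table["train_source"], table["test_source"])) == {
            ("siteA", "siteA"), ("siteA", "siteB"),
            ("siteB", "siteA"), ("siteB", "siteB")}

    def test_diagonal_matches_direct_evaluation(self, models_and_testsets):
        models, testsets = models_and_testsets
        table = evaluate_cross(models, testsets)
        direct, _ = evaluate_model(models["siteA"], testsets["siteA"])
        row = table[(table["train_source"] == "siteA")
                    & (table["test_source"] == "siteA")].iloc[0]
        for key, val in direct.as_dict().items():
            assert row[key] == val

    def test_repeated_evaluation_identical(self, models_and_testsets):
        a = evaluate_cross(*models_and_testsets)
        b = evaluate_cross(*models_and_testsets)
        pd.testing.assert_frame_equal(a, b)


class TestDataEfficiency:
    def test_full_pool_single_resample_matches_direct_training(self):
        pool = _pool(15, seed=90)
        test = _pool(10, seed=91)
        table = data_efficiency_study(pool, sizes=[len(pool)], n_resamples=1,
                                      seed=0, params=KernelParams(0.1, 0.5),
                                      cost_ratio=1.0, test_set=test)
        model = DistributionalSVC(sigma=0.1, gamma=0.5)
        model.fit(pool, [v.binary_label for v in pool])
        direct, _ = evaluate_model(model, test)
        assert table.iloc[0]["f1"] == direct.f1
        assert table.iloc[0]["auroc"] == direct.auroc

    def test_determinism(self):
        pool, test = _pool(20, seed=92), _pool(10, seed=93)
        kw = dict(sizes=[10, 20], n_resamples=3, seed=7,
                  params=KernelParams(0.1, 0.5), cost_ratio=1.0, test_set=test)
        pd.testing.assert_frame_equal(data_efficiency_study(pool, **kw),
                                      data_efficiency_study(pool, **kw))

    def test_learning_curve_improves_with_size(self):
        pool = _pool(110, seed=94, cvs=(0.07, 0.22))
        test = _pool(40, seed=95, cvs=(0.07, 0.22))
        table = data_efficiency_study(pool, sizes=[20, 200], n_resamples=5,
                                      seed=3, params=KernelParams(0.1, 0.5),
                                      cost_ratio=1.0, test_set=test)
        med = table.groupby("size")["f1"].median()
        assert med[200] >= med[20]

    def test_too_small_size_errors(self):
        pool = _pool(50, seed=96)
        dense = [v for v in pool if v.binary_label == -1] + \
                [v for v in pool if v.binary_label == 1][:2]
        with pytest.raises(ValueError, match="both classes"):
            data_efficiency_study(dense, sizes=[3], n_resamples=1, seed=0,
                                  params=KernelParams(0.1, 0.5), cost_ratio=1.0,
                                  test_set=pool)

    def test_quantile_summary_shape(self):
        pool, test = _pool(20, seed=97), _pool(10, seed=98)
        table = data_efficiency_study(pool, sizes=[10], n_resamples=4, seed=1,
                                      params=KernelParams(0.1, 0.5),
                                      cost_ratio=1.0, test_set=test)
        summary = summarize_data_efficiency(table, quantiles=(0.25, 0.5, 0.75))
        assert len(summary) == 3
        assert {"size", "quantile", "f1", "auroc"} <= set(summary.columns)
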