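import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import matthews_corrcoef

from prionscore.metrics import (
    LabeledPrediction,
    confusion_metrics,
    correlation_stats,
    error_stats,
    evaluate_predictions,
)

from oracles import oracle_confusion, oracle_spearman


def preds_from(pred_scores, observed, observed_class):
    return [
        LabeledPrediction(id=f"v{i}", predicted=p, observed=o, observed_class=c)
        for i, (p, o, c) in enumerate(zip(pred_scores, observed, observed_class))
    ]


class TestConfusionMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        preds = preds_from([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], [True, True, False, False])
        m = confusion_metrics(preds, threshold=0.45)
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0,
                     "accuracy": 1.0, "mcc": 1.0}

    def test_all_negative_classifier_degenerates(self):
        preds = preds_from([0.1, 0.2, 0.3, 0.4], [1, 1, 0, 0], [True, True, False, False])
        m = confusion_metrics(preds, threshold=0.45)
        assert m["sensitivity"] == 0.0
        assert math.isnan(m["precision"])
        assert math.isnan(m["mcc"])
        assert m["specificity"] == 1.0
        assert m["accuracy"] == 0.5

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=30))
    def test_matches_enumerated_table_oracle(self, pairs):
        preds = preds_from(
            [1.0 if p else 0.0 for p, _ in pairs],
            [1.0 if o else 0.0 for _, o in pairs],
            [o for _, o in pairs],
        )
        m = confusion_metrics(preds, threshold=0.5)
        exp = dict(zip(("sensitivity", "specificity", "precision", "accuracy", "mcc"),
                       oracle_confusion(pairs)))
        for key, val in exp.items():
            if val is None:
                assert math.isnan(m[key])
            else:
                assert m[key] == pytest.approx(val, abs=1e-12)

    def test_mcc_cross_checked_against_sklearn(self):
        rng = np.random.default_rng(5)
        pred_class = rng.random(50) > 0.4
        obs_class = rng.random(50) > 0.5
        preds = preds_from(pred_class.astype(float), obs_class.astype(float),
                           list(obs_class))
        m = confusion_metrics(preds, threshold=0.5)
        assert m["mcc"] == pytest.approx(
            matthews_corrcoef(obs_class, pred_class), abs=1e-12
        )

    def test_mcc_symmetric_under_simultaneous_class_swap(self):
        rng = np.random.default_rng(6)
        pred_class = rng.random(40) > 0.3
        obs_class = rng.random(40) > 0.6
        base = confusion_metrics(
            preds_from(pred_class.astype(float), obs_class.astype(float), list(obs_class)),
            threshold=0.5,
        )
        swapped = confusion_metrics(
            preds_from((~pred_class).astype(float), (~obs_class).astype(float),
                       list(~obs_class)),
            threshold=0.5,
        )
        assert base["mcc"] == pytest.approx(swapped["mcc"], abs=1e-12)
        assert base["accuracy"] == pytest.approx(swapped["accuracy"], abs=1e-12)


class TestCorrelationStats:
    def test_identity_prediction(self):
        preds = preds_from([0.1, 0.5, 0.9, 0.3], [0.1, 0.5, 0.9, 0.3], [True] * 4)
        c = correlation_stats(preds)
        assert c["r_squared"] == pytest.approx(1.0)
        assert c["spearman_rho"] == pytest.approx(1.0)

    def test_anti_monotone_data(self):
        preds = preds_from([1, 2, 3, 4], [8, 6, 4, 2], [True] * 4)
        assert correlation_stats(preds)["spearman_rho"] == pytest.approx(-1.0)

    def test_rho_matches_independent_rank_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.random(10)
        y = np.round(rng.random(10), 1)  # coarse values force ties
        preds = preds_from(x, y, [True] * 10)
        assert correlation_stats(preds)["spearman_rho"] == pytest.approx(
            oracle_spearman(list(x), list(y)), abs=1e-12
        )

    def test_zero_variance_undefined(self):
        preds = preds_from([0.5, 0.5, 0.5], [1, 2, 3], [True] * 3)
        assert all(math.isnan(v) for v in correlation_stats(preds).values())

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlation_stats(preds_from([1, 2], [1, 2], [True, True]))


class TestErrorStats:
    def test_identity_gives_zero_mean_and_sd(self):
        preds = preds_from([0.1, 0.4, 0.9], [0.1, 0.4, 0.9], [True] * 3)
        e = error_stats(preds)
        assert e["mean_pct_error"] == pytest.approx(0.0)
        assert e["sd_pct_error"] == pytest.approx(0.0)

    def test_two_point_case_by_hand(self):
        # rescaled errors are -100 and +100: mean 0, sample SD 141.42, SEM 100
        preds = preds_from([0.0, 1.0], [1.0, 0.0], [True, False])
        e = error_stats(preds)
        assert e["mean_pct_error"] == pytest.approx(0.0)
        assert e["sd_pct_error"] == pytest.approx(math.sqrt(20000), abs=1e-9)
        assert e["sem_pct_error"] == pytest.approx(100.0, abs=1e-9)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(15), rng.random(15)
        preds = preds_from(x, y, [True] * 15)
        xs = (x - x.min()) / (x.max() - x.min())
        ys = (y - y.min()) / (y.max() - y.min())
        err = 100 * (xs - ys)
        e = error_stats(preds)
        assert e["mean_pct_error"] == pytest.approx(err.mean(), abs=1e-12)
        assert e["sd_pct_error"] == pytest.approx(err.std(ddof=1), abs=1e-12)

    def test_sem_times_sqrt_n_equals_sd(self):
        rng = np.random.default_rng(4)
        preds = preds_from(rng.random(12), rng.random(12), [True] * 12)
        e = error_stats(preds)
        assert e["sem_pct_error"] * math.sqrt(12) == pytest.approx(e["sd_pct_error"])


class TestEvaluatePredictions:
    def test_full_panel_assembles_and_renders(self):
        rng = np.random.default_rng(8)
        obs = rng.random(10)
        preds = preds_from(obs + rng.normal(0, 0.05, 10), obs, list(obs > 0.5))
        report = evaluate_predictions(preds, threshold=0.5)
        assert report.n == 10
        assert report.sem_pct_error * math.sqrt(10) == pytest.approx(report.sd_pct_error)
        tsv = report.to_tsv()
        assert "Sensitivity" in tsv and "Rho" in tsv
        assert isinstance(report.to_dict()["mcc"], float)
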