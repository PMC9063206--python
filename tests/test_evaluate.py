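"""Metrics: DeLong AUROC vs exhaustive pairwise oracle, confusion-matrix
arithmetic, cohort comparison statistics, Shapley properties, ablation guard."""

import numpy as np
import pandas as pd
import pytest

from hfreadmit.evaluate import (
    ablation_run,
    auroc_delong,
    classification_metrics,
    compare_cohorts,
    grouped_shapley,
)


def pairwise_auroc(scores, labels):
    """Exhaustive U-statistic with half tie credit."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def test_auroc_matches_exhaustive_pairwise_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(10, 500))
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        if labels.all() or not labels.any():
            continue
        # include heavy ties via rounding
        scores = np.round(rng.normal(size=n) + labels, int(rng.integers(0, 3)))
        auc, lo, hi = auroc_delong(scores, labels)
        assert auc == pytest.approx(pairwise_auroc(scores, labels), abs=1e-12)
        assert lo <= auc <= hi


def test_perfect_separation_and_all_ties():
    y = np.array([0, 0, 1, 1], dtype=bool)
    assert auroc_delong(np.array([0.1, 0.2, 0.8, 0.9]), y)[0] == 1.0
    assert auroc_delong(np.ones(4), y)[0] == 0.5


def test_single_class_rejected():
    with pytest.raises(ValueError):
        auroc_delong(np.arange(4.0), np.ones(4, dtype=bool))


def test_confusion_matrix_arithmetic():
    # TP=8, FP=2, FN=2, TN=8
    scores = np.concatenate([np.full(8, 0.9), np.full(2, 0.9),
                             np.full(2, 0.1), np.full(8, 0.1)])
    labels = np.concatenate([np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]).astype(bool)
    r = classification_metrics(scores, labels)
    assert (r.precision, r.sensitivity, r.accuracy, r.f_score) == pytest.approx(
        (0.8, 0.8, 0.8, 0.8)
    )
    assert r.n == 20 and r.n_positive == 10


def test_all_positive_predictions_accuracy_one():
    scores = np.full(6, 0.9)
    labels = np.array([True, True, True, True, True, False])
    r = classification_metrics(scores, labels)
    assert r.sensitivity == 1.0
    # single-class labels: threshold metrics still defined, AUROC is NaN
    r2 = classification_metrics(scores[:5], labels[:5].copy())
    assert r2.accuracy == 1.0 and np.isnan(r2.auroc)


def test_no_predicted_positives_precision_zero(caplog):
    scores = np.full(10, 0.1)
    labels = np.array([True] * 3 + [False] * 7)
    r = classification_metrics(scores, labels)
    assert r.precision == 0.0 and r.sensitivity == 0.0


def test_positive_rate_of_train_cohort_counts():
    """581 readmissions among 2422 training patients is a 23.9% rate."""
    labels = np.array([True] * 581 + [False] * (2422 - 581))
    rate = 100.0 * labels.mean()
    assert abs(rate - 23.9) < 0.1


def test_identical_cohorts_not_significant(rng):
    df = pd.DataFrame({"age": rng.normal(70, 10, 200), "gender": ["F", "M"] * 100})
    out = compare_cohorts(df, df.copy(), categorical=["gender"], continuous=["age"])
    assert out["p_value"].tolist() == pytest.approx([1.0, 1.0])
    assert not out["significant"].any()


def test_balanced_contingency_table_chi_square_zero():
    a = pd.DataFrame({"g": ["x"] * 50 + ["y"] * 50})
    out = compare_cohorts(a, a.copy(), categorical=["g"], continuous=[])
    assert out.loc[0, "statistic"] == pytest.approx(0.0)


def test_one_sd_shift_detected_at_n500(rng):
    a = pd.DataFrame({"v": rng.normal(0, 1, 500)})
    b = pd.DataFrame({"v": rng.normal(1, 1, 500)})
    out = compare_cohorts(a, b, categorical=[], continuous=["v"])
    assert out.loc[0, "p_value"] < 0.05 and bool(out.loc[0, "significant"])


def test_zero_variance_note():
    a = pd.DataFrame({"v": np.ones(10)})
    out = compare_cohorts(a, a.copy(), categorical=[], continuous=["v"])
    assert out.loc[0, "p_value"] == 1.0 and out.loc[0, "note"] == "zero variance"


# ---------------------------------------------------------------------------
# Shapley on a linear surrogate (closed-form ground truth)


@pytest.fixture(scope="module")
def linear_setup():
    rng = np.random.default_rng(99)
    n, d = 40, 9
    X = rng.normal(size=(n, d))
    w = np.array([1.0, -2.0, 0.5, 0.0, 0.0, 0.0, 3.0, 1.0, -1.0])
    groups = {"a": [0, 1, 2], "dummy": [3, 4, 5], "b": [6, 7, 8]}
    background = X.mean(axis=0)
    predict = lambda M: M @ w
    return X, w, groups, background, predict


def test_linear_shapley_matches_closed_form(linear_setup):
    X, w, groups, background, predict = linear_setup
    values, se, phi = grouped_shapley(predict, X, groups, background,
                                      n_coalitions=40, seed=0)
    for g, idx in groups.items():
        exact = (X[:, idx] - background[idx]) @ w[idx]
        np.testing.assert_allclose(phi[g], exact, atol=1e-10)
        assert values[g] == pytest.approx(np.abs(exact).mean(), abs=1e-10)


def test_dummy_group_contributes_nothing(linear_setup):
    X, w, groups, background, predict = linear_setup
    values, _, _ = grouped_shapley(predict, X, groups, background,
                                   n_coalitions=30, seed=1)
    assert values["dummy"] == pytest.approx(0.0, abs=1e-10)


def test_efficiency_per_instance(linear_setup):
    X, w, groups, background, predict = linear_setup
    _, _, phi = grouped_shapley(predict, X, groups, background,
                                n_coalitions=30, seed=2)
    total = sum(phi.values())
    np.testing.assert_allclose(total, predict(X) - predict(background[None, :]), atol=1e-10)


def test_two_seeds_agree_within_mc_error(linear_setup):
    X, w, groups, background, predict = linear_setup
    v1, _, _ = grouped_shapley(predict, X, groups, background, n_coalitions=30, seed=3)
    v2, _, _ = grouped_shapley(predict, X, groups, background, n_coalitions=30, seed=4)
    for g in groups:  # linear model: exact for any sampling, so equal
        assert v1[g] == pytest.approx(v2[g], abs=1e-9)


def test_groups_must_partition_columns(linear_setup):
    X, w, groups, background, predict = linear_setup
    bad = {"a": [0, 1], "b": [3, 4, 5, 6, 7, 8]}  # column 2 missing
    with pytest.raises(ValueError, match="partition"):
        grouped_shapley(predict, X, bad, background)


# ---------------------------------------------------------------------------


def test_discharge_ablation_refused():
    from hfreadmit.config import PipelineConfig

    with pytest.raises(ValueError, match="discharge"):
        ablation_run(PipelineConfig(), ["discharge_events"], n_repeats=1, tables="unused")


def test_unknown_ablation_rejected():
    from hfreadmit.config import PipelineConfig

    with pytest.raises(ValueError, match="unknown ablation"):
        ablation_run(PipelineConfig(), ["bogus"], n_repeats=1, tables="unused")
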