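import numpy as np
import pandas as pd
import pytest

from embow import (AnnotationConfig, build_dataset, evaluate, make_partitions,
                   oversample, run_annotation_experiment, select_terms,
                   train_ovr)
from embow.annotate import AnnotationDataset, EvalResult


def toy_dataset(rng, n=40, n_terms=4, prevalences=(0.6, 0.5, 0.4, 0.3)):
    Y = (rng.random((n, n_terms)) < np.asarray(prevalences)).astype(int)
    Y[:2, :] = 1  # guarantee every term has positives
    Y[2:4, :] = 0
    X = Y @ rng.random((n_terms, 6)) + 0.05 * rng.random((n, 6))
    labels = {f"g{i}": {f"t{j}" for j in range(n_terms) if Y[i, j]} for i in range(n)}
    return build_dataset(X, [f"g{i}" for i in range(n)], labels)


def test_terms_ordered_by_frequency_ties_by_name(rng):
    labels = {"a": {"x", "y"}, "b": {"x", "z"}, "c": {"y"}}
    ds = build_dataset(np.zeros((3, 2)), ["a", "b", "c"], labels)
    # x:2 y:2 z:1 -> frequency desc, ties alphabetical
    assert ds.term_names == ["x", "y", "z"]
    assert ds.term_counts.tolist() == [2, 2, 1]


def test_select_terms_prefix_property_and_drops(rng):
    ds = toy_dataset(rng)
    full = select_terms(ds, len(ds.term_names))
    assert full.term_names == ds.term_names
    assert len(full.group_ids) <= len(ds.group_ids)
    sub2 = select_terms(ds, 2)
    sub3 = select_terms(ds, 3)
    assert sub3.term_names[:2] == sub2.term_names  # nested term sets
    # every retained group carries at least one retained term
    assert np.all(sub2.Y.sum(axis=1) > 0)
    with pytest.raises(ValueError):
        select_terms(ds, 99)


def test_select_terms_rejects_rare_term():
    labels = {f"g{i}": ({"common"} if i < 4 else {"other"}) | ({"rare"} if i == 0 else set())
              for i in range(8)}
    ds = build_dataset(np.zeros((8, 2)), list(labels), labels)
    with pytest.raises(ValueError, match="rare"):
        select_terms(ds, 3)


def test_partitions_stratify_each_term(rng):
    ds = toy_dataset(rng, n=60)
    parts = make_partitions(ds, n_partitions=10, seed=1)
    assert len(parts) == 10
    for tr, te in parts:
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == len(ds.group_ids)
        assert abs(len(tr) - len(te)) <= 1
        for j in range(len(ds.term_names)):
            pos_tr = int(ds.Y[tr, j].sum())
            pos_te = int(ds.Y[te, j].sum())
            assert abs(pos_tr - pos_te) <= 1  # as even as parity allows
            assert pos_tr >= 1 and pos_te >= 1


def test_minimal_two_positive_term_forced_split():
    labels = {"a": {"t"}, "b": {"t"}, "c": set(), "d": set()}
    X = np.zeros((4, 2))
    ds = AnnotationDataset(X=X, Y=np.array([[1], [1], [0], [0]]),
                           term_names=["t"], group_ids=list(labels))
    for tr, te in make_partitions(ds, n_partitions=8, seed=0):
        assert int(ds.Y[tr, 0].sum()) == 1 and int(ds.Y[te, 0].sum()) == 1


def test_oversample_contract(rng):
    X = rng.random((12, 3))
    y = np.array([1, 1] + [0] * 10)
    Xb, yb = oversample(X, y, seed=4)
    assert (yb == 1).sum() == (yb == 0).sum() == 10
    # negatives untouched
    assert np.array_equal(Xb[yb == 0], X[y == 0])
    # resampled positives all come from the original positive rows
    pos_rows = {tuple(r) for r in X[y == 1]}
    assert all(tuple(r) in pos_rows for r in Xb[yb == 1])
    # deterministic under seed; no-op when balanced
    Xb2, yb2 = oversample(X, y, seed=4)
    assert np.array_equal(Xb, Xb2)
    Xn, yn = oversample(X[:4], np.array([1, 1, 0, 0]), seed=4)
    assert np.array_equal(Xn, X[:4])
    with pytest.raises(ValueError):
        oversample(X, np.zeros(12, dtype=int), seed=0)


@pytest.mark.parametrize("classifier", ["linear_svm", "logistic", "ridge"])
def test_train_ovr_separable_and_deterministic(rng, classifier):
    ds = toy_dataset(rng, n=50)
    models = train_ovr(ds.X, ds.Y, classifier=classifier)
    assert len(models) == len(ds.term_names)
    res = evaluate(models, ds.X, ds.Y, ds.term_names)
    # the toy features are (nearly) linear in the labels: training fit is tight
    assert res.frame["auc"].mean() > 0.95

    perm = np.random.default_rng(0).permutation(len(ds.X))
    models_p = train_ovr(ds.X[perm], ds.Y[perm], classifier=classifier)
    for m, mp in zip(models, models_p):
        a = m.decision_function(ds.X)
        b = mp.decision_function(ds.X)
        assert np.allclose(a, b, atol=1e-6)


def test_train_ovr_cv_selection_runs(rng):
    ds = toy_dataset(rng, n=40)
    models = train_ovr(ds.X, ds.Y, classifier="logistic", cv_select=True)
    assert len(models) == len(ds.term_names)


def test_single_class_term_raises(rng):
    X = rng.random((6, 3))
    with pytest.raises(ValueError):
        train_ovr(X, np.ones((6, 1), dtype=int))


def test_evaluate_hand_contingency():
    class Fixed:
        def __init__(self, s):
            self.s = np.asarray(s, dtype=float)

        def decision_function(self, X):
            return self.s

    # contingency TP=3 FP=1 FN=1 TN=5
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    scores = np.array([1, 1, 1, -1, 1, -1, -1, -1, -1, -1], dtype=float)
    res = evaluate([Fixed(scores)], np.zeros((10, 1)), y[:, None], ["t"])
    row = res.frame.iloc[0]
    assert row["sensitivity"] == pytest.approx(0.75)
    assert row["specificity"] == pytest.approx(5 / 6)
    assert row["f1"] == pytest.approx(0.75)

    # perfect scores
    res2 = evaluate([Fixed(2 * y - 1)], np.zeros((10, 1)), y[:, None], ["t"])
    assert res2.frame.iloc[0]["auc"] == 1.0 and res2.frame.iloc[0]["f1"] == 1.0


def test_auc_random_scores_near_half_and_monotone_invariant(rng):
    class Fixed:
        def __init__(self, s):
            self.s = s

        def decision_function(self, X):
            return self.s

    y = np.array([0, 1] * 500)
    s = rng.normal(size=1000)
    auc = evaluate([Fixed(s)], np.zeros((1000, 1)), y[:, None], ["t"]).frame.iloc[0]["auc"]
    assert abs(auc - 0.5) < 0.05
    # AUC invariant under a strictly monotone transform of the scores
    auc2 = evaluate([Fixed(np.exp(3 * s))], np.zeros((1000, 1)), y[:, None],
                    ["t"]).frame.iloc[0]["auc"]
    assert auc == pytest.approx(auc2, abs=1e-12)


def test_macro_f1_equals_mean_of_per_term_f1(rng):
    ds = toy_dataset(rng, n=50)
    models = train_ovr(ds.X, ds.Y)
    res = evaluate(models, ds.X, ds.Y, ds.term_names)
    macro = res.macro_per_partition()
    assert macro["f1"].iloc[0] == pytest.approx(res.frame["f1"].mean())


def test_oversampling_never_reduces_recall_on_toy():
    # two positives drowned by many negatives, scaled so C=1 underfits
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(2.0, 0.3, size=(3, 1)),
                   rng.normal(-0.5, 0.3, size=(30, 1))]) * 0.1
    y = np.array([1] * 3 + [0] * 30)
    base = train_ovr(X, y[:, None])[0]
    over = train_ovr(X, y[:, None], oversample_positives=True, seed=0)[0]
    rec_base = ((base.decision_function(X) > 0) & (y == 1)).sum() / 3
    rec_over = ((over.decision_function(X) > 0) & (y == 1)).sum() / 3
    assert rec_over >= rec_base


def test_experiment_table_shape_and_determinism(small_group_set, small_codebook):
    cfg = AnnotationConfig(modes=("global-hard",), term_counts=(2, 4),
                           n_partitions=3, seed=3)
    a = run_annotation_experiment(small_group_set, cfg, codebook=small_codebook)
    b = run_annotation_experiment(small_group_set, cfg, codebook=small_codebook)
    pd.testing.assert_frame_equal(a, b)
    assert set(a.columns) == {"dataset", "n_terms", "mode", "metric", "mean", "sd"}
    # one row per (term count, metric) for the single mode
    assert len(a) == 2 * 4
    assert ((a["mean"] >= 0) & (a["mean"] <= 1)).all() and (a["sd"] >= 0).all()
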