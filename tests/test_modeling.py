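import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quadscreen import modeling
from quadscreen.modeling import (
    GAParams,
    evaluate,
    exhaustive_select,
    fit_lda,
    fit_rf,
    ga_select,
    load_model,
    metrics_from_confusion,
    save_model,
    split_external,
    split_train_test,
    wilks_lambda,
)
from quadscreen.multitask import ConditionMeans


def fake_records(n_pos, n_neg):
    recs = [SimpleNamespace(record_id=f"P{i}", class_label=1) for i in range(n_pos)]
    recs += [SimpleNamespace(record_id=f"N{i}", class_label=0) for i in range(n_neg)]
    return recs


# --- splitting ---

def test_stratified_external_split_20_percent_per_class():
    plan = split_external(fake_records(60, 40), seed=1)
    ext = set(plan.second)
    assert sum(1 for r in ext if r.startswith("P")) == 12
    assert sum(1 for r in ext if r.startswith("N")) == 8
    assert len(set(plan.first) | ext) == 100


def test_single_class_split_warns_and_keeps_minimum_one():
    with pytest.warns(UserWarning):
        plan = split_external(fake_records(10, 0), seed=1)
    assert len(plan.second) == 2


def test_split_deterministic_under_seed():
    a = split_external(fake_records(33, 21), seed=9)
    b = split_external(fake_records(33, 21), seed=9)
    assert a == b


@settings(deadline=None, max_examples=40)
@given(st.integers(10, 10000), st.floats(0.1, 0.5))
def test_stratified_ratio_within_one_record_per_class(n, frac):
    n_pos = n // 2
    n_neg = n - n_pos
    plan = split_external(fake_records(n_pos, n_neg), fraction=frac, seed=0)
    ext = set(plan.second)
    for prefix, total in (("P", n_pos), ("N", n_neg)):
        got = sum(1 for r in ext if r.startswith(prefix))
        assert abs(got - total * frac) <= 1


def test_random_train_test_split_sizes():
    ids = [f"r{i}" for i in range(100)]
    plan = split_train_test(ids, method="random", fraction=0.2, seed=4)
    assert len(plan.second) == 20 and len(plan.first) == 80
    assert set(plan.first) | set(plan.second) == set(ids)


def test_euclidean_split_takes_every_kth_by_distance_rank():
    ids = [f"r{i}" for i in range(10)]
    # collinear points: distance rank equals coordinate rank
    m = pd.DataFrame({"x": np.arange(10.0)}, index=ids)
    plan = split_train_test(ids, method="euclidean", fraction=0.2, matrix=m)
    # centroid 4.5; distances: 4.5,3.5,...,0.5,0.5,...,4.5 -> ranks by
    # stable sort: r4,r5,r3,r6,r2,r7,r1,r8,r0,r9; every 5th -> r2, r9
    assert set(plan.second) == {"r2", "r9"}


def test_split_fraction_bounds():
    with pytest.raises(ValueError):
        split_train_test(["a", "b"], fraction=0.9)
    with pytest.raises(ValueError):
        split_external(fake_records(5, 5), fraction=0.0)


# --- Wilks lambda ---

def test_wilks_identical_class_means_gives_one():
    X = np.array([[1.0, 0.0], [3.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
    y = [0, 0, 1, 1]  # both class means are (2, 1)
    assert wilks_lambda(X, y) == pytest.approx(1.0)


def test_wilks_zero_within_class_variance_limit():
    lam = wilks_lambda([[0.0], [0.0], [10.0], [10.0]], [0, 0, 1, 1])
    assert lam == pytest.approx(0.0, abs=1e-12)


def test_wilks_hand_computed_one_dimensional_instances():
    # {1,2} vs {3,4}: W = 1, T = 5 -> 0.2 ; {1,2} vs {4,5}: W = 1, T = 10 -> 0.1
    assert wilks_lambda([[1], [2], [3], [4]], [0, 0, 1, 1]) == pytest.approx(0.2)
    assert wilks_lambda([[1], [2], [4], [5]], [0, 0, 1, 1]) == pytest.approx(0.1)


def test_wilks_singular_total_matrix_errors():
    X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])  # collinear
    with pytest.raises(np.linalg.LinAlgError, match="prune"):
        wilks_lambda(X, [0, 0, 1, 1])


def test_wilks_requires_two_populated_classes():
    with pytest.raises(ValueError):
        wilks_lambda([[1], [2], [3]], [0, 0, 0])
    with pytest.raises(ValueError):
        wilks_lambda([[1], [2], [3]], [0, 0, 1])


# --- LDA ---

def test_lda_separates_distant_clusters():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"x": np.r_[rng.normal(-5, 0.5, 50), rng.normal(5, 0.5, 50)]})
    y = np.r_[np.zeros(50), np.ones(50)]
    model = fit_lda(X, y)
    assert evaluate(model, X, y).metrics["accuracy"] == 1.0


def test_lda_null_labels_mcc_concentrates_near_zero():
    """Training MCC on label-permuted data: E|MCC| ~ sqrt(k/n), so the
    permutation-null mean over draws stays well below 0.15."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
    mccs = []
    for _ in range(20):
        y = rng.permutation(np.r_[np.zeros(250, int), np.ones(250, int)])
        mcc = evaluate(fit_lda(X, y), X, y).metrics["mcc"]
        mccs.append(abs(mcc))
    assert np.mean(mccs) < 0.15


def test_lda_singular_covariance_gets_ridge(caplog):
    X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [0.0, 1.0, 2.0, 3.0]})
    y = [0, 0, 1, 1]
    model = fit_lda(X, y)
    assert model.params["ridge_applied"]
    assert np.isfinite(model.params["weights"]).all()


def test_lda_matches_sklearn_on_well_conditioned_data():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
    y = (X["a"] + 0.5 * X["b"] + rng.normal(0, 0.5, 200) > 0).astype(int)
    ours = fit_lda(X, y).predict(X)
    ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(X)
    assert (ours == ref).mean() > 0.99


def test_lda_predict_refuses_column_mismatch():
    X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
    model = fit_lda(X, [0, 0, 1, 1])
    with pytest.raises(ValueError, match="column mismatch"):
        model.predict(X.rename(columns={"a": "b"}))


# --- RF ---

def test_rf_learns_xor_pattern():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.uniform(size=(400, 2)), columns=["u", "v"])
    y = ((X["u"] > 0.5) ^ (X["v"] > 0.5)).astype(int)
    model = fit_rf(X, y, seed=0)
    assert evaluate(model, X, y).metrics["accuracy"] >= 0.95


def test_rf_deterministic_under_seed():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
    y = rng.integers(0, 2, 100)
    p1 = fit_rf(X, y, n_trees=50, seed=5).predict(X)
    p2 = fit_rf(X, y, n_trees=50, seed=5).predict(X)
    assert np.array_equal(p1, p2)


def test_rf_zero_trees_rejected():
    with pytest.raises(ValueError):
        fit_rf(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], n_trees=0)


# --- metrics / evaluate ---

def test_perfect_confusion_metrics():
    m = metrics_from_confusion(tp=5, tn=5, fp=0, fn=0)
    assert m["accuracy"] == 1.0 and m["mcc"] == 1.0


def test_hand_computed_confusion_metrics():
    m = metrics_from_confusion(tp=3, fp=1, tn=4, fn=2)
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["precision"] == pytest.approx(0.75)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.8)


def test_zero_denominator_metrics_are_undefined_not_zero():
    m = metrics_from_confusion(tp=0, tn=5, fp=0, fn=5)  # all predicted negative
    assert m["precision"] is None
    assert m["mcc"] is None
    assert m["sensitivity"] == 0.0
    assert m["specificity"] == 1.0


def test_metrics_match_sklearn():
    from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 200)
    p = rng.integers(0, 2, 200)
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    m = metrics_from_confusion(tp, tn, fp, fn)
    assert m["accuracy"] == pytest.approx(accuracy_score(y, p))
    assert m["f_measure"] == pytest.approx(f1_score(y, p))
    assert m["mcc"] == pytest.approx(matthews_corrcoef(y, p))


def test_cross_validation_reports_mean_and_sd():
    rng = np.random.default_rng(11)
    X = pd.DataFrame(rng.normal(size=(120, 2)), columns=["a", "b"])
    y = (X["a"] > 0).astype(int)
    model = fit_lda(X, y)
    rep = evaluate(model, X, y, folds=10)
    assert rep.cv_mean["accuracy"] > 0.9
    assert rep.cv_sd["accuracy"] is not None and rep.cv_sd["accuracy"] >= 0


# --- GA ---

def _planted_matrix(n=200, n_noise=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_noise + 2))
    y = (X[:, 0] - X[:, 1] > 0).astype(int)
    cols = ["inf1", "inf2"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


def test_ga_finds_planted_columns():
    X, y = _planted_matrix()
    res = ga_select(X, y, n_features=2, ga_params=GAParams(seed=1), fitness="wilks")
    assert set(res.columns) == {"inf1", "inf2"}


def test_ga_matches_exhaustive_on_small_instance():
    X, y = _planted_matrix(n=80, n_noise=10, seed=2)  # 12 columns, C(12,2)=66
    best_cols, best_score = exhaustive_select(X, y, n_features=2, fitness="wilks")
    res = ga_select(X, y, n_features=2, ga_params=GAParams(seed=3), fitness="wilks")
    assert res.fitness == pytest.approx(best_score, abs=1e-12)
    assert set(res.columns) == set(best_cols)


def test_ga_deterministic_and_zero_generations_contract():
    X, y = _planted_matrix(n=60, n_noise=8, seed=4)
    p = GAParams(seed=9, generations=0, pop_size=20)
    r1 = ga_select(X, y, n_features=2, ga_params=p)
    r2 = ga_select(X, y, n_features=2, ga_params=p)
    assert r1.columns == r2.columns and len(r1.trace) == 1


def test_ga_mcc_and_combined_fitness_run():
    X, y = _planted_matrix(n=60, n_noise=5, seed=5)
    for fitness in ("mcc", "combined"):
        res = ga_select(X, y, n_features=2, ga_params=GAParams(seed=2, generations=5, pop_size=15), fitness=fitness)
        assert len(res.columns) == 2


def test_ga_overfit_guard():
    X, y = _planted_matrix(n=10, n_noise=12, seed=6)
    with pytest.raises(ValueError, match="overfit"):
        ga_select(X, y, n_features=10)


# --- bundles ---

def _bundled_model(tmp_path, kind="lda"):
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["D1|f", "D2|f"])
    y = (X["D1|f"] > 0).astype(int)
    model = fit_lda(X, y) if kind == "lda" else fit_rf(X, y, n_trees=20, seed=1)
    model.backend = "builtin-2d-v1"
    model.condition_means = ConditionMeans(
        fields=("f",),
        descriptors=("D1", "D2"),
        means={"f": {"K": np.zeros(2)}},
        counts={"f": {"K": 40}},
    )
    from quadscreen.applicability import build_ad_reference

    fps = (rng.uniform(size=(40, 166)) > 0.5).astype(float)
    model.ad_reference = build_ad_reference(fps, X)
    return model, X, y


@pytest.mark.parametrize("kind", ["lda", "rf"])
def test_save_load_roundtrip_predictions_identical(tmp_path, kind):
    model, X, y = _bundled_model(tmp_path, kind)
    save_model(model, tmp_path / "bundle")
    loaded = load_model(tmp_path / "bundle")
    assert np.array_equal(model.predict(X), loaded.predict(X))
    assert loaded.backend == model.backend
    assert loaded.condition_means.descriptors == ("D1", "D2")
    assert loaded.ad_reference.n == 40


def test_tampered_bundle_detected(tmp_path):
    model, _, _ = _bundled_model(tmp_path)
    save_model(model, tmp_path / "bundle")
    meta = (tmp_path / "bundle" / "metadata.json").read_text()
    (tmp_path / "bundle" / "metadata.json").write_text(meta.replace("D1|f", "Dx|f"))
    with pytest.raises(modeling.ModelBundleError, match="hash"):
        load_model(tmp_path / "bundle")


def test_bundle_requires_condition_means(tmp_path):
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(10, 1)), columns=["a"])
    model = fit_lda(X, [0] * 5 + [1] * 5)
    with pytest.raises(ValueError, match="ConditionMeans"):
        save_model(model, tmp_path / "bundle")
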