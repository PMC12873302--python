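"""Feature selection stages and the stacked ensemble."""

import numpy as np
import pandas as pd
import pytest

import fcstack as fc
from fcstack import spd
from fcstack.dataset import ProblemSpec
from fcstack.stacking import (
    LABEL_COL,
    StackedConnectivityClassifier,
    aggregate_per_subject,
    class_distinctiveness,
    filter_select,
    fit_meta,
    generate_oof_probabilities,
    sequential_select,
    subject_folds,
)
from tests.conftest import make_cohort, random_spd_stack


# ----------------------------------------------------- class distinctiveness


def test_distinctiveness_identical_distributions_small(rng):
    base = random_spd_stack(rng, 10, 3)
    Cs = np.concatenate([base, base])
    y = np.repeat([0, 1], 10)
    assert class_distinctiveness(Cs, y, "log_euclidean") <= 0.1


def test_distinctiveness_separated_clusters_large(rng):
    """Between-mean distance ~10x dispersion gives a score >= 5."""
    jitter = 0.02
    c0 = np.stack([np.eye(3) + jitter * np.diag(rng.standard_normal(3)) for _ in range(10)])
    c1 = np.stack([3 * np.eye(3) + jitter * np.diag(rng.standard_normal(3)) for _ in range(10)])
    Cs = np.concatenate([c0, c1])
    y = np.repeat([0, 1], 10)
    assert class_distinctiveness(Cs, y, "euclidean") >= 5


def test_distinctiveness_relabel_invariant(rng):
    Cs = random_spd_stack(rng, 20, 3)
    y = np.repeat([0, 1], 10)
    a = class_distinctiveness(Cs, y, "log_euclidean")
    b = class_distinctiveness(Cs, 1 - y, "log_euclidean")
    assert a == pytest.approx(b, rel=1e-10)


def test_distinctiveness_errors(rng):
    Cs = random_spd_stack(rng, 4, 2)
    with pytest.raises(ValueError, match="exactly 2"):
        class_distinctiveness(Cs, np.array([0, 1, 2, 0]), "euclidean")
    # identical matrices in both classes: zero dispersion, zero numerator
    same = np.stack([np.eye(2)] * 4)
    assert class_distinctiveness(same, np.array([0, 0, 1, 1]), "euclidean") == 0.0
    distinct = np.stack([np.eye(2), np.eye(2), 2 * np.eye(2), 2 * np.eye(2)])
    with pytest.raises(ZeroDivisionError):
        class_distinctiveness(distinct, np.array([0, 0, 1, 1]), "euclidean")


# ------------------------------------------------------------ filter select


def test_filter_select_top_half():
    scores = {(f"b{i}", "M"): float(i) for i in range(60)}
    kept = filter_select(scores)
    assert len(kept) == 30
    assert all(int(k[0][1:]) >= 30 for k in kept)


def test_filter_select_small_and_ties():
    assert filter_select({("a", "x"): 1.0, ("b", "x"): 0.5}) == [("a", "x")]
    tied = {("d", "x"): 1.0, ("a", "x"): 1.0, ("c", "x"): 1.0, ("b", "x"): 1.0}
    assert filter_select(tied) == [("a", "x"), ("b", "x")]
    with pytest.raises(ValueError):
        filter_select({})


# ------------------------------------------------------------- OOF + folds


@pytest.fixture(scope="module")
def small_ds():
    cohort = make_cohort(seed=21, n_per_group=4, epochs=(3, 4), n_channels=5)
    ds = fc.extract_features(cohort, bands=("alpha", "gamma"), metrics=("Cov", "Corr"))
    return ds, ProblemSpec("C", "P")


def test_oof_no_leakage(small_ds):
    """Each epoch is scored by a model that never saw its subject."""
    ds, problem = small_ds
    audit = []
    table = generate_oof_probabilities(
        ds, problem, ds.keys, n_folds=2, seed=0, audit=audit
    )
    assert not table.drop(columns=["subject_id", "epoch_index", LABEL_COL]).isna().any().any()
    scored = table.set_index("subject_id")
    for rec in audit:
        assert rec["train_subjects"].isdisjoint(rec["scored_subjects"])
    # every subject is scored by some model and never by one it trained
    for s in ds.subjects():
        assert any(s in rec["scored_subjects"] for rec in audit)
    assert len(scored) == ds.n_epochs


def test_two_fold_training_sizes(small_ds):
    ds, problem = small_ds
    folds = subject_folds(ds, problem, n_folds=2, seed=0)
    for train, test in folds:
        assert len(train) == 4 and len(test) == 4


def test_too_few_subjects_for_folds(small_ds):
    ds, problem = small_ds
    with pytest.raises(ValueError, match="fewer than"):
        subject_folds(ds, problem, n_folds=5, seed=0)


def test_oof_probabilities_in_unit_interval(small_ds):
    ds, problem = small_ds
    table = generate_oof_probabilities(ds, problem, ds.keys, n_folds=2, seed=0)
    probs = table.drop(columns=["subject_id", "epoch_index", LABEL_COL])
    assert ((probs >= 0) & (probs <= 1)).all().all()


# -------------------------------------------------------------- aggregation


def test_aggregate_mean_and_counts():
    table = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s1", "s2"],
            "epoch_index": [0, 1, 2, 0],
            LABEL_COL: [1, 1, 1, 0],
            "alpha/Cov": [0.2, 0.4, 0.6, 0.9],
        }
    )
    out = aggregate_per_subject(table)
    assert len(out) == 2
    assert out.set_index("subject_id").loc["s1", "alpha/Cov"] == pytest.approx(0.4)
    assert out.set_index("subject_id").loc["s2", "alpha/Cov"] == pytest.approx(0.9)


def test_aggregate_mixed_labels_error():
    table = pd.DataFrame(
        {
            "subject_id": ["s1", "s1"],
            "epoch_index": [0, 1],
            LABEL_COL: [1, 0],
            "alpha/Cov": [0.5, 0.5],
        }
    )
    with pytest.raises(ValueError, match="mixed labels"):
        aggregate_per_subject(table)


# --------------------------------------------------------------- meta model


def subject_table(cols: dict, labels) -> pd.DataFrame:
    df = pd.DataFrame({f"{b}/{m}": v for (b, m), v in cols.items()})
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(labels))])
    df[LABEL_COL] = labels
    return df


def test_meta_perfectly_ordered_column_gives_auc_one(rng):
    y = np.repeat([0, 1], 10)
    col = np.concatenate([rng.uniform(0.0, 0.4, 10), rng.uniform(0.6, 1.0, 10)])
    tab = subject_table({("alpha", "Cov"): col}, y)
    meta = fit_meta(tab, [("alpha", "Cov")])
    assert fc.roc_auc(meta.predict_proba(tab), y) == 1.0


def test_meta_constant_columns_zero_coef_prior_prediction():
    """L1 zeroes uninformative coefficients; prediction is the class prior."""
    y = np.array([1] * 6 + [0] * 14)
    tab = subject_table({("alpha", "Cov"): np.full(20, 0.5)}, y)
    meta = fit_meta(tab, [("alpha", "Cov")])
    assert meta.coefficients["alpha/Cov"] == 0.0
    np.testing.assert_allclose(meta.predict_proba(tab), 6 / 20, atol=1e-9)


def test_meta_balanced_constant_gives_half():
    y = np.array([1] * 6 + [0] * 14)
    tab = subject_table({("alpha", "Cov"): np.full(20, 0.5)}, y)
    meta = fit_meta(tab, [("alpha", "Cov")], balanced=True)
    np.testing.assert_allclose(meta.predict_proba(tab), 0.5, atol=1e-12)


def test_meta_column_scaling_preserves_sign_pattern(rng):
    y = np.repeat([0, 1], 10)
    col = y * 0.5 + rng.uniform(0, 0.3, 20)
    noise = rng.uniform(0, 1, 20)
    tab1 = subject_table({("alpha", "Cov"): col, ("beta", "Cov"): noise}, y)
    tab10 = subject_table({("alpha", "Cov"): col * 10, ("beta", "Cov"): noise}, y)
    m1 = fit_meta(tab1, [("alpha", "Cov"), ("beta", "Cov")], alpha=0.05)
    m10 = fit_meta(tab10, [("alpha", "Cov"), ("beta", "Cov")], alpha=0.05)
    s1 = np.sign([m1.coefficients["alpha/Cov"], m1.coefficients["beta/Cov"]])
    s10 = np.sign([m10.coefficients["alpha/Cov"], m10.coefficients["beta/Cov"]])
    assert s1[0] == s10[0] == 1.0


def test_meta_single_class_error():
    tab = subject_table({("alpha", "Cov"): np.linspace(0, 1, 6)}, np.ones(6, int))
    with pytest.raises(ValueError, match="both classes"):
        fit_meta(tab, [("alpha", "Cov")])


# --------------------------------------------------------- wrapper selection


def test_wrapper_duplicates_select_one(rng):
    y = np.repeat([0, 1], 10)
    informative = y * 0.6 + rng.uniform(0, 0.2, 20)
    cols = {
        ("alpha", "Cov"): informative,
        ("beta", "Cov"): informative.copy(),
        ("delta", "Cov"): informative.copy(),
    }
    tab = subject_table(cols, y)
    selected = sequential_select(tab, list(cols), n_folds=5, seed=0)
    assert len(selected) == 1


def test_wrapper_noise_minimum_one(rng):
    """Uninformative features never yield an empty selection."""
    y = np.repeat([0, 1], 10)
    cols = {("a", "x"): rng.uniform(size=20), ("b", "x"): rng.uniform(size=20)}
    tab = subject_table(cols, y)
    selected = sequential_select(tab, list(cols), n_folds=5, seed=3)
    assert len(selected) >= 1
    # with constant columns every internal score ties, so exactly the first
    # (lexicographically smallest) key is taken and no addition improves
    const = subject_table(
        {("b", "x"): np.full(20, 0.5), ("a", "x"): np.full(20, 0.5)}, y
    )
    only = sequential_select(const, [("a", "x"), ("b", "x")], n_folds=5, seed=3)
    assert only == [("a", "x")]


def test_wrapper_deterministic(rng):
    y = np.repeat([0, 1], 10)
    cols = {
        ("a", "x"): rng.uniform(size=20),
        ("b", "x"): y * 0.5 + rng.uniform(0, 0.4, 20),
        ("c", "x"): rng.uniform(size=20),
    }
    tab = subject_table(cols, y)
    a = sequential_select(tab, list(cols), seed=7)
    b = sequential_select(tab, list(cols), seed=7)
    assert a == b


# ---------------------------------------------------------------- full stack


def test_stack_fit_predict_separable(separable_dataset):
    ds, problem = separable_dataset
    stack = StackedConnectivityClassifier(problem=problem, n_folds=5)
    stack.fit(ds)
    # filter halves the candidate keys
    assert len(stack.retained_keys_) == 2
    probs = stack.predict_proba_subjects(ds)
    assert probs.between(0, 1).all()
    preds = stack.predict_subjects(ds)
    labels = ds.subject_labels()
    assert (preds == labels[preds.index]).mean() == 1.0


def test_stack_unseen_key_errors(separable_dataset):
    ds, problem = separable_dataset
    stack = StackedConnectivityClassifier(problem=problem, n_folds=5).fit(ds)
    reduced = fc.ConnectivityDataset(
        features={k: v for k, v in ds.features.items() if k[0] == "theta"},
        subject_ids=ds.subject_ids,
        groups=ds.groups,
        epoch_index=ds.epoch_index,
    )
    if any(k[0] == "alpha" for k in stack.selected_keys_):
        with pytest.raises(KeyError, match="lacks feature key"):
            stack.predict_proba_subjects(reduced)


def test_stack_requires_problem(separable_dataset):
    ds, _ = separable_dataset
    with pytest.raises(ValueError, match="ProblemSpec"):
        StackedConnectivityClassifier().fit(ds)


def test_inverse_epoch_weights_equalize_subjects(small_ds):
    """Duplicating a subject's epochs leaves weighted base fits unchanged."""
    ds, problem = small_ds
    key = ("alpha", "Cov")
    y = ds.binary_y(problem)
    from fcstack.fgmdm import FgMDM

    base = FgMDM().fit(ds.features[key], y, sample_weight=ds.sample_weights())

    # duplicate the first subject's epochs tenfold
    sid = ds.subject_ids.astype(str)
    first = ds.subjects()[0]
    idx = np.concatenate([np.flatnonzero(sid == first)] * 9 + [np.arange(ds.n_epochs)])
    dup = fc.ConnectivityDataset(
        features={key: ds.features[key][idx]},
        subject_ids=ds.subject_ids[idx],
        groups=ds.groups[idx],
        epoch_index=np.arange(len(idx)),
    )
    dup_model = FgMDM().fit(
        dup.features[key], dup.binary_y(problem), sample_weight=dup.sample_weights()
    )
    np.testing.assert_allclose(base.reference_, dup_model.reference_, atol=1e-8)
    np.testing.assert_allclose(base.class_means_, dup_model.class_means_, atol=1e-8)


def test_filter_prefers_alpha_over_gamma_under_alpha_effect():
    """With an alpha-coupling group difference the filter ranks alpha keys
    above gamma keys in >= 80% of seeds."""
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cohort = make_cohort(
            seed=100 + seed, n_per_group=4, epochs=(3, 3), n_channels=5
        )
        ds = fc.extract_features(cohort, bands=("alpha", "gamma"), metrics=("Corr",))
        y = ds.binary_y(ProblemSpec("C", "P"))
        s_alpha = class_distinctiveness(ds.features[("alpha", "Corr")], y, "log_euclidean")
        s_gamma = class_distinctiveness(ds.features[("gamma", "Corr")], y, "log_euclidean")
        wins += s_alpha > s_gamma
    assert wins >= 0.8 * n_seeds
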