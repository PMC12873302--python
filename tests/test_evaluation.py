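"""Metrics, DeLong test, diversity, dendrogram, and demographics statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fcstack as fc
from fcstack.dataset import ProblemSpec
from fcstack.evaluation import (
    anova_from_summaries,
    chi_square_counts,
    classification_metrics,
    delong_pvalue,
    demographics_stats,
    disagreement_dendrogram,
    disagreement_matrix,
    losocv_evaluate,
    normalized_disagreement,
    roc_auc,
)


# --------------------------------------------------------------- metrics


def test_hand_counted_confusion_table():
    """labels [1,1,0,0], preds [1,0,0,0]: acc .75, sens .5, spec 1, F1 2/3."""
    rep = classification_metrics([0.9, 0.1, 0.2, 0.3], [1, 1, 0, 0])
    assert rep.accuracy == 0.75
    assert rep.sensitivity == 0.5
    assert rep.specificity == 1.0
    assert rep.f1 == pytest.approx(2 / 3)


def test_perfect_predictions():
    rep = classification_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert all(v == 1.0 for v in rep.as_dict().values())


def test_all_ties_auc_half():
    rep = classification_metrics([0.5] * 6, [1, 1, 1, 0, 0, 0])
    assert rep.roc_auc == 0.5


def test_metric_consistency_identity(rng):
    """accuracy == (sens*n_pos + spec*n_neg) / n, exactly."""
    for _ in range(50):
        n = int(rng.integers(6, 30))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        p = rng.uniform(size=n)
        rep = classification_metrics(p, y)
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        lhs = rep.accuracy
        rhs = (rep.sensitivity * n_pos + rep.specificity * n_neg) / n
        assert lhs == pytest.approx(rhs, abs=1e-12)


def test_auc_brute_force_oracle():
    """Rank AUC equals pairwise comparison counting (ties get 1/2credit)."""
    rng = np.random.default_rng(8)
    for _ in range(500):
        n = int(rng.integers(4, 25))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        p = np.round(rng.uniform(size=n), 1)  # coarse grid to force ties
        pos, neg = p[y == 1], p[y == 0]
        brute = np.mean([
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        ])
        assert roc_auc(p, y) == pytest.approx(brute, abs=1e-12)


def test_metrics_validation():
    with pytest.raises(ValueError):
        classification_metrics([0.5, 1.5], [0, 1])
    with pytest.raises(ValueError, match="single class"):
        classification_metrics([0.5, 0.6], [1, 1])


# ----------------------------------------------------------------- DeLong


def test_delong_perfect_separation_significant():
    rng = np.random.default_rng(0)
    p = np.concatenate([rng.uniform(0.6, 1.0, 20), rng.uniform(0.0, 0.4, 20)])
    y = np.repeat([1, 0], 20)
    auc, pval = delong_pvalue(p, y)
    assert auc == 1.0
    assert pval < 0.001


def test_delong_null_calibration():
    """Under random pairing, p-values are roughly uniform."""
    rng = np.random.default_rng(1)
    big = 0
    for _ in range(200):
        y = np.repeat([1, 0], 15)
        p = rng.uniform(size=30)
        _, pv = delong_pvalue(p, y)
        big += pv > 0.5
    assert 0.3 <= big / 200 <= 0.7


def test_delong_class_swap_antisymmetry(rng):
    p = rng.uniform(size=24)
    y = np.repeat([1, 0], 12)
    auc1, p1 = delong_pvalue(p, y)
    auc2, p2 = delong_pvalue(p, 1 - y)
    assert auc2 == pytest.approx(1 - auc1, abs=1e-12)
    assert p2 == pytest.approx(p1, abs=1e-9)


def test_delong_degenerate_variance_warns():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        _, pv = delong_pvalue([0.5] * 10, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    assert pv == 1.0


# -------------------------------------------------------------- diversity


def test_disagreement_identical_is_zero():
    preds = np.array([1, 0, 1, 0])
    assert normalized_disagreement(preds, preds, [1, 0, 0, 1]) == 0.0


def test_disagreement_fixed_example():
    """Hand oracle: 2 disagreements; pair-ensemble (avg >= .5) predicts
    [1,1,1,0] vs labels [1,1,0,0] so accuracy 3/4; D = 2/(4*(1/4)) = 2."""
    D = normalized_disagreement([1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0])
    assert D == pytest.approx(2.0)


def test_disagreement_symmetric(rng):
    for _ in range(100):
        a = rng.integers(0, 2, 12)
        b = rng.integers(0, 2, 12)
        y = rng.integers(0, 2, 12)
        try:
            d1 = normalized_disagreement(a, b, y)
            d2 = normalized_disagreement(b, a, y)
        except ZeroDivisionError:
            continue
        assert d1 == pytest.approx(d2, abs=1e-12)


def test_disagreement_matrix_and_dendrogram():
    y = np.array([1, 1, 0, 0, 1, 0])
    preds = {
        "a": np.array([1, 1, 0, 0, 1, 0]),
        "b": np.array([1, 1, 0, 0, 1, 0]),  # identical to a
        "c": np.array([0, 1, 1, 0, 0, 1]),
    }
    D = disagreement_matrix(preds, y)
    assert D.loc["a", "b"] == 0.0
    clusters, Z, newick = disagreement_dendrogram(D)
    assert clusters["a"] == clusters["b"]
    assert clusters["c"] != clusters["a"]
    assert newick.count("(") == newick.count(")") - 0
    for name in preds:
        assert name in newick


def test_dendrogram_two_classifiers():
    D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
    clusters, Z, _ = disagreement_dendrogram(D)
    assert Z.shape == (1, 4)
    assert set(clusters) == {"a", "b"}


def test_dendrogram_order_invariance(rng):
    names = ["a", "b", "c", "d"]
    M = np.abs(rng.standard_normal((4, 4)))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    D = pd.DataFrame(M, index=names, columns=names)
    ref, _, _ = disagreement_dendrogram(D)
    perm = ["c", "a", "d", "b"]
    got, _, _ = disagreement_dendrogram(D.loc[perm, perm])
    # same partition up to relabeling of cluster ids
    ref_parts = {frozenset(k for k in ref if ref[k] == v) for v in set(ref.values())}
    got_parts = {frozenset(k for k in got if got[k] == v) for v in set(got.values())}
    assert ref_parts == got_parts


def test_dendrogram_errors():
    with pytest.raises(ValueError, match="symmetric"):
        disagreement_dendrogram(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match=">= 2"):
        disagreement_dendrogram(np.zeros((1, 1)))


# ------------------------------------------------------------ demographics


def test_anova_matches_raw_data(rng):
    """Summary-statistics ANOVA equals scipy's raw-data ANOVA."""
    groups = [rng.normal(loc, 2.0, n) for loc, n in ((5, 12), (6, 9), (4.5, 15))]
    f_raw, p_raw = stats.f_oneway(*groups)
    f, db, dw, p = anova_from_summaries(
        [len(g) for g in groups],
        [g.mean() for g in groups],
        [g.std(ddof=1) for g in groups],
    )
    assert f == pytest.approx(f_raw, abs=1e-10)
    assert p == pytest.approx(p_raw, abs=1e-10)
    assert (db, dw) == (2, 33)


def test_anova_identical_groups_zero():
    f, _, _, p = anova_from_summaries([10, 10], [5.0, 5.0], [1.0, 1.0])
    assert f == 0.0
    assert p == 1.0


def test_anova_validation():
    with pytest.raises(ValueError):
        anova_from_summaries([10], [1.0], [1.0])
    with pytest.raises(ValueError):
        anova_from_summaries([10, 1], [1.0, 2.0], [1.0, 1.0])


def test_chi_square_hand_formula(rng):
    for _ in range(20):
        obs = rng.integers(5, 40, size=(2, 3)).astype(float)
        chi2, dof, _ = chi_square_counts(obs)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(hand, abs=1e-10)
        assert dof == 2


def test_demographics_stats_frame():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {
            "Group": np.repeat(["AD", "FTD", "HC"], 10),
            "Age": rng.normal(65, 5, 30),
            "MMSE": rng.normal(25, 3, 30),
            "Sex": rng.choice(["female", "male"], 30),
        }
    )
    out = demographics_stats(df)
    assert list(out["variable"]) == ["Age", "MMSE", "Sex"]
    assert out["p"].between(0, 1).all()


# ----------------------------------------------------------------- LOSOCV


def test_losocv_separable_perfect(separable_dataset):
    """A separable cohort yields 1.0 for every subject-level metric."""
    ds, problem = separable_dataset
    audit = []
    rep = losocv_evaluate(ds, problem, audit=audit)
    assert all(v == 1.0 for v in rep.as_dict().values())
    # one fold per subject
    assert len(rep.table) == len(ds.subjects())
    # fold audit: no component was trained on a subject it scored
    assert audit
    for rec in audit:
        assert rec["train_subjects"].isdisjoint(rec["scored_subjects"])


# ------------------------------------------------------- property (hypothesis)

from hypothesis import given, settings, strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(0, 1), st.integers(0, 1)), min_size=4, max_size=40
    ).filter(lambda rows: len({y for _, y in rows}) == 2)
)
def test_auc_class_swap_symmetry(rows):
    """AUC(p, y) + AUC(p, 1-y) == 1 for any probability table."""
    p = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    assert roc_auc(p, y) + roc_auc(p, 1 - y) == pytest.approx(1.0, abs=1e-12)


def test_disagreement_matrix_caps_perfect_pair_ensemble():
    """A perfectly accurate averaged-probability pair with disagreeing hard
    votes gets a finite, maximal normalization instead of an error."""
    y = np.array([1, 1, 0])
    preds = {"a": np.array([1, 1, 0]), "b": np.array([1, 0, 0])}
    probs = {"a": np.array([0.9, 0.9, 0.1]), "b": np.array([0.9, 0.4, 0.1])}
    D = disagreement_matrix(preds, y, probs)
    assert np.isfinite(D.loc["a", "b"])
    assert D.loc["a", "b"] == pytest.approx(1 / (3 * (0.5 / 3)))
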