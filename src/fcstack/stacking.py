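"""Two-stage feature selection and the stacked generalization ensemble.

The ensemble combines one FgMDM base classifier per (band, metric) feature
key into a subject-level stacked model:

1. *Filter*: every key is scored by class distinctiveness — the manifold
   distance between the two class means divided by the average within-class
   dispersion — and the top 50% of keys are retained.
2. *Out-of-fold probabilities*: subjects are split into stratified folds
   (epochs follow their subject); for each fold and key an FgMDM model is
   fit on the out-of-fold subjects with inverse-epoch-count sample weights
   and scores the held-out epochs, so every epoch receives one positive-class
   probability per key from a model that never saw its subject.
3. *Aggregation*: epoch probabilities are averaged per subject.
4. *Wrapper*: greedy forward selection over keys, scored by internal
   stratified 5-fold cross-validated subject-level ROC-AUC of the
   elastic-net meta-classifier, stopping when no candidate strictly improves
   the score (at least one key is always selected).
5. *Meta*: an elastic-net-penalized logistic regression (regularization
   strength alpha=1, L1 ratio lambda=0.15, unpenalized intercept) fit on the
   subject-level probabilities of the selected keys.

Prediction averages the refit base models' epoch probabilities per subject
and maps them through the meta model; class = probability >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import spd
from .dataset import ConnectivityDataset, FeatureKey, ProblemSpec, key_name
from .evaluation import roc_auc
from .fgmdm import FgMDM

LABEL_COL = "label"
META_COLS = ("subject_id", "epoch_index", LABEL_COL)


# ------------------------------------------------------------ filter stage


def class_distinctiveness(
    Cs: np.ndarray,
    y: np.ndarray,
    metric: str,
    sample_weight: np.ndarray | None = None,
) -> float:
    """Between-class mean distance over average within-class dispersion.

    ``d(m1, m2) / (0.5 * (sigma1 + sigma2))`` where ``m_k`` is the class
    manifold mean and ``sigma_k`` the (weighted) mean distance of class-k
    samples to ``m_k``, all under ``metric``.  Defined as 0 when the class
    means coincide; raises if the dispersion vanishes while the means differ.
    """
    Cs = np.asarray(Cs, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"class distinctiveness needs exactly 2 classes, got {classes}")
    if sample_weight is None:
        sample_weight = np.ones(len(y))
    w = np.asarray(sample_weight, dtype=float)
    means = []
    sigmas = []
    for c in classes:
        mask = y == c
        if mask.sum() < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples")
        m = spd.manifold_mean(Cs[mask], w[mask], metric)
        d = spd.pairwise_distances(Cs[mask], m[None], metric)[:, 0]
        wk = w[mask] / w[mask].sum()
        means.append(m)
        sigmas.append(float(wk @ d))
    num = spd.spd_distance(means[0], means[1], metric)
    den = 0.5 * (sigmas[0] + sigmas[1])
    if den == 0:
        if num < 1e-12:
            return 0.0
        raise ZeroDivisionError(
            "zero within-class dispersion with distinct class means"
        )
    return num / den


def filter_select(scores: dict[FeatureKey, float]) -> list[FeatureKey]:
    """Retain the top ceil(n/2) keys by score; ties broken lexicographically."""
    if not scores:
        raise ValueError("empty score map")
    n_keep = int(np.ceil(len(scores) / 2))
    ordered = sorted(scores, key=lambda k: (-scores[k], k))
    return sorted(ordered[:n_keep])


# ----------------------------------------------------- out-of-fold stage


def subject_folds(
    dataset: ConnectivityDataset,
    problem: ProblemSpec,
    n_folds: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified subject-level folds (all epochs follow their subject)."""
    labels = dataset.subject_labels()
    subjects = labels.index.to_numpy()
    y_subj = (labels.to_numpy() == problem.positive).astype(int)
    for cls, cnt in zip(*np.unique(y_subj, return_counts=True)):
        if cnt < n_folds:
            raise ValueError(
                f"class {cls} has {cnt} subjects, fewer than {n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (subjects[tr], subjects[te]) for tr, te in skf.split(subjects, y_subj)
    ]


def generate_oof_probabilities(
    dataset: ConnectivityDataset,
    problem: ProblemSpec,
    keys: list[FeatureKey],
    metric: str = "log_euclidean",
    n_folds: int = 5,
    seed: int = 0,
    shrinkage: float = 0.1,
    audit: list | None = None,
) -> pd.DataFrame:
    """Epoch-level out-of-fold positive-class probabilities, one column per key.

    For each stratified subject fold and each key, an FgMDM model is fit on
    the out-of-fold subjects (inverse-epoch-count weights) and predicts the
    held-out epochs.
    """
    ds = dataset.select_problem(problem)
    y = ds.binary_y(problem)
    df = pd.DataFrame(
        {
            "subject_id": ds.subject_ids.astype(str),
            "epoch_index": ds.epoch_index,
            LABEL_COL: y,
        }
    )
    for key in keys:
        df[key_name(key)] = np.nan

    for train_subs, test_subs in subject_folds(ds, problem, n_folds, seed):
        tr = ds.select_subjects(train_subs)
        w = tr.sample_weights()
        y_tr = tr.binary_y(problem)
        test_mask = np.isin(ds.subject_ids.astype(str), test_subs)
        for key in keys:
            model = FgMDM(metric=metric, shrinkage=shrinkage)
            model.fit(tr.features[key], y_tr, sample_weight=w)
            proba = model.predict_proba(ds.features[key][test_mask])
            pos = proba[:, model.classes_ == 1][:, 0]
            df.loc[test_mask, key_name(key)] = pos
            if audit is not None:
                audit.append(
                    {
                        "component": f"oof-base[{key_name(key)}]",
                        "train_subjects": set(map(str, train_subs)),
                        "scored_subjects": set(map(str, test_subs)),
                    }
                )
    if df.drop(columns=list(META_COLS)).isna().any().any():
        raise RuntimeError("some epochs did not receive an OOF probability")
    return df


def aggregate_per_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Average epoch-level probabilities per subject (labels preserved)."""
    if "subject_id" not in table:
        raise ValueError("epoch-level table required")
    labels = table.groupby("subject_id")[LABEL_COL].nunique()
    mixed = labels[labels > 1]
    if len(mixed):
        raise ValueError(f"mixed labels within subject(s) {list(mixed.index)}")
    prob_cols = [c for c in table.columns if c not in META_COLS]
    out = table.groupby("subject_id")[prob_cols + [LABEL_COL]].mean().reset_index()
    out[LABEL_COL] = out[LABEL_COL].astype(int)
    return out


# ------------------------------------------------------------- meta stage


def _refit_intercept_exact(model, X: np.ndarray, y: np.ndarray, balanced: bool) -> None:
    """Replace the solver's intercept by its exact 1-D ML value.

    The intercept is unpenalized, so given the regularized coefficients its
    maximum-likelihood value is the root of the (weighted) mean-residual
    equation sum_i w_i (sigmoid(x_i.w + b) - y_i) = 0, a strictly monotone
    1-D problem.  Solving it exactly matters when the L1 penalty zeroes every
    coefficient: the prediction is then a constant, and any solver residue in
    the intercept would differ systematically between cross-validation folds
    of different class composition, turning pure noise into a deterministic
    (anti-)ranking when probabilities are pooled across folds.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    if balanced:
        n = len(y)
        w = np.where(y == 1, n / (2.0 * (y == 1).sum()), n / (2.0 * (y == 0).sum()))
    else:
        w = np.ones(len(y))
    z = X @ model.coef_[0]
    if np.all(z == 0.0):
        # constant model: closed-form intercept logit(weighted class prior)
        prior = float(w @ y) / float(w.sum())
        model.intercept_ = np.array([np.log(prior / (1.0 - prior))]) if 0 < prior < 1 else model.intercept_
        if balanced:
            model.intercept_ = np.array([0.0])
        return

    def grad(b):
        return float(w @ (expit(z + b) - y))
    lo, hi = -50.0, 50.0
    if grad(lo) > 0 or grad(hi) < 0:  # degenerate separation; keep solver value
        return
    model.intercept_ = np.array([brentq(grad, lo, hi, xtol=1e-12)])


@dataclass
class MetaModel:
    """Elastic-net logistic meta-classifier over base-classifier probabilities."""

    keys: list[FeatureKey]
    model: LogisticRegression
    alpha: float
    l1_ratio: float

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip([key_name(k) for k in self.keys], self.model.coef_[0]))

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = table[[key_name(k) for k in self.keys]].to_numpy()
        return self.model.predict_proba(X)[:, 1]


def fit_meta(
    table: pd.DataFrame,
    keys: list[FeatureKey],
    alpha: float = 1.0,
    l1_ratio: float = 0.15,
    seed: int = 0,
    balanced: bool = False,
) -> MetaModel:
    """Fit the elastic-net logistic regression on a subject-level table.

    Regularization follows the standard parameterization: total penalty
    strength ``alpha`` (sklearn ``C = 1/alpha``) split between L1 and L2 by
    ``l1_ratio``; the intercept is unpenalized.  Each subject is one sample.

    With ``balanced=True`` the two classes receive equal total weight
    (subjects stay uniform within their class), so the unpenalized intercept
    encodes a neutral prior instead of the training fold's class imbalance.
    Under leave-one-subject-out evaluation the fold's imbalance is the
    complement of the held-out label, so an imbalance-encoding intercept is
    anti-correlated with the truth whenever regularization shrinks the
    coefficients to zero; the full stack therefore enables this by default.
    """
    y = table[LABEL_COL].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("meta fit requires both classes")
    X = table[[key_name(k) for k in keys]].to_numpy()
    model = LogisticRegression(
        solver="saga",
        C=1.0 / alpha,
        l1_ratio=l1_ratio,
        max_iter=10000,
        tol=1e-6,
        random_state=seed,
        class_weight="balanced" if balanced else None,
    )
    model.fit(X, y)
    # snap solver residue below tolerance to an exact zero so that a fully
    # regularized-away model emits the constant 0.5, not numerical noise
    model.coef_[np.abs(model.coef_) < 1e-8] = 0.0
    _refit_intercept_exact(model, X, y, balanced)
    return MetaModel(keys=list(keys), model=model, alpha=alpha, l1_ratio=l1_ratio)


def _internal_cv_auc(
    table: pd.DataFrame,
    keys: list[FeatureKey],
    alpha: float,
    l1_ratio: float,
    n_folds: int,
    seed: int,
    balanced: bool = False,
) -> float:
    """Mean subject-level ROC-AUC over an internal stratified K-fold."""
    y = table[LABEL_COL].to_numpy()
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        aucs = []
        ok = True
        for tr, te in skf.split(table, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                ok = False
                break
            meta = fit_meta(table.iloc[tr], keys, alpha, l1_ratio, seed, balanced)
            aucs.append(roc_auc(meta.predict_proba(table.iloc[te]), y[te]))
        if ok:
            return float(np.mean(aucs))
    raise RuntimeError("could not build internal folds with both classes present")


def sequential_select(
    table: pd.DataFrame,
    keys: list[FeatureKey],
    alpha: float = 1.0,
    l1_ratio: float = 0.15,
    n_folds: int = 5,
    seed: int = 0,
    balanced: bool = False,
) -> list[FeatureKey]:
    """Greedy forward selection of base classifiers for the meta model.

    Candidates are scored by internal stratified cross-validated ROC-AUC on
    the subject-level table; selection stops when the best candidate fails
    to strictly improve the score.  At least one key (the best single one)
    is always selected.  Ties break lexicographically.
    """
    remaining = sorted(keys)
    selected: list[FeatureKey] = []
    best_score = -np.inf
    while remaining:
        score, best_k = -np.inf, None
        for k in remaining:  # sorted: ties keep the lexicographically first
            s = _internal_cv_auc(
                table, selected + [k], alpha, l1_ratio, n_folds, seed, balanced
            )
            if s > score:
                score, best_k = s, k
        if score > best_score or not selected:
            selected.append(best_k)
            remaining.remove(best_k)
            best_score = max(best_score, score)
        else:
            break
    return selected


# -------------------------------------------------------------- full stack


class StackedConnectivityClassifier(BaseEstimator):
    """Stacked ensemble of FgMDM base classifiers with subject-level output.

    Parameters
    ----------
    problem : ProblemSpec
        Binary problem (positive vs negative group).
    keys : list of (band, metric) or None
        Candidate feature keys; None uses every key in the dataset.
    metric : str
        SPD geometry of the base classifiers and the filter score.
    n_folds : int
        Folds of the internal stratified subject CV (OOF and wrapper).
    alpha, l1_ratio : float
        Elastic-net regularization strength and L1 ratio of the meta model.
    enable_filter, enable_wrapper : bool
        Ablation switches for the two feature-selection stages.
    random_state : int
        Seed for fold shuffling and the saga solver.

    Attributes (after fit)
    ----------------------
    filter_scores_ : dict, retained_keys_ : list, selected_keys_ : list,
    meta_ : MetaModel, base_models_ : dict key -> FgMDM,
    oof_subject_table_ : DataFrame, audit_ : list of component records
    (each with the subject sets that trained and were scored by it).
    """

    def __init__(
        self,
        problem: ProblemSpec | None = None,
        keys: list[FeatureKey] | None = None,
        metric: str = "log_euclidean",
        n_folds: int = 5,
        alpha: float = 1.0,
        l1_ratio: float = 0.15,
        shrinkage: float = 0.1,
        enable_filter: bool = True,
        enable_wrapper: bool = True,
        meta_balanced: bool = True,
        random_state: int = 0,
    ):
        self.problem = problem
        self.keys = keys
        self.metric = metric
        self.n_folds = n_folds
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.shrinkage = shrinkage
        self.enable_filter = enable_filter
        self.enable_wrapper = enable_wrapper
        self.meta_balanced = meta_balanced
        self.random_state = random_state

    def fit(self, dataset: ConnectivityDataset, y=None):
        if self.problem is None:
            raise ValueError("a ProblemSpec is required")
        ds = dataset.select_problem(self.problem)
        keys = sorted(self.keys) if self.keys is not None else ds.keys
        y_ep = ds.binary_y(self.problem)
        w = ds.sample_weights()
        train_subjects = set(map(str, ds.subjects()))
        self.audit_: list[dict] = []

        if self.enable_filter and len(keys) >= 2:
            self.filter_scores_ = {
                k: class_distinctiveness(ds.features[k], y_ep, self.metric, w)
                for k in keys
            }
            self.retained_keys_ = filter_select(self.filter_scores_)
        else:
            self.filter_scores_ = {}
            self.retained_keys_ = list(keys)
        self.audit_.append(
            {
                "component": "filter",
                "train_subjects": train_subjects,
                "scored_subjects": set(),
            }
        )

        oof_epoch = generate_oof_probabilities(
            ds,
            self.problem,
            self.retained_keys_,
            metric=self.metric,
            n_folds=self.n_folds,
            seed=self.random_state,
            shrinkage=self.shrinkage,
            audit=self.audit_,
        )
        self.oof_subject_table_ = aggregate_per_subject(oof_epoch)

        if self.enable_wrapper and len(self.retained_keys_) > 1:
            self.selected_keys_ = sequential_select(
                self.oof_subject_table_,
                self.retained_keys_,
                self.alpha,
                self.l1_ratio,
                self.n_folds,
                self.random_state,
                balanced=self.meta_balanced,
            )
        else:
            self.selected_keys_ = list(self.retained_keys_)
        self.audit_.append(
            {
                "component": "wrapper+meta",
                "train_subjects": train_subjects,
                "scored_subjects": set(),
            }
        )

        self.meta_ = fit_meta(
            self.oof_subject_table_,
            self.selected_keys_,
            self.alpha,
            self.l1_ratio,
            self.random_state,
            balanced=self.meta_balanced,
        )
        self.base_models_ = {}
        for key in self.selected_keys_:
            m = FgMDM(metric=self.metric, shrinkage=self.shrinkage)
            m.fit(ds.features[key], y_ep, sample_weight=w)
            self.base_models_[key] = m
            self.audit_.append(
                {
                    "component": f"final-base[{key_name(key)}]",
                    "train_subjects": train_subjects,
                    "scored_subjects": set(),
                }
            )
        return self

    def _subject_features(self, dataset: ConnectivityDataset) -> pd.DataFrame:
        """Per-subject averaged base probabilities for the selected keys."""
        check_is_fitted(self, "meta_")
        missing = [k for k in self.selected_keys_ if k not in dataset.features]
        if missing:
            raise KeyError(f"dataset lacks feature key(s) {[key_name(k) for k in missing]}")
        subs = dataset.subjects()
        rows = []
        sid = dataset.subject_ids.astype(str)
        for s in subs:
            mask = sid == s
            row = {"subject_id": s}
            for key in self.selected_keys_:
                model = self.base_models_[key]
                proba = model.predict_proba(dataset.features[key][mask])
                row[key_name(key)] = float(proba[:, model.classes_ == 1].mean())
            rows.append(row)
        return pd.DataFrame(rows)

    def predict_proba_subjects(self, dataset: ConnectivityDataset) -> pd.Series:
        """Positive-class probability per subject (index: subject id)."""
        table = self._subject_features(dataset)
        probs = self.meta_.predict_proba(table)
        return pd.Series(probs, index=table["subject_id"].to_numpy(), name="probability")

    def predict_subjects(self, dataset: ConnectivityDataset) -> pd.Series:
        """Predicted group per subject (threshold 0.5)."""
        p = self.predict_proba_subjects(dataset)
        return p.ge(0.5).map({True: self.problem.positive, False: self.problem.negative})
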