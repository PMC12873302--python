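"""Subject-level evaluation: LOSOCV, metrics, DeLong tests, diversity, stats.

All performance numbers are computed at the subject level: within each
leave-one-subject-out fold the entire stack (filter, base models, wrapper,
meta) is refit on the remaining subjects, the held-out subject receives one
positive-class probability, and the metrics are computed over all subjects'
out-of-fold probabilities with a 0.5 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


# ------------------------------------------------------------- basic metrics


def roc_auc(probabilities, labels) -> float:
    """ROC-AUC by the Mann-Whitney rank statistic (ties count 1/2)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Subject-level classification performance."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    roc_auc: float
    threshold: float = 0.5
    table: pd.DataFrame | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
        }

    def summary(self) -> str:
        """Plain-text one-liner with percentages at 2 dp."""
        d = self.as_dict()
        return "  ".join(f"{k}={100 * v:.2f}%" for k, v in d.items())


def classification_metrics(
    probabilities, labels, threshold: float = 0.5
) -> EvaluationReport:
    """Accuracy, sensitivity, specificity, F1 and ROC-AUC from probabilities.

    Predictions are ``probability >= threshold``; sensitivity is the recall
    of the positive class; F1 = 2PR/(P+R) with the convention 0 when both
    precision and recall vanish.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    auc = roc_auc(p, y)
    table = pd.DataFrame({"probability": p, "label": y, "prediction": pred})
    return EvaluationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        roc_auc=auc,
        threshold=threshold,
        table=table,
    )


# ------------------------------------------------------------------- DeLong


def delong_pvalue(probabilities, labels) -> tuple[float, float]:
    """Two-sided DeLong test of ROC-AUC against the chance value 0.5.

    Returns ``(auc, p_value)``.  The AUC variance is computed from placement
    values; if it vanishes (all probabilities identical) p = 1 is returned
    with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong test requires >= 2 samples per class")
    # placement values
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        if auc == 0.5:
            warnings.warn(
                "degenerate DeLong variance with chance-level AUC; p = 1",
                RuntimeWarning,
            )
            return auc, 1.0
        # placement-value variance vanishes at perfect separation; fall back
        # to the Mann-Whitney null variance (score test), valid under H0
        var = (m + n + 1) / (12.0 * m * n)
    z = (auc - 0.5) / np.sqrt(var)
    return auc, float(2 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------- diversity


def normalized_disagreement(
    preds_i,
    preds_j,
    labels,
    probs_i=None,
    probs_j=None,
) -> float:
    """Pairwise classifier diversity D_ij = N_disagree / (N (1 - Accuracy_ij)).

    ``Accuracy_ij`` is the accuracy of the two-classifier ensemble obtained
    by averaging probabilities and thresholding at 0.5; when only hard
    predictions are given they stand in for the probabilities.  D = 0 when
    the classifiers agree everywhere.
    """
    pi = np.asarray(preds_i).astype(int)
    pj = np.asarray(preds_j).astype(int)
    y = np.asarray(labels).astype(int)
    if not (len(pi) == len(pj) == len(y)):
        raise ValueError("prediction vectors and labels must have equal length")
    n = len(y)
    n_dis = int((pi != pj).sum())
    if n_dis == 0:
        return 0.0
    qi = pi if probs_i is None else np.asarray(probs_i, dtype=float)
    qj = pj if probs_j is None else np.asarray(probs_j, dtype=float)
    ens = ((qi + qj) / 2.0 >= 0.5).astype(int)
    acc = float((ens == y).mean())
    if acc >= 1.0:
        raise ZeroDivisionError(
            "pair-ensemble accuracy is 1 while classifiers disagree; "
            "normalized disagreement is undefined"
        )
    return n_dis / (n * (1.0 - acc))


def disagreement_matrix(
    predictions: dict[str, np.ndarray],
    labels,
    probabilities: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Symmetric normalized-disagreement matrix over a set of classifiers.

    When a pair's averaged-probability ensemble is perfectly accurate while
    its hard votes still disagree, the normalizer 1 - Accuracy vanishes; the
    matrix builder then caps the accuracy at 1 - 1/(2N) (half a sample) so
    the entry stays finite and maximal instead of aborting the analysis.
    """
    names = sorted(predictions)
    y = np.asarray(labels).astype(int)
    D = pd.DataFrame(0.0, index=names, columns=names)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            i, j = names[a], names[b]
            try:
                d = normalized_disagreement(
                    predictions[i],
                    predictions[j],
                    labels,
                    None if probabilities is None else probabilities.get(i),
                    None if probabilities is None else probabilities.get(j),
                )
            except ZeroDivisionError:
                n = len(y)
                n_dis = int((np.asarray(predictions[i]) != np.asarray(predictions[j])).sum())
                d = n_dis / (n * (0.5 / n))
            D.loc[i, j] = D.loc[j, i] = d
    return D


def disagreement_dendrogram(
    D: pd.DataFrame | np.ndarray,
    threshold_frac: float = 0.75,
    names: list[str] | None = None,
):
    """Average-linkage clustering of the disagreement matrix.

    Flat clusters are cut at ``threshold_frac * max(D)``.  Returns
    ``(cluster_labels: dict name -> int, linkage_matrix, newick: str)``.
    """
    if isinstance(D, pd.DataFrame):
        names = list(D.index)
        D = D.to_numpy()
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need >= 2 classifiers")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("disagreement matrix must be symmetric")
    if names is None:
        names = [f"clf{i}" for i in range(n)]
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    cut = threshold_frac * D.max() if D.max() > 0 else 0.0
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    clusters = dict(zip(names, flat.tolist()))
    newick = _tree_to_newick(hierarchy.to_tree(Z), names)
    return clusters, Z, newick


def _tree_to_newick(node, names: list[str]) -> str:
    def rec(nd, parent_dist):
        length = parent_dist - nd.dist
        if nd.is_leaf():
            return f"{names[nd.id]}:{length:.6g}"
        left = rec(nd.left, nd.dist)
        right = rec(nd.right, nd.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


# ----------------------------------------------------------------- LOSOCV


def losocv_evaluate(
    dataset,
    problem,
    stack_params: dict | None = None,
    threshold: float = 0.5,
    audit: list | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation of the full stacked ensemble.

    One fold per subject; the entire stack is refit on the remaining
    subjects and the held-out subject's probability recorded.  The report
    is computed over all subjects' out-of-fold probabilities.
    """
    from .stacking import StackedConnectivityClassifier  # local: avoid cycle

    ds = dataset.select_problem(problem)
    labels = ds.subject_labels()
    for s, cnt in ds.epoch_counts().items():
        if cnt == 0:
            raise ValueError(f"subject {s} has zero epochs")
    subjects = labels.index.to_numpy()
    probs = {}
    for held_out in subjects:
        train = [s for s in subjects if s != held_out]
        stack = StackedConnectivityClassifier(
            problem=problem, **(stack_params or {})
        )
        stack.fit(ds.select_subjects(train))
        probs[held_out] = float(
            stack.predict_proba_subjects(ds.select_subjects([held_out])).iloc[0]
        )
        if audit is not None:
            for rec in stack.audit_:
                audit.append({**rec, "scored_subjects": rec["scored_subjects"] | {held_out}})
    y = (labels.loc[list(probs)] == problem.positive).astype(int).to_numpy()
    p = np.array(list(probs.values()))
    report = classification_metrics(p, y, threshold)
    report.table = pd.DataFrame(
        {"subject_id": list(probs), "probability": p, "label": y}
    )
    return report


# ------------------------------------------------------------ demographics


def anova_from_summaries(ns, means, sds) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group n, mean, and SD.

    Returns ``(F, df_between, df_within, p)``.  Between and within sums of
    squares are rebuilt from the summaries, so the result equals the
    raw-data ANOVA when the summaries are exact.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k = len(ns)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    N = ns.sum()
    grand = (ns * means).sum() / N
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, int(N - k)
    if ssw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return float(f), df_b, df_w, p


def chi_square_counts(table) -> tuple[float, int, float]:
    """Chi-square test of independence (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def demographics_stats(participants: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons for a participants table (Age/MMSE ANOVA, Sex chi2)."""
    rows = []
    for col in ("Age", "MMSE"):
        g = participants.groupby("Group")[col]
        f, db, dw, p = anova_from_summaries(
            g.count().to_numpy(), g.mean().to_numpy(), g.std(ddof=1).fillna(0).to_numpy()
        )
        rows.append({"variable": col, "test": f"ANOVA F({db},{dw})", "statistic": f, "p": p})
    counts = pd.crosstab(participants["Group"], participants["Sex"])
    chi2, dof, p = chi_square_counts(counts.to_numpy())
    rows.append({"variable": "Sex", "test": f"chi2({dof})", "statistic": chi2, "p": p})
    return pd.DataFrame(rows)
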