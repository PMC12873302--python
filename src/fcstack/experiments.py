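"""Reproduction experiments: calibration and recovery studies on synthetic cohorts.

These routines define the package's reference experiments at desk scale:

- :func:`null_calibration` — repeated full-stack LOSOCV on cohorts with *no*
  group effect; a well-calibrated pipeline shows chance-level subject AUC and
  a nominal DeLong false-positive rate.
- :func:`signal_recovery` — cohorts with a strong alpha-coupling group
  difference; alpha-band base classifiers should approach perfect
  subject-level out-of-fold AUC while gamma-band classifiers stay near
  chance.
- :func:`reference_demographics_stats` — the group-comparison statistics of
  the public 88-subject clinical cohort (ds004504: 36 AD / 23 FTD / 29 HC),
  recomputed from its published summary table.

The synthetic studies run at a reduced scale (8 channels, tens of epochs per
subject) chosen so a complete calibration study is a matter of minutes on one
core; the generative structure is unchanged by the reduction.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, generate_cohort
from .dataset import ProblemSpec, extract_features
from .evaluation import (
    anova_from_summaries,
    chi_square_counts,
    delong_pvalue,
    losocv_evaluate,
    roc_auc,
)
from .stacking import aggregate_per_subject, generate_oof_probabilities

#: Published demographic summaries of the ds004504 cohort (AD, FTD, HC):
#: sex counts (female, male), and n/mean/sd for age and MMSE.
REFERENCE_SEX_COUNTS = [[24, 12], [9, 14], [11, 18]]
REFERENCE_AGE = {"n": [36, 23, 29], "mean": [66.4, 63.6, 67.9], "sd": [7.9, 8.2, 5.4]}
REFERENCE_MMSE = {"n": [36, 23, 29], "mean": [17.75, 22.17, 30.0], "sd": [4.5, 2.6, 0.0]}

NULL_BANDS = ("alpha", "theta")
NULL_METRICS = ("Cov", "Corr", "PLV")
SIGNAL_BANDS = ("alpha", "gamma")
SIGNAL_METRICS = ("Cov", "Corr")


def reference_demographics_stats() -> dict[str, float]:
    """Chi-square (sex) and one-way ANOVAs (age, MMSE) of the clinical cohort."""
    chi2, chi2_dof, chi2_p = chi_square_counts(REFERENCE_SEX_COUNTS)
    f_age, *_ = anova_from_summaries(
        REFERENCE_AGE["n"], REFERENCE_AGE["mean"], REFERENCE_AGE["sd"]
    )
    f_mmse, *_ = anova_from_summaries(
        REFERENCE_MMSE["n"], REFERENCE_MMSE["mean"], REFERENCE_MMSE["sd"]
    )
    return {
        "sex_chi2": chi2,
        "sex_chi2_dof": float(chi2_dof),
        "sex_chi2_p": chi2_p,
        "age_anova_F": f_age,
        "mmse_anova_F": f_mmse,
    }


def _cohort_spec(seed: int, coupling: tuple[float, float], n_per_group: int,
                 epochs: tuple[int, int], n_channels: int) -> CohortSpec:
    return CohortSpec(
        group_sizes={"P": n_per_group, "C": n_per_group},
        n_channels=n_channels,
        epochs_per_subject=epochs,
        alpha_coupling={"P": coupling[0], "C": coupling[1]},
        delta_power_scale={},
        seed=seed,
    )


def null_calibration(
    n_seeds: int = 20,
    n_per_group: int = 15,
    epochs: tuple[int, int] = (20, 25),
    n_channels: int = 8,
    coupling: float = 0.4,
    base_seed: int = 0,
) -> dict:
    """Full-stack LOSOCV on cohorts with no group effect.

    Both groups share the same alpha coupling, delta power, and noise level,
    so any subject-level discrimination is spurious.  Returns the per-seed
    pooled LOSOCV AUCs, DeLong p-values, their mean/counts.
    """
    aucs, pvals = [], []
    for i in range(n_seeds):
        seed = (base_seed * 1009 + i) % (2**31)
        spec = _cohort_spec(seed, (coupling, coupling), n_per_group, epochs, n_channels)
        ds = extract_features(
            generate_cohort(spec), bands=NULL_BANDS, metrics=NULL_METRICS
        )
        rep = losocv_evaluate(ds, ProblemSpec("P", "C"))
        auc, p = delong_pvalue(
            rep.table["probability"].to_numpy(), rep.table["label"].to_numpy()
        )
        aucs.append(auc)
        pvals.append(p)
    return {
        "aucs": aucs,
        "pvalues": pvals,
        "mean_auc": float(np.mean(aucs)),
        "n_significant": int(sum(p < 0.05 for p in pvals)),
        "n_seeds": n_seeds,
    }


def signal_recovery(
    n_seeds: int = 20,
    n_per_group: int = 20,
    epochs: tuple[int, int] = (30, 34),
    n_channels: int = 8,
    coupling: tuple[float, float] = (0.1, 0.7),
    n_folds: int = 5,
    base_seed: int = 0,
) -> dict:
    """Per-key subject-level out-of-fold AUC under a strong alpha effect.

    For each seed, computes stratified 5-fold OOF probabilities for the
    (alpha|gamma) x (Cov|Corr) base classifiers and scores them at the
    subject level.  A seed counts as a success when both alpha-band keys
    reach AUC >= 0.9 while every gamma-band key stays below 0.7.
    """
    keys = [(b, m) for b in SIGNAL_BANDS for m in SIGNAL_METRICS]
    per_key: dict[str, list[float]] = {f"{b}/{m}": [] for b, m in keys}
    successes = 0
    problem = ProblemSpec("C", "P")  # coupled controls are the positive class
    for i in range(n_seeds):
        seed = (base_seed * 1013 + 500 + i) % (2**31)
        spec = _cohort_spec(seed, coupling, n_per_group, epochs, n_channels)
        ds = extract_features(
            generate_cohort(spec), bands=SIGNAL_BANDS, metrics=SIGNAL_METRICS
        )
        table = aggregate_per_subject(
            generate_oof_probabilities(ds, problem, keys, n_folds=n_folds, seed=seed)
        )
        y = table["label"].to_numpy()
        aucs = {
            f"{b}/{m}": roc_auc(table[f"{b}/{m}"].to_numpy(), y) for b, m in keys
        }
        for k, v in aucs.items():
            per_key[k].append(v)
        ok_alpha = all(aucs[f"alpha/{m}"] >= 0.9 for m in SIGNAL_METRICS)
        ok_gamma = all(aucs[f"gamma/{m}"] < 0.7 for m in SIGNAL_METRICS)
        successes += ok_alpha and ok_gamma
    return {
        "per_key_aucs": per_key,
        "mean_aucs": {k: float(np.mean(v)) for k, v in per_key.items()},
        "n_success": successes,
        "n_seeds": n_seeds,
    }
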