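"""Feature extraction over cohorts and the per-epoch feature container.

A :class:`ConnectivityDataset` holds, for each (band, metric) feature key,
one SPD matrix per epoch, alongside the epoch's subject id and group label.
It is the in-memory currency of the classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BAND_ORDER, bandpass_epochs
from .cohort import Cohort
from .connectivity import (
    DEFAULT_EPS,
    METRIC_IDS,
    fc_matrix,
    freedman_diaconis_edges,
)

FeatureKey = tuple[str, str]  # (band, metric)


def key_name(key: FeatureKey) -> str:
    """Serialize a feature key as ``"band/metric"``."""
    return f"{key[0]}/{key[1]}"


def parse_key(name: str) -> FeatureKey:
    band, _, metric = name.partition("/")
    if not metric:
        raise ValueError(f"feature key {name!r} is not of the form 'band/metric'")
    return band, metric


@dataclass(frozen=True)
class ProblemSpec:
    """A binary classification problem between two diagnostic groups."""

    positive: str
    negative: str

    def __post_init__(self) -> None:
        if self.positive == self.negative:
            raise ValueError("positive and negative classes must differ")

    @property
    def name(self) -> str:
        return f"{self.positive}/{self.negative}"


#: The three problems evaluated on the clinical cohort, former class positive.
DEFAULT_PROBLEMS = (
    ProblemSpec("AD", "HC"),
    ProblemSpec("FTD", "HC"),
    ProblemSpec("FTD", "AD"),
)


@dataclass
class ConnectivityDataset:
    """Per-epoch SPD feature matrices with subject and group annotations.

    Attributes
    ----------
    features : dict
        (band, metric) -> array of shape (n_epochs, n_channels, n_channels).
    subject_ids : ndarray of str, shape (n_epochs,)
    groups : ndarray of str, shape (n_epochs,)
        Group label of each epoch (constant within a subject).
    epoch_index : ndarray of int, shape (n_epochs,)
        Epoch index within its subject.
    """

    features: dict[FeatureKey, np.ndarray]
    subject_ids: np.ndarray
    groups: np.ndarray
    epoch_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.epoch_index is None:
            idx = np.zeros(n, dtype=int)
            for s in np.unique(self.subject_ids.astype(str)):
                m = self.subject_ids == s
                idx[m] = np.arange(m.sum())
            self.epoch_index = idx
        for key, arr in self.features.items():
            if arr.shape[0] != n:
                raise ValueError(
                    f"feature {key_name(key)} has {arr.shape[0]} epochs, "
                    f"expected {n}"
                )
        for s in np.unique(self.subject_ids.astype(str)):
            g = np.unique(self.groups[self.subject_ids == s].astype(str))
            if len(g) != 1:
                raise ValueError(f"subject {s} carries mixed group labels {g}")

    @property
    def n_epochs(self) -> int:
        return len(self.subject_ids)

    @property
    def keys(self) -> list[FeatureKey]:
        return sorted(self.features)

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids.astype(str))

    def subject_labels(self) -> pd.Series:
        """Group label per subject (index: subject id)."""
        df = pd.DataFrame(
            {"subject": self.subject_ids.astype(str), "group": self.groups.astype(str)}
        )
        return df.groupby("subject")["group"].first()

    def epoch_counts(self) -> pd.Series:
        return pd.Series(self.subject_ids.astype(str)).value_counts().sort_index()

    def sample_weights(self) -> np.ndarray:
        """Inverse epoch-count weight per epoch, so every subject counts equally."""
        counts = self.epoch_counts()
        return 1.0 / counts[self.subject_ids.astype(str)].to_numpy()

    def select_subjects(self, subjects) -> "ConnectivityDataset":
        subjects = set(map(str, subjects))
        mask = np.array([str(s) in subjects for s in self.subject_ids])
        return self._mask(mask)

    def select_problem(self, problem: ProblemSpec) -> "ConnectivityDataset":
        """Restrict to the two groups of a binary problem."""
        mask = np.array(
            [g in (problem.positive, problem.negative) for g in self.groups.astype(str)]
        )
        if not mask.any():
            raise ValueError(f"no epochs for problem {problem.name}")
        return self._mask(mask)

    def _mask(self, mask: np.ndarray) -> "ConnectivityDataset":
        return ConnectivityDataset(
            features={k: v[mask] for k, v in self.features.items()},
            subject_ids=self.subject_ids[mask],
            groups=self.groups[mask],
            epoch_index=self.epoch_index[mask],
        )

    def binary_y(self, problem: ProblemSpec) -> np.ndarray:
        """Per-epoch 0/1 labels (1 = positive class)."""
        return (self.groups.astype(str) == problem.positive).astype(int)


def extract_features(
    cohort: Cohort,
    bands: tuple[str, ...] = BAND_ORDER,
    metrics: tuple[str, ...] = METRIC_IDS,
    fs: float | None = None,
    eps: float = DEFAULT_EPS,
) -> ConnectivityDataset:
    """Compute the (band x metric) SPD matrices for every epoch of a cohort.

    Band filtering is shared across the metrics of a band, and for the
    information metrics the Freedman-Diaconis bin edges are computed once per
    subject from that subject's pooled band-limited samples per channel and
    reused for all of the subject's epochs.
    """
    if fs is None:
        fs = cohort.spec.fs if cohort.spec is not None else 500.0
    features: dict[FeatureKey, list[np.ndarray]] = {
        (b, m): [] for b in bands for m in metrics
    }
    subject_ids: list[str] = []
    groups: list[str] = []
    epoch_index: list[int] = []

    info_metrics = {"MI", "ECC"} & set(metrics)
    for sub in cohort.subjects:
        n_ep = sub.n_epochs
        if n_ep == 0:
            raise ValueError(f"subject {sub.subject_id} has no epochs")
        subject_ids.extend([sub.subject_id] * n_ep)
        groups.extend([sub.group] * n_ep)
        epoch_index.extend(range(n_ep))
        for band in bands:
            filt = bandpass_epochs(sub.epochs, fs, band)
            bin_edges = None
            if info_metrics:
                pooled = filt.transpose(1, 0, 2).reshape(filt.shape[1], -1)
                bin_edges = [
                    freedman_diaconis_edges(pooled[ch])
                    for ch in range(pooled.shape[0])
                ]
            for metric in metrics:
                mats = [
                    fc_matrix(
                        ep, metric, fs=fs, band=band, bin_edges=bin_edges, eps=eps
                    )
                    for ep in filt
                ]
                features[(band, metric)].extend(mats)

    return ConnectivityDataset(
        features={k: np.stack(v) for k, v in features.items()},
        subject_ids=np.array(subject_ids, dtype=object),
        groups=np.array(groups, dtype=object),
        epoch_index=np.array(epoch_index),
    )
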