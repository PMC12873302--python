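"""Persistent containers: HDF5 epoch store, participants TSV, configs, models.

The epoch container is a hierarchical HDF5 file::

    /subjects/<id>/epochs   float64 (n_epochs, n_channels, n_samples)
    /subjects/<id>.attrs    group, age, sex, mmse
    /.attrs                 fs, channel_names, spec_json, spec_hash

Arrays round-trip bit-exactly (float64).  The participants table is a
BIDS-participants-style TSV.  Configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortSpec, SubjectRecord
from .dataset import ConnectivityDataset, key_name, parse_key


def spec_hash(spec: CohortSpec) -> str:
    """Stable SHA-256 of the generator spec (provenance tag)."""
    payload = json.dumps(spec.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_channel_names(n: int) -> list[str]:
    """Standard 10-20 names for 19 channels, generic names otherwise."""
    ten_twenty = [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
        "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
    ]
    if n == 19:
        return ten_twenty
    return [f"ch{i:02d}" for i in range(n)]


# --------------------------------------------------------- epoch container


def write_cohort(path, cohort: Cohort, fs: float | None = None) -> None:
    if fs is None:
        fs = cohort.spec.fs if cohort.spec is not None else 500.0
    with h5py.File(path, "w") as h5:
        h5.attrs["fs"] = float(fs)
        h5.attrs["container_version"] = 1
        if cohort.subjects:
            n_ch = cohort.subjects[0].epochs.shape[1]
            h5.attrs["channel_names"] = default_channel_names(n_ch)
        if cohort.spec is not None:
            h5.attrs["spec_json"] = json.dumps(cohort.spec.to_dict(), default=str)
            h5.attrs["spec_hash"] = spec_hash(cohort.spec)
        grp = h5.create_group("subjects")
        for sub in cohort.subjects:
            g = grp.create_group(sub.subject_id)
            g.create_dataset("epochs", data=np.asarray(sub.epochs, dtype=np.float64))
            g.attrs["group"] = sub.group
            g.attrs["age"] = sub.age
            g.attrs["sex"] = sub.sex
            g.attrs["mmse"] = sub.mmse


def read_cohort(path) -> tuple[Cohort, float]:
    """Read an epoch container; returns ``(cohort, fs)``.

    Subjects with inconsistent channel or sample counts are rejected with
    their ids listed.
    """
    with h5py.File(path, "r") as h5:
        fs = float(h5.attrs["fs"])
        subjects = []
        shapes: dict[str, tuple] = {}
        for sid in sorted(h5["subjects"]):
            g = h5["subjects"][sid]
            ep = g["epochs"][()]
            if ep.ndim != 3 or ep.shape[0] < 1:
                raise ValueError(f"subject {sid!r}: invalid epochs shape {ep.shape}")
            shapes[sid] = ep.shape[1:]
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=str(g.attrs["group"]),
                    age=float(g.attrs.get("age", np.nan)),
                    sex=str(g.attrs.get("sex", "")),
                    mmse=float(g.attrs.get("mmse", np.nan)),
                    epochs=ep,
                )
            )
        if len(set(shapes.values())) > 1:
            ref = subjects[0].epochs.shape[1:]
            bad = [s for s, sh in shapes.items() if sh != ref]
            raise ValueError(
                f"inconsistent channel/sample counts across subjects: {bad}"
            )
        spec = None
        if "spec_json" in h5.attrs:
            d = json.loads(h5.attrs["spec_json"])
            d["epochs_per_subject"] = tuple(d["epochs_per_subject"])
            spec = CohortSpec(**d)
    return Cohort(subjects=subjects, spec=spec), fs


# --------------------------------------------------------- participants TSV


def write_participants(path, cohort: Cohort) -> None:
    cohort.participants_frame().to_csv(path, sep="\t", index=False)


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ feature store


def write_features(path, dataset: ConnectivityDataset) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["container_version"] = 1
        h5.create_dataset(
            "subject_ids", data=np.array(dataset.subject_ids, dtype="S64")
        )
        h5.create_dataset("groups", data=np.array(dataset.groups, dtype="S16"))
        h5.create_dataset("epoch_index", data=dataset.epoch_index)
        feats = h5.create_group("features")
        for key, arr in dataset.features.items():
            feats.create_dataset(key_name(key), data=arr)


def read_features(path) -> ConnectivityDataset:
    with h5py.File(path, "r") as h5:
        subject_ids = h5["subject_ids"][()].astype(str)
        groups = h5["groups"][()].astype(str)
        epoch_index = h5["epoch_index"][()]
        # "band/metric" names create nested HDF5 groups; walk both levels
        features = {
            (band, metric): h5["features"][band][metric][()]
            for band in h5["features"]
            for metric in h5["features"][band]
        }
    return ConnectivityDataset(
        features=features,
        subject_ids=np.array(subject_ids, dtype=object),
        groups=np.array(groups, dtype=object),
        epoch_index=epoch_index,
    )


# ------------------------------------------------------------------ config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def cohort_spec_from_config(cfg: dict, seed: int | None = None) -> CohortSpec:
    c = dict(cfg.get("cohort", {}))
    if "epochs_per_subject" in c:
        c["epochs_per_subject"] = tuple(c["epochs_per_subject"])
    if seed is not None:
        c["seed"] = seed
    return CohortSpec(**c)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ------------------------------------------------------------ model store


def save_stack(path, stack) -> None:
    """Serialize a fitted stacked classifier (matrices + JSON metadata)."""
    meta = {
        "problem": [stack.problem.positive, stack.problem.negative],
        "metric": stack.metric,
        "alpha": stack.alpha,
        "l1_ratio": stack.l1_ratio,
        "selected_keys": [key_name(k) for k in stack.selected_keys_],
        "meta_intercept": stack.meta_.intercept,
        "meta_coefficients": stack.meta_.coefficients,
        "filter_scores": {key_name(k): v for k, v in stack.filter_scores_.items()},
    }
    with h5py.File(path, "w") as h5:
        h5.attrs["meta_json"] = json.dumps(meta)
        for key in stack.selected_keys_:
            m = stack.base_models_[key]
            g = h5.create_group(f"base/{key_name(key)}")
            g.create_dataset("reference", data=m.reference_)
            g.create_dataset("filter_basis", data=m.filter_basis_)
            g.create_dataset("class_means", data=m.class_means_)
            g.attrs["classes"] = m.classes_.astype(int)


def load_stack(path):
    """Load a serialized stack into a ready-to-predict classifier."""
    from sklearn.linear_model import LogisticRegression

    from .dataset import ProblemSpec
    from .fgmdm import FgMDM
    from .stacking import MetaModel, StackedConnectivityClassifier

    with h5py.File(path, "r") as h5:
        meta = json.loads(h5.attrs["meta_json"])
        stack = StackedConnectivityClassifier(
            problem=ProblemSpec(*meta["problem"]),
            metric=meta["metric"],
            alpha=meta["alpha"],
            l1_ratio=meta["l1_ratio"],
        )
        stack.filter_scores_ = {
            parse_key(k): v for k, v in meta["filter_scores"].items()
        }
        stack.selected_keys_ = [parse_key(k) for k in meta["selected_keys"]]
        stack.retained_keys_ = list(stack.selected_keys_)
        stack.base_models_ = {}
        for key in stack.selected_keys_:
            g = h5[f"base/{key_name(key)}"]
            m = FgMDM(metric=meta["metric"])
            m.reference_ = g["reference"][()]
            m.filter_basis_ = g["filter_basis"][()]
            m.class_means_ = g["class_means"][()]
            m.classes_ = np.asarray(g.attrs["classes"])
            stack.base_models_[key] = m
        lr = LogisticRegression()
        lr.classes_ = np.array([0, 1])
        lr.coef_ = np.array(
            [[meta["meta_coefficients"][key_name(k)] for k in stack.selected_keys_]]
        )
        lr.intercept_ = np.array([meta["meta_intercept"]])
        stack.meta_ = MetaModel(
            keys=stack.selected_keys_,
            model=lr,
            alpha=meta["alpha"],
            l1_ratio=meta["l1_ratio"],
        )
        stack.audit_ = []
    return stack


# --------------------------------------------------------------- EDF import


def import_bids_edf(
    paths_and_groups: list[tuple[str, str]],
    epoch_len_s: float = 5.0,
    channels: list[str] | None = None,
) -> Cohort:
    """Convert BIDS-organized EDF resting-state recordings into a cohort.

    ``paths_and_groups`` pairs each EDF path with its group label.  Channels
    are picked by 10-20 names (defaults to the standard 19), the continuous
    signal is cut into non-overlapping epochs of ``epoch_len_s`` seconds,
    and each file becomes one subject.  Requires the optional ``mne``
    dependency.
    """
    import mne  # optional dependency

    records = []
    for path, group in paths_and_groups:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        records.append(raw_to_record(raw, Path(path).stem, group, epoch_len_s, channels))
    return Cohort(subjects=records, spec=None)


def raw_to_record(
    raw,
    subject_id: str,
    group: str,
    epoch_len_s: float = 5.0,
    channels: list[str] | None = None,
) -> SubjectRecord:
    """Cut an mne Raw object into epochs and wrap it as a SubjectRecord."""
    picks = channels or default_channel_names(19)
    present = [ch for ch in picks if ch in raw.ch_names]
    if not present:
        raise ValueError(f"{subject_id}: none of the requested channels found")
    data = raw.get_data(picks=present)
    fs = float(raw.info["sfreq"])
    n_samp = int(round(fs * epoch_len_s))
    n_ep = data.shape[1] // n_samp
    if n_ep < 1:
        raise ValueError(f"{subject_id}: recording shorter than one epoch")
    epochs = data[:, : n_ep * n_samp].reshape(len(present), n_ep, n_samp)
    epochs = np.transpose(epochs, (1, 0, 2))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=np.nan,
        sex="",
        mmse=np.nan,
        epochs=epochs,
    )
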