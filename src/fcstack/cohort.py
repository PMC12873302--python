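"""Synthetic resting-state EEG cohorts with group-dependent connectivity.

The generator emulates the statistical structure the downstream analysis
assumes it is measuring, without claiming physiological realism: each epoch
is a sum of five band-limited Gaussian sources (white noise filtered into the
delta/theta/alpha/beta/gamma bands and normalized to unit per-channel
variance) mixed across channels, plus independent white sensor noise.

Group structure enters through two dials:

- ``alpha_coupling[group]``: the alpha-band source of every channel is a
  convex mixture ``sqrt(c) * shared + sqrt(1-c) * independent``, so the
  expected off-diagonal alpha-band channel correlation is approximately ``c``.
  The implied channel covariance ``(1-c) I + c 11^T`` is positive definite for
  ``c in [0, 1)``.
- ``delta_power_scale[group]``: multiplies the delta-source variance,
  emulating the slow-wave power increase reported in dementia.

Epochs are independent draws except for one per-subject log-normal gain,
which gives every subject an amplitude signature and makes subject-grouped
cross-validation meaningfully different from epoch-shuffled cross-validation.

Demographics (age, sex, MMSE) are drawn from group-wise normal / Bernoulli
distributions whose defaults match the clinical cohort the pipeline targets
(AD / FTD / HC, 36 / 23 / 29 subjects).

Everything is reproducible: a subject's record is a pure function of
``(spec.seed, group, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, band_sos
from scipy import signal as _signal

GROUPS = ("AD", "FTD", "HC")

DEFAULT_GROUP_SIZES = {"AD": 36, "FTD": 23, "HC": 29}

#: Group-wise demographic distributions: age (mean, sd), MMSE (mean, sd,
#: truncated to [0, 30]), probability of female sex.
DEFAULT_DEMOGRAPHICS = {
    "AD": {"age": (66.4, 7.9), "mmse": (17.75, 4.5), "p_female": 24 / 36},
    "FTD": {"age": (63.6, 8.2), "mmse": (22.17, 2.6), "p_female": 9 / 23},
    "HC": {"age": (67.9, 5.4), "mmse": (30.0, 0.0), "p_female": 11 / 29},
}
_GENERIC_DEMOGRAPHICS = {"age": (65.0, 8.0), "mmse": (27.0, 3.0), "p_female": 0.5}


@dataclass
class CohortSpec:
    """Parameters of a synthetic EEG cohort.

    Attributes
    ----------
    group_sizes : dict
        Mapping group name -> number of subjects (each >= 2).
    n_channels : int
        Electrode count (default 19, the standard 10-20 montage size).
    fs : float
        Sampling rate in Hz (default 500).
    epoch_len_s : float
        Epoch length in seconds (default 5); ``fs * epoch_len_s`` must be an
        integer number of samples.
    epochs_per_subject : (int, int)
        Inclusive range; each subject's epoch count is drawn uniformly from
        it.  The default (60, 250) mirrors 5-s epochs cut from 5-21 minute
        resting-state recordings.
    alpha_coupling : dict
        Group -> shared-source mixing weight in [0, 1) for the alpha band.
    delta_power_scale : dict
        Group -> multiplier (>= 0) on delta-source variance.
    noise_sd : float
        Standard deviation of the white sensor noise.
    subject_gain_sd : float
        Sigma of the per-subject log-normal amplitude gain.
    seed : int
        Root seed; all randomness derives from it.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_channels: int = 19
    fs: float = 500.0
    epoch_len_s: float = 5.0
    epochs_per_subject: tuple[int, int] = (60, 250)
    alpha_coupling: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.2, "FTD": 0.3, "HC": 0.5}
    )
    delta_power_scale: dict[str, float] = field(
        default_factory=lambda: {"AD": 1.5, "FTD": 1.0, "HC": 1.0}
    )
    noise_sd: float = 0.5
    subject_gain_sd: float = 0.2
    seed: int = 0
    demographics: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()}
    )

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must declare at least one group")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects, got {n}")
        n_samp = self.fs * self.epoch_len_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError(
                f"fs * epoch_len_s = {n_samp} is not an integer sample count"
            )
        lo, hi = self.epochs_per_subject
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid epochs_per_subject range {self.epochs_per_subject}")
        for g in self.group_sizes:
            c = self.coupling_for(g)
            if not 0.0 <= c < 1.0:
                raise ValueError(
                    f"alpha_coupling[{g!r}]={c} does not yield a positive-definite "
                    "mixing model (need 0 <= c < 1)"
                )
            if self.delta_scale_for(g) < 0:
                raise ValueError(f"delta_power_scale[{g!r}] must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len_s))

    def coupling_for(self, group: str) -> float:
        return float(self.alpha_coupling.get(group, 0.0))

    def delta_scale_for(self, group: str) -> float:
        return float(self.delta_power_scale.get(group, 1.0))

    def demographics_for(self, group: str) -> dict:
        return self.demographics.get(group, _GENERIC_DEMOGRAPHICS)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    """One subject: epochs plus label and demographics."""

    subject_id: str
    group: str
    age: float
    sex: str
    mmse: float
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class Cohort:
    """A set of subject records with the spec that generated them."""

    subjects: list[SubjectRecord]
    spec: CohortSpec | None = None

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_epochs(self) -> int:
        return sum(s.n_epochs for s in self.subjects)

    def participants_frame(self) -> pd.DataFrame:
        """BIDS-participants-style demographics table."""
        return pd.DataFrame(
            {
                "participant_id": [s.subject_id for s in self.subjects],
                "Group": [s.group for s in self.subjects],
                "Age": [s.age for s in self.subjects],
                "Sex": [s.sex for s in self.subjects],
                "MMSE": [s.mmse for s in self.subjects],
            }
        )


def _band_noise(rng: np.random.Generator, sos, shape) -> np.ndarray:
    """White noise filtered into a band, normalized to unit variance."""
    x = rng.standard_normal(shape)
    y = _signal.sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _subject_rng(seed: int, group: str, subject_index: int) -> np.random.Generator:
    # stable integer encoding of the group name keeps the stream independent
    # of iteration order
    gkey = int.from_bytes(group.encode("utf8"), "big") % (2**31)
    ss = np.random.SeedSequence([int(seed), gkey, int(subject_index)])
    return np.random.default_rng(ss)


def generate_subject(
    spec: CohortSpec, group: str, subject_index: int
) -> SubjectRecord:
    """Generate one subject's epochs and demographics.

    Fully reproducible from ``(spec.seed, group, subject_index)``.
    """
    if group not in spec.group_sizes:
        raise ValueError(f"group {group!r} is not declared in the spec")
    rng = _subject_rng(spec.seed, group, subject_index)
    n_ch, n_samp, fs = spec.n_channels, spec.n_samples, spec.fs
    lo, hi = spec.epochs_per_subject
    n_epochs = int(rng.integers(lo, hi + 1))
    gain = float(np.exp(rng.normal(0.0, spec.subject_gain_sd)))

    coupling = spec.coupling_for(group)
    delta_scale = spec.delta_scale_for(group)

    sig = np.zeros((n_epochs, n_ch, n_samp))
    for name, band in DEFAULT_BANDS.items():
        sos = band_sos(band, fs)
        indep = _band_noise(rng, sos, (n_epochs, n_ch, n_samp))
        if name == "alpha" and coupling > 0:
            shared = _band_noise(rng, sos, (n_epochs, 1, n_samp))
            comp = np.sqrt(coupling) * shared + np.sqrt(1.0 - coupling) * indep
        else:
            comp = indep
        if name == "delta":
            comp = comp * np.sqrt(delta_scale)
        sig += comp
    sig += spec.noise_sd * rng.standard_normal(sig.shape)
    sig *= gain

    demo = spec.demographics_for(group)
    age = float(rng.normal(*demo["age"]))
    mmse_mean, mmse_sd = demo["mmse"]
    mmse = float(np.clip(rng.normal(mmse_mean, mmse_sd), 0.0, 30.0))
    sex = "female" if rng.random() < demo["p_female"] else "male"

    return SubjectRecord(
        subject_id=f"sub-{group}{subject_index:03d}",
        group=group,
        age=round(age, 1),
        sex=sex,
        mmse=round(mmse, 2),
        epochs=sig,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate every subject declared in ``spec.group_sizes``.

    Identical spec (including seed) yields a bit-identical cohort.
    """
    subjects: list[SubjectRecord] = []
    seen: set[str] = set()
    for group in sorted(spec.group_sizes):
        for idx in range(spec.group_sizes[group]):
            rec = generate_subject(spec, group, idx)
            if rec.subject_id in seen:
                raise ValueError(f"duplicate subject id {rec.subject_id!r}")
            seen.add(rec.subject_id)
            subjects.append(rec)
    return Cohort(subjects=subjects, spec=spec)
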