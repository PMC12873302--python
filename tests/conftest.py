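"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import fcstack as fc
from fcstack.dataset import ProblemSpec


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random SPD matrix."""
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T / n + np.eye(n))


def random_spd_stack(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    return np.stack([random_spd(rng, n) for _ in range(k)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_cohort(
    seed: int,
    n_per_group: int = 6,
    n_channels: int = 8,
    epochs=(4, 6),
    coupling=(0.05, 0.8),
    groups=("P", "C"),
) -> fc.Cohort:
    """Small two-group cohort; ``coupling`` gives (patients, controls)."""
    spec = fc.CohortSpec(
        group_sizes={groups[0]: n_per_group, groups[1]: n_per_group},
        n_channels=n_channels,
        epochs_per_subject=tuple(epochs),
        alpha_coupling={groups[0]: coupling[0], groups[1]: coupling[1]},
        delta_power_scale={},
        seed=seed,
    )
    return fc.generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_dataset() -> tuple[fc.ConnectivityDataset, ProblemSpec]:
    """Strong alpha-coupling difference: classes separable at subject level."""
    cohort = make_cohort(seed=42, n_per_group=7, epochs=(5, 7))
    ds = fc.extract_features(cohort, bands=("alpha", "theta"), metrics=("Cov", "Corr"))
    return ds, ProblemSpec("C", "P")
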