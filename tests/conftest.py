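"""Shared fixtures: stable parameter sets, small grids and a tiny cohort."""

import numpy as np
import pytest

from eispec.cohort import CohortConfig, generate_cohort
from eispec.forward import FrequencyGrid, NMMParameters, is_stable


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def stable_params() -> NMMParameters:
    """A parameter set verified to be linearly stable (damped oscillatory)."""
    p = NMMParameters.from_ms(12.0, 15.0, 1.2, 1.5)
    assert is_stable(p)
    return p


def draw_stable_params(rng: np.random.Generator, margin: float = 0.0) -> NMMParameters:
    """Rejection-sample a stable parameter set from the fitting bounds box.

    ``margin`` requires every eigenvalue's real part below ``-margin`` (1/s),
    which excludes near-critical sets whose resonances are extremely narrow.
    """
    from eispec.forward import state_matrices

    for _ in range(10_000):
        p = NMMParameters.from_ms(
            rng.uniform(5, 30),
            rng.uniform(5, 30),
            rng.uniform(0.1, 10),
            rng.uniform(0.1, 10),
        )
        A, _ = state_matrices(p)
        if np.max(np.linalg.eigvals(A).real) < -margin:
            return p
    raise RuntimeError("failed to draw a stable parameter set")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort reused by stats/mediation/pipeline tests."""
    cfg = CohortConfig(
        n_controls=6,
        n_patients=6,
        roi_list=tuple(f"roi{i:02d}" for i in range(12)),
        seed=11,
    )
    return generate_cohort(cfg)
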