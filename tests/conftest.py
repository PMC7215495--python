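import numpy as np
import pytest

from tailorrec.data_model import RatingMatrix
from tailorrec.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed small cohort reused across modules (no truth oracle)."""
    spec = CohortSpec(n_per_group=(12, 14), n_messages=40, seed=7)
    return generate_cohort(spec, include_truth=False)


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size cohort at the generator defaults."""
    return generate_cohort(CohortSpec(seed=3), include_truth=False)


def planted_matrix(
    n_users=30,
    n_items=40,
    rank=2,
    noise=0.0,
    obs_frac=0.8,
    seed=1,
    factor_sd=0.5,
    offset=3.0,
):
    """Low-rank Likert-range matrix with a held-out cell set.

    Returns (matrix, holdout) where holdout is a list of
    (user, item, true_value) cells absent from the matrix.
    """
    rng = np.random.default_rng(seed)
    U = rng.normal(0, factor_sd, (n_users, rank))
    V = rng.normal(0, factor_sd, (n_items, rank))
    R = np.clip(offset + U @ V.T + rng.normal(0, noise, (n_users, n_items)), 1, 5)
    users = [f"u{i:03d}" for i in range(n_users)]
    items = [f"i{j:03d}" for j in range(n_items)]
    mask = rng.random((n_users, n_items)) < obs_frac
    mat = RatingMatrix(users, items)
    holdout = []
    for i in range(n_users):
        for j in range(n_items):
            if mask[i, j]:
                mat.set(users[i], items[j], R[i, j])
            else:
                holdout.append((users[i], items[j], R[i, j]))
    return mat, holdout
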