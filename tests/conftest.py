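"""Shared fixtures: a planted-structure recovery dataset and its fitted model.

The recovery fixture is the suite's workhorse: two views of four ROIs
carrying 2 and 3 subject clusters, separation 1.5, nu = 200, N = 120.
It is generated once per session and reused wherever a fitted model or
a prepared (whitened + regularized) dataset is needed.
"""

import numpy as np
import pytest

from fcmvc.fc_data import regularize_dataset
from fcmvc.multiview import ModelHyperparams, greedy_fit
from fcmvc.synthetic import SyntheticSpec, generate_dataset
from fcmvc.whitening import apply_whitening, fit_whitening

RECOVERY_SEED = 3
FIT_SEED = 7


@pytest.fixture(scope="session")
def recovery_spec():
    return SyntheticSpec(
        n_subjects=120,
        roi_sizes_per_view=(4, 4),
        clusters_per_view=(2, 3),
        separation=1.5,
        dof=200.0,
        seed=RECOVERY_SEED,
    )


@pytest.fixture(scope="session")
def recovery_data(recovery_spec):
    return generate_dataset(recovery_spec)


@pytest.fixture(scope="session")
def discovery_transform(recovery_data):
    dataset, _ = recovery_data
    return fit_whitening(dataset, reference_label="discovery")


@pytest.fixture(scope="session")
def prepared_recovery(recovery_data, discovery_transform):
    dataset, _ = recovery_data
    return regularize_dataset(apply_whitening(discovery_transform, dataset), 0.05)


@pytest.fixture(scope="session")
def recovery_hyper():
    return ModelHyperparams(dof=200.0)


@pytest.fixture(scope="session")
def recovery_model(prepared_recovery, recovery_hyper):
    return greedy_fit(prepared_recovery, recovery_hyper, seed=FIT_SEED)


@pytest.fixture(scope="session")
def truth_view_map(recovery_model, recovery_data):
    """Fitted view id -> planted view id, by majority ROI membership."""
    _, truth = recovery_data
    model = recovery_model
    return {
        v: int(np.bincount(truth.view_of_roi[model.partition.rois_of_view(v)]).argmax())
        for v in range(model.partition.n_views)
    }
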