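"""Whitening pre-processing for correlation matrices.

The clustering model assumes independence between subnetworks.  Real FC
matrices violate this, so before fitting, every subject matrix is
transformed by the symmetric inverse square root W = Rbar^{-1/2} of a
*reference* sample mean correlation matrix Rbar.  W is the unique
symmetric linear map that turns the reference mean into the identity;
applied to each subject it suppresses shared (between-subnetwork)
correlation on average while preserving subject-specific structure
within subnetworks.  After the transform, each matrix is rescaled to
unit diagonal so that it remains a correlation matrix.

The reference can be the dataset itself ("self-whitening") or another
dataset (e.g. whitening validation data with the discovery mean); the
two paths are distinguished by ``reference_label``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc_data import FCDataset


@dataclass(frozen=True)
class WhiteningTransform:
    reference_mean: np.ndarray
    operator: np.ndarray
    reference_label: str
    jitter: float

    def __post_init__(self) -> None:
        Rbar, W = self.reference_mean, self.operator
        if np.abs(W @ Rbar @ W - np.eye(len(W))).max() > 1e-8:
            raise ValueError("operator does not satisfy W Rbar W = I")


def fit_whitening(
    dataset: FCDataset, jitter: float = 1e-6, reference_label: str = "self"
) -> WhiteningTransform:
    """Fit W = Rbar^{-1/2} from the entrywise mean of all subject matrices.

    ``jitter`` is added to the eigenvalues of Rbar before inversion to
    guard against a numerically singular mean.
    """
    if dataset.n_subjects < 2:
        raise ValueError("whitening reference needs at least two subjects")
    Rbar = dataset.stack().mean(axis=0)
    lam, U = np.linalg.eigh(Rbar)
    if lam.max() <= jitter:
        raise ValueError(
            "reference mean is singular beyond jitter repair; "
            "regularize the correlation matrices first"
        )
    # Floor (rather than shift) the eigenvalues: a well-conditioned mean
    # is inverted exactly; only degenerate directions are repaired.
    lam = np.maximum(lam, jitter)
    Rbar_repaired = (U * lam) @ U.T
    W = (U * (1.0 / np.sqrt(lam))) @ U.T
    return WhiteningTransform(Rbar_repaired, W, reference_label, jitter)


def apply_whitening(transform: WhiteningTransform, dataset: FCDataset) -> FCDataset:
    """Map every R_i to the correlation normalization of W R_i W."""
    W = transform.operator
    if W.shape[0] != dataset.p:
        raise ValueError(
            f"transform is {W.shape[0]}x{W.shape[0]} but dataset has p={dataset.p}"
        )
    stacked = dataset.stack()
    out = np.einsum("ab,ibc,cd->iad", W, stacked, W)
    d = np.sqrt(np.einsum("ijj->ij", out))
    out = out / (d[:, :, None] * d[:, None, :])
    out = 0.5 * (out + np.swapaxes(out, 1, 2))
    diag_idx = np.arange(dataset.p)
    out[:, diag_idx, diag_idx] = 1.0
    return dataset.with_matrices(
        out, provenance=f"whitened:{transform.reference_label}"
    )


def whiten_dataset(
    dataset: FCDataset,
    reference: FCDataset | None = None,
    jitter: float = 1e-6,
    reference_label: str | None = None,
) -> tuple[FCDataset, WhiteningTransform]:
    """Whiten ``dataset`` against itself or against a reference dataset."""
    if reference is None:
        label = reference_label or "self"
        t = fit_whitening(dataset, jitter=jitter, reference_label=label)
    else:
        label = reference_label or "reference"
        t = fit_whitening(reference, jitter=jitter, reference_label=label)
    return apply_whitening(t, dataset), t
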