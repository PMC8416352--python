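"""Synthetic FC datasets with planted multi-view Wishart structure.

The generator emulates the shape of a multi-site resting-state FC study:
N subjects, p ROIs split exclusively into views, and within each view a
cluster-specific scale (correlation) matrix from which each subject's
scatter submatrix is drawn as Wishart(nu, Sigma_{v,k}).  Views are
independent by construction (block-diagonal population scatter in a
randomized ROI order), which is exactly the assumption the clustering
model makes and the whitening step is meant to restore on real data.
Optional confounds re-introduce what real data have and the model does
not want: a rank-one cross-view coupling of strength c and a per-site
linear distortion of the correlation matrices.

Cluster separation is controlled by one scalar delta: each cluster's
scale is the correlation normalization of B_k B_k' + I with a d x 2
loading matrix B_k whose entries have standard deviation delta.
delta = 0 plants no structure at all (every scale is the identity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import wishart

from .fc_data import (
    CorrelationMatrix,
    DataValidationError,
    FCDataset,
    RoiSet,
    SubjectRecord,
)

_DIAG_POOL = ("HC", "MDD", "BD", "SCZ", "ASD", "DY")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for one synthetic dataset.

    Defaults give the desk-scale regime used throughout the test suite:
    two views of four ROIs carrying 2 and 3 subject clusters, moderate
    separation delta = 1.5, nu = 200 pseudo-volumes, no confounds.
    """

    n_subjects: int = 120
    roi_sizes_per_view: tuple[int, ...] = (4, 4)
    clusters_per_view: tuple[int, ...] = (2, 3)
    mixing_per_view: tuple[tuple[float, ...], ...] | None = None
    separation: float = 1.5
    dof: float = 200.0
    coupling_strength: float = 0.0
    sites: tuple[str, ...] = ("S1",)
    site_effects: Mapping[str, np.ndarray] | None = None
    diagnosis_link_view: int | None = None
    diagnosis_link_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.clusters_per_view):
            raise ValueError("clusters_per_view entries must be >= 1")
        if len(self.roi_sizes_per_view) != len(self.clusters_per_view):
            raise ValueError("one cluster count per view is required")
        if not 0.0 <= self.coupling_strength < 1.0:
            raise ValueError("coupling_strength must lie in [0, 1)")
        if self.mixing_per_view is not None:
            for v, mix in enumerate(self.mixing_per_view):
                if len(mix) != self.clusters_per_view[v]:
                    raise ValueError(f"view {v}: mixing length != cluster count")
                if abs(sum(mix) - 1.0) > 1e-9:
                    raise ValueError(f"view {v}: mixing probabilities must sum to 1")

    @property
    def p(self) -> int:
        return int(sum(self.roi_sizes_per_view))

    @property
    def n_views(self) -> int:
        return len(self.roi_sizes_per_view)

    def to_json(self) -> str:
        d = {
            k: getattr(self, k)
            for k in (
                "n_subjects",
                "roi_sizes_per_view",
                "clusters_per_view",
                "mixing_per_view",
                "separation",
                "dof",
                "coupling_strength",
                "sites",
                "diagnosis_link_view",
                "diagnosis_link_strength",
                "seed",
            )
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        for key in ("roi_sizes_per_view", "clusters_per_view", "sites"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("mixing_per_view") is not None:
            d["mixing_per_view"] = tuple(tuple(m) for m in d["mixing_per_view"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Planted latent structure of a synthetic dataset.

    ``view_of_roi`` is indexed in the *dataset's* (randomized) ROI order,
    so recovery scores can be computed directly against fitted partitions.
    """

    view_of_roi: np.ndarray
    cluster_of_subject: tuple[np.ndarray, ...]
    scale_matrices: tuple[tuple[np.ndarray, ...], ...]
    roi_permutation: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "view_of_roi": self.view_of_roi.tolist(),
                "cluster_of_subject": [c.tolist() for c in self.cluster_of_subject],
                "roi_permutation": self.roi_permutation.tolist(),
                "scale_matrices": [
                    [m.tolist() for m in view] for view in self.scale_matrices
                ],
            },
            sort_keys=True,
        )


def _correlation_normalize(matrix: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(matrix))
    out = matrix / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def sample_cluster_scales(
    view_size: int,
    n_clusters: int,
    separation: float,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """Draw K cluster-specific scale matrices for one view.

    Each is the correlation normalization of B_k B_k' + I, with B_k a
    d x 2 matrix of N(0, separation^2) loadings resampled per cluster.
    separation = 0 returns K identity matrices.
    """
    if view_size < 1 or n_clusters < 1:
        raise ValueError("view_size and n_clusters must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scales = []
    for _ in range(n_clusters):
        B = separation * rng.standard_normal((view_size, 2))
        scales.append(_correlation_normalize(B @ B.T + np.eye(view_size)))
    return scales


def _draw_diagnoses(
    spec: SyntheticSpec,
    clusters: Sequence[np.ndarray],
    rng: np.random.Generator,
    n: int | None = None,
) -> list[str]:
    """Diagnoses either uniform or tied to the clusters of one planted view."""
    n = spec.n_subjects if n is None else n
    if spec.diagnosis_link_view is None:
        return [str(rng.choice(_DIAG_POOL[:4])) for _ in range(n)]
    z = clusters[spec.diagnosis_link_view]
    k_link = spec.clusters_per_view[spec.diagnosis_link_view]
    out = []
    for i in range(n):
        if rng.random() < spec.diagnosis_link_strength:
            out.append(_DIAG_POOL[int(z[i]) % len(_DIAG_POOL)])
        else:
            out.append(str(rng.choice(_DIAG_POOL[: max(2, k_link)])))
    return out


def generate_dataset(spec: SyntheticSpec) -> tuple[FCDataset, GroundTruth]:
    """Generate one dataset with planted multi-view Wishart structure.

    Per subject, a latent cluster is drawn per view from the mixing
    probabilities; the view's scatter is Wishart(nu, Sigma_{v,z});
    the full scatter is assembled block-diagonally, shuffled by a single
    dataset-wide ROI permutation (so recovery cannot exploit contiguity),
    and normalized to correlation form.
    """
    max_d = max(spec.roi_sizes_per_view)
    if spec.dof <= max_d - 1:
        raise ValueError(
            f"dof={spec.dof} must exceed the largest view size - 1 = {max_d - 1}"
        )
    rng = np.random.default_rng(spec.seed)
    p, n = spec.p, spec.n_subjects

    scale_matrices = tuple(
        tuple(
            sample_cluster_scales(
                spec.roi_sizes_per_view[v], spec.clusters_per_view[v],
                spec.separation, rng,
            )
        )
        for v in range(spec.n_views)
    )
    mixing = spec.mixing_per_view or tuple(
        tuple(np.full(k, 1.0 / k)) for k in spec.clusters_per_view
    )
    clusters = tuple(
        rng.choice(spec.clusters_per_view[v], size=n, p=mixing[v])
        for v in range(spec.n_views)
    )

    # One permutation maps the block-grouped ROI order to the dataset order.
    perm = rng.permutation(p)  # dataset position j holds grouped ROI perm[j]
    view_of_grouped = np.repeat(
        np.arange(spec.n_views), spec.roi_sizes_per_view
    )
    view_of_roi = view_of_grouped[perm]
    offsets = np.concatenate([[0], np.cumsum(spec.roi_sizes_per_view)])

    matrices = []
    for i in range(n):
        full = np.zeros((p, p))
        for v in range(spec.n_views):
            sigma = scale_matrices[v][int(clusters[v][i])]
            block = wishart.rvs(df=spec.dof, scale=sigma, random_state=rng)
            block = np.atleast_2d(block)
            full[offsets[v]:offsets[v + 1], offsets[v]:offsets[v + 1]] = block
        full = full[np.ix_(perm, perm)]
        matrices.append(
            CorrelationMatrix(f"sub{i:04d}", _correlation_normalize(full))
        )

    diagnoses = _draw_diagnoses(spec, clusters, rng)
    records = tuple(
        SubjectRecord(
            subject_id=f"sub{i:04d}",
            diagnosis=diagnoses[i],
            age=float(np.clip(rng.normal(35.0, 13.0), 18.0, 80.0)),
            sex="M" if rng.random() < 0.5 else "F",
            site=spec.sites[i % len(spec.sites)],
        )
        for i in range(n)
    )
    roi_set = RoiSet(tuple(f"ROI{j:03d}" for j in range(p)))
    dataset = FCDataset(
        roi_set, tuple(matrices), records, dof=spec.dof, provenance="synthetic"
    )
    truth = GroundTruth(view_of_roi, clusters, scale_matrices, perm)
    if spec.coupling_strength > 0 or spec.site_effects is not None:
        dataset = inject_confounds(
            dataset, truth, spec.coupling_strength, spec.site_effects
        )
    return dataset, truth


def sample_subjects_from_truth(
    spec: SyntheticSpec,
    truth: GroundTruth,
    n_subjects: int,
    seed: int,
    prefix: str = "new",
) -> tuple[FCDataset, tuple[np.ndarray, ...]]:
    """Draw fresh subjects from an existing planted structure.

    Uses the same scale matrices, mixing proportions and ROI permutation
    as ``truth``; returns the new dataset and its per-view cluster labels.
    Intended for out-of-sample classification experiments.
    """
    rng = np.random.default_rng(seed)
    p = spec.p
    mixing = spec.mixing_per_view or tuple(
        tuple(np.full(k, 1.0 / k)) for k in spec.clusters_per_view
    )
    clusters = tuple(
        rng.choice(spec.clusters_per_view[v], size=n_subjects, p=mixing[v])
        for v in range(spec.n_views)
    )
    offsets = np.concatenate([[0], np.cumsum(spec.roi_sizes_per_view)])
    perm = truth.roi_permutation
    matrices = []
    for i in range(n_subjects):
        full = np.zeros((p, p))
        for v in range(spec.n_views):
            sigma = truth.scale_matrices[v][int(clusters[v][i])]
            block = np.atleast_2d(
                wishart.rvs(df=spec.dof, scale=sigma, random_state=rng)
            )
            full[offsets[v]:offsets[v + 1], offsets[v]:offsets[v + 1]] = block
        full = full[np.ix_(perm, perm)]
        matrices.append(
            CorrelationMatrix(f"{prefix}{i:04d}", _correlation_normalize(full))
        )
    diagnoses = _draw_diagnoses(spec, clusters, rng, n_subjects)
    records = tuple(
        SubjectRecord(
            subject_id=f"{prefix}{i:04d}",
            diagnosis=diagnoses[i],
            age=float(np.clip(rng.normal(35.0, 13.0), 18.0, 80.0)),
            sex="M" if rng.random() < 0.5 else "F",
            site=spec.sites[i % len(spec.sites)],
        )
        for i in range(n_subjects)
    )
    roi_set = RoiSet(tuple(f"ROI{j:03d}" for j in range(p)))
    dataset = FCDataset(
        roi_set, tuple(matrices), records, dof=spec.dof, provenance="synthetic"
    )
    return dataset, clusters


def inject_confounds(
    dataset: FCDataset,
    truth: GroundTruth,
    coupling_strength: float = 0.0,
    site_effect: Mapping[str, np.ndarray] | None = None,
) -> FCDataset:
    """Add cross-view coupling and/or a site distortion to every matrix.

    Each correlation matrix R becomes the correlation normalization of
    A_s M_c R M_c' A_s', where M_c = I + c u u' (u the uniform unit
    vector) injects rank-one mixing across all views and A_s is the
    subject's site transform.  c = 0 with identity transforms is the
    identity map; a purely scalar site transform cancels in the
    correlation normalization.
    """
    if not 0.0 <= coupling_strength < 1.0:
        raise ValueError("coupling_strength must lie in [0, 1)")
    p = dataset.p
    u = np.ones(p) / np.sqrt(p)
    M = np.eye(p) + coupling_strength * np.outer(u, u)
    transforms = {}
    if site_effect:
        for site, A in site_effect.items():
            A = np.asarray(A, dtype=float)
            if A.shape != (p, p):
                raise ValueError(f"site {site}: transform must be {p}x{p}")
            if np.linalg.cond(A) > 1e8:
                raise ValueError(f"site {site}: transform is singular or near-singular")
            transforms[site] = A
    stacked = dataset.stack()
    out = np.empty_like(stacked)
    for i, rec in enumerate(dataset.metadata):
        A = transforms.get(rec.site, np.eye(p))
        X = A @ M @ stacked[i] @ M.T @ A.T
        out[i] = _correlation_normalize(X)
    return dataset.with_matrices(out, provenance=f"{dataset.provenance}+confounded")


def mean_abs_off_block(matrix: np.ndarray, view_of_roi: np.ndarray) -> float:
    """Mean |entry| over ROI pairs whose ROIs lie in different views."""
    off = view_of_roi[:, None] != view_of_roi[None, :]
    return float(np.abs(matrix[off]).mean()) if off.any() else 0.0


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())
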