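"""Out-of-sample assignment of subjects to the clusters of one view.

A new subject's whitened, regularized correlation matrix is restricted
to the chosen view's ROIs, scaled to a scatter S = nu * R[v, v], and
scored against every existing cluster by the CRP-predictive rule

    score_k   = log m_k + [marginal(stats_k + S) - marginal(stats_k)]
    score_NEW = log alpha_cluster + marginal({S})

The sentinel ``NEW`` is the nonparametric "open a new cluster" outcome;
a subject wins it when its connectivity pattern on the view fits none
of the training clusters better than a fresh draw from the prior.

Also provided: the traveling-subject agreement permutation test, which
asks whether per-subject cluster labels reproduce across two scan sites
better than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc_data import CorrelationMatrix, FCDataset, regularize_dataset
from .multiview import (
    ModelHyperparams,
    MultiViewModel,
    WishartClusterStats,
    cluster_log_marginal,
)
from .whitening import WhiteningTransform, apply_whitening, fit_whitening

NEW = "NEW"


@dataclass(frozen=True)
class ClassificationResult:
    subject_id: str
    assigned: int | str
    log_scores: dict


@dataclass(frozen=True)
class TravelingSubjectSet:
    """Cluster labels per subject for repeated scans at two sites."""

    labels_site_a: np.ndarray  # (n_subjects, n_scans)
    labels_site_b: np.ndarray
    sites: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        a, b = np.asarray(self.labels_site_a), np.asarray(self.labels_site_b)
        if a.shape != b.shape or a.ndim != 2:
            raise ValueError("both sites need equal (n_subjects, n_scans) label arrays")


def _merged_stats(
    stats: WishartClusterStats, S: np.ndarray
) -> WishartClusterStats:
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("subject scatter is not positive definite")
    return WishartClusterStats(
        member_count=stats.member_count + 1,
        scatter_sum=stats.scatter_sum + S,
        logdet_sum=stats.logdet_sum + float(logdet),
    )


def classify_subject(
    model: MultiViewModel, view_id: int, C: CorrelationMatrix
) -> ClassificationResult:
    """Assign one whitened+regularized subject matrix to a cluster or NEW."""
    if view_id < 0 or view_id >= model.partition.n_views:
        raise ValueError(f"view {view_id} not in model (has {model.partition.n_views})")
    idx = model.partition.rois_of_view(view_id)
    d = len(idx)
    hyper = model.hyper
    S = hyper.dof * C.values[np.ix_(idx, idx)]
    empty = WishartClusterStats(0, np.zeros((d, d)), 0.0)
    log_scores: dict = {}
    for k, stats in enumerate(model.stats[view_id]):
        delta = cluster_log_marginal(
            _merged_stats(stats, S), d, hyper
        ) - cluster_log_marginal(stats, d, hyper)
        log_scores[k] = float(np.log(stats.member_count) + delta)
    log_scores[NEW] = float(
        np.log(hyper.alpha_cluster)
        + cluster_log_marginal(_merged_stats(empty, S), d, hyper)
    )
    # deterministic tie-break: existing clusters in id order beat NEW
    best = max(log_scores.values())
    assigned: int | str = NEW
    for k in list(range(len(model.stats[view_id]))) + [NEW]:
        if log_scores[k] >= best - 1e-12:
            assigned = k
            break
    return ClassificationResult(C.subject_id, assigned, log_scores)


def classify_dataset(
    model: MultiViewModel,
    view_id: int,
    dataset: FCDataset,
    whitening: WhiteningTransform | str = "self",
    epsilon: float = 0.05,
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify every subject of a raw dataset into one view's clusters.

    ``whitening`` is either the string ``"self"`` (fit the whitening
    reference on this dataset — the validation dataset's own mean) or a
    fitted WhiteningTransform from the discovery data.  Regularization
    with ``epsilon`` is applied after whitening, before scoring.

    Returns per-subject results and a cluster x diagnosis count summary
    whose rows are the model's clusters plus a NEW row.
    """
    n_clusters = len(model.stats[view_id])
    diagnoses = sorted(set(dataset.diagnoses)) if dataset.n_subjects else []
    if dataset.n_subjects == 0:
        summary = pd.DataFrame(
            0, index=[*range(1, n_clusters + 1), NEW], columns=diagnoses
        )
        return [], summary
    if isinstance(whitening, str):
        if whitening != "self":
            raise ValueError("whitening must be 'self' or a WhiteningTransform")
        transform = fit_whitening(dataset, reference_label="self")
    else:
        transform = whitening
    prepared = regularize_dataset(apply_whitening(transform, dataset), epsilon)
    results = [
        classify_subject(model, view_id, m) for m in prepared.matrices
    ]
    rows = [*range(1, n_clusters + 1), NEW]
    summary = pd.DataFrame(0, index=rows, columns=diagnoses)
    for res, rec in zip(results, dataset.metadata):
        row = NEW if res.assigned == NEW else int(res.assigned) + 1
        summary.loc[row, rec.diagnosis] += 1
    return results, summary


def ts_agreement_test(
    ts: TravelingSubjectSet,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean cross-site label agreement and its permutation p-value.

    Per subject, agreement is the number of scan indices whose cluster
    labels coincide between the two sites (0..n_scans).  The statistic
    is the mean over subjects.  The null pairs each site-A subject with
    a random site-B subject (subject-level shuffling, preserving the
    within-subject scan dependence); p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    a = np.asarray(ts.labels_site_a)
    b = np.asarray(ts.labels_site_b)
    n_subjects = a.shape[0]
    observed = float((a == b).sum(axis=1).mean())
    rng = np.random.default_rng(seed)
    perms = np.array(
        [rng.permutation(n_subjects) for _ in range(n_perm)]
    )  # (n_perm, n_subjects)
    stats = (a[None, :, :] == b[perms]).sum(axis=2).mean(axis=1)
    p = float((1 + (stats >= observed - 1e-12).sum()) / (n_perm + 1))
    return observed, p
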