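"""Comparison methods: FC-based multiple clustering and supervised pairwise classification.

The FC-based baseline vectorizes each correlation matrix into its
p(p-1)/2 upper-triangular entries (optionally Fisher z-transformed) and
runs the same CRP partition-search engine as the ROI-based model, but
with features partitioned into views and per-view diagonal-covariance
Gaussian clusters under a conjugate normal-inverse-gamma prior.

The supervised baseline builds, for every ordered pair of diagnoses, a
class-balanced elastic-net classifier evaluated by leave-one-out
cross-validation, then aggregates the pairwise probabilities p_i(j, k)
into marginal per-diagnosis probabilities and assigns the argmax label.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.linear_model import LogisticRegression

from ._engine import Backend, ClusterState, GreedySearch, ViewData
from .fc_data import FCDataset


@dataclass(frozen=True)
class FeatureVectorTable:
    values: np.ndarray  # (n_subjects, q)
    pairs: tuple[tuple[int, int], ...]  # feature index -> (roi_i, roi_j)
    subject_ids: tuple[str, ...]
    fisher_z: bool

    @property
    def q(self) -> int:
        return self.values.shape[1]


def vectorize_fc(dataset: FCDataset, fisher_z: bool = True) -> FeatureVectorTable:
    """Upper-triangular FC entries in row-major ROI order, one row per subject."""
    p = dataset.p
    rows, cols = np.triu_indices(p, k=1)
    stacked = dataset.stack()
    values = stacked[:, rows, cols]
    if fisher_z:
        values = np.arctanh(np.clip(values, -1 + 1e-6, 1 - 1e-6))
    pairs = tuple(zip(rows.tolist(), cols.tolist()))
    return FeatureVectorTable(values, pairs, dataset.subject_ids, fisher_z)


def devectorize(table: FeatureVectorTable, p: int) -> np.ndarray:
    """Rebuild (N, p, p) unit-diagonal matrices from a non-z table."""
    if table.fisher_z:
        raise ValueError("round-trip requires fisher_z=False")
    n = table.values.shape[0]
    out = np.zeros((n, p, p))
    rows = np.array([a for a, _ in table.pairs])
    cols = np.array([b for _, b in table.pairs])
    out[:, rows, cols] = table.values
    out = out + np.swapaxes(out, 1, 2)
    idx = np.arange(p)
    out[:, idx, idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# Gaussian multi-view baseline


@dataclass(frozen=True)
class GaussianHyperparams:
    """Normal-inverse-gamma prior per feature: mean mu0 with precision
    scale kappa0, variance IG(a0, b0).  Defaults suit roughly unit-scale,
    centered features (Fisher-z correlations)."""

    alpha_view: float = 1.0
    alpha_cluster: float = 1.0
    mu0: float = 0.0
    kappa0: float = 0.01
    a0: float = 1.0
    b0: float = 0.1


@dataclass
class GaussianViewModel:
    hyper: GaussianHyperparams
    view_of_feature: np.ndarray
    labels_per_view: tuple[np.ndarray, ...]
    score: float
    score_trace: tuple[float, ...] = ()


class _GaussView(ViewData):
    def __init__(self, backend: "GaussianBackend", items: tuple[int, ...]):
        self.items = items
        self.X = backend.X[:, list(items)]  # (N, d)
        self.X2 = self.X**2
        self.h = backend.hyper

    def new_cluster(self) -> "_GaussCluster":
        return _GaussCluster(self)

    def marginal_from_stats(self, n: int, s1: np.ndarray, s2: np.ndarray) -> float:
        if n == 0:
            return 0.0
        h = self.h
        kn = h.kappa0 + n
        an = h.a0 + 0.5 * n
        xbar = s1 / n
        ss = np.maximum(s2 - s1**2 / n, 0.0)
        bn = h.b0 + 0.5 * ss + 0.5 * h.kappa0 * n * (xbar - h.mu0) ** 2 / kn
        per_feature = (
            gammaln(an)
            - gammaln(h.a0)
            + h.a0 * np.log(h.b0)
            - an * np.log(bn)
            + 0.5 * (np.log(h.kappa0) - np.log(kn))
            - 0.5 * n * np.log(2 * np.pi)
        )
        return float(per_feature.sum())

    def frozen_marginal_sum(self, labels: np.ndarray) -> float:
        total = 0.0
        for lab in np.unique(labels):
            mask = labels == lab
            total += self.marginal_from_stats(
                int(mask.sum()), self.X[mask].sum(axis=0), self.X2[mask].sum(axis=0)
            )
        return total


class _GaussCluster(ClusterState):
    def __init__(self, view: _GaussView):
        self.view = view
        self.m = 0
        self.s1 = np.zeros(view.X.shape[1])
        self.s2 = np.zeros(view.X.shape[1])

    def add(self, i: int) -> None:
        self.s1 += self.view.X[i]
        self.s2 += self.view.X2[i]
        self.m += 1

    def remove(self, i: int) -> None:
        self.s1 -= self.view.X[i]
        self.s2 -= self.view.X2[i]
        self.m -= 1

    def log_marginal(self) -> float:
        return self.view.marginal_from_stats(self.m, self.s1, self.s2)

    def predictive_delta(self, i: int) -> float:
        with_i = self.view.marginal_from_stats(
            self.m + 1, self.s1 + self.view.X[i], self.s2 + self.view.X2[i]
        )
        return with_i - self.log_marginal()


class GaussianBackend(Backend):
    def __init__(self, features: FeatureVectorTable, hyper: GaussianHyperparams):
        self.X = features.values
        self.n_subjects, self.n_items = self.X.shape
        self.hyper = hyper
        self.max_view_dim = None

    def make_view(self, items: tuple[int, ...]) -> _GaussView:
        return _GaussView(self, items)


def fit_fc_multiview_gmm(
    features: FeatureVectorTable,
    hyper: GaussianHyperparams | None = None,
    n_init: int = 10,
    max_sweeps: int = 50,
    seed: int = 0,
) -> GaussianViewModel:
    """Best-of-``n_init`` greedy fits of the FC-based Gaussian baseline."""
    if features.q < 2:
        raise ValueError("need at least two features")
    hyper = hyper or GaussianHyperparams()
    backend = GaussianBackend(features, hyper)
    from .multiview import derive_seeds

    best: GaussianViewModel | None = None
    for s in derive_seeds(seed, n_init):
        search = GreedySearch(
            backend,
            alpha_view=hyper.alpha_view,
            alpha_cluster=hyper.alpha_cluster,
            max_sweeps=max_sweeps,
            seed=s,
        ).fit()
        item_of, labels = search.partitions()
        model = GaussianViewModel(
            hyper=hyper,
            view_of_feature=item_of,
            labels_per_view=tuple(labels[v] for v in range(len(labels))),
            score=search.score(),
            score_trace=tuple(search.score_trace),
        )
        if best is None or model.score > best.score:
            best = model
    return best


def gaussian_score_from_scratch(
    features: FeatureVectorTable, model: GaussianViewModel
) -> float:
    """Recompute a GaussianViewModel's score from raw features."""
    from ._engine import crp_log_prior

    backend = GaussianBackend(features, model.hyper)
    sizes = np.unique(model.view_of_feature, return_counts=True)[1]
    s = crp_log_prior(sizes, model.hyper.alpha_view, backend.n_items)
    for v in range(len(sizes)):
        items = tuple(np.where(model.view_of_feature == v)[0])
        labels = model.labels_per_view[v]
        view = backend.make_view(items)
        csizes = np.unique(labels, return_counts=True)[1]
        s += crp_log_prior(csizes, model.hyper.alpha_cluster, backend.n_subjects)
        s += view.frozen_marginal_sum(labels)
    return float(s)


# ---------------------------------------------------------------------------
# supervised pairwise classification


@dataclass(frozen=True)
class PairwiseProbabilityTable:
    """p[i, (j, k)] = probability subject i belongs to diagnosis j in the
    j-vs-k model; antisymmetric: p(j, k) = 1 - p(k, j)."""

    probabilities: pd.DataFrame  # index: subject ids, columns: (j, k) tuples
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cols = set(self.probabilities.columns)
        for j, k in combinations(self.labels, 2):
            if (j, k) not in cols or (k, j) not in cols:
                raise ValueError(f"missing probability column for pair ({j}, {k})")
            resid = (
                self.probabilities[(j, k)] + self.probabilities[(k, j)] - 1.0
            ).abs()
            if resid.max() > 1e-12:
                raise ValueError(
                    f"antisymmetry violated for pair ({j}, {k}): "
                    f"max |p(j,k)+p(k,j)-1| = {resid.max():.3g}"
                )


def pairwise_marginal_classify(
    probs: PairwiseProbabilityTable,
) -> pd.DataFrame:
    """Average p_i(j, k) over k != j and assign the argmax diagnosis.

    Returns a frame with one marginal-probability column per diagnosis
    plus an ``assigned`` column; ties go to the lexicographically first
    label.
    """
    labels = sorted(probs.labels)
    marg = pd.DataFrame(index=probs.probabilities.index)
    for j in labels:
        others = [k for k in probs.labels if k != j]
        marg[j] = probs.probabilities[[(j, k) for k in others]].mean(axis=1)
    assigned = marg[labels].idxmax(axis=1)
    out = marg.copy()
    out["assigned"] = assigned
    return out


def pairwise_probability_table(
    features: FeatureVectorTable,
    diagnoses,
    l1_ratio: float = 0.5,
    C: float = 1.0,
    seed: int = 0,
) -> PairwiseProbabilityTable:
    """Balanced LOOCV elastic-net probabilities for every diagnosis pair.

    For each unordered pair (j, k): subsample the larger class down to
    the smaller one; estimate in-sample probabilities by leave-one-out
    cross-validation; refit on the full balanced set to score everyone
    else.  The inner classifier is L1+L2-penalized logistic regression.
    """
    y = np.asarray(list(diagnoses))
    labels = tuple(sorted(set(y.tolist())))
    rng = np.random.default_rng(seed)
    X = features.values
    index = list(features.subject_ids)
    cols: dict[tuple[str, str], np.ndarray] = {}

    def make_clf():
        return LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=C, max_iter=5000, tol=1e-4,
        )

    for j, k in combinations(labels, 2):
        idx_j = np.where(y == j)[0]
        idx_k = np.where(y == k)[0]
        n_bal = min(len(idx_j), len(idx_k))
        if n_bal < 2:
            raise ValueError(f"pair ({j}, {k}): need >= 2 subjects per class")
        sub_j = rng.choice(idx_j, n_bal, replace=False)
        sub_k = rng.choice(idx_k, n_bal, replace=False)
        bal = np.concatenate([sub_j, sub_k])
        Xb, yb = X[bal], (y[bal] == j).astype(int)
        p_j = np.empty(len(y))
        # leave-one-out for balanced members
        for pos, i in enumerate(bal):
            mask = np.ones(len(bal), dtype=bool)
            mask[pos] = False
            clf = make_clf().fit(Xb[mask], yb[mask])
            p_j[i] = clf.predict_proba(X[i][None, :])[0, clf.classes_.tolist().index(1)]
        clf = make_clf().fit(Xb, yb)
        rest = np.setdiff1d(np.arange(len(y)), bal)
        if rest.size:
            p_j[rest] = clf.predict_proba(X[rest])[:, clf.classes_.tolist().index(1)]
        cols[(j, k)] = p_j
        cols[(k, j)] = 1.0 - p_j
    frame = pd.DataFrame(cols, index=index)
    return PairwiseProbabilityTable(frame, labels)
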