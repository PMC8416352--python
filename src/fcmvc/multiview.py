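"""ROI-based multi-view Wishart mixture clustering.

Model.  ROIs are partitioned into views by a CRP prior (concentration
``alpha_view``); within each view v of dimension d_v, subjects are
partitioned into clusters by a second CRP (``alpha_cluster``), and a
subject's scatter submatrix S_i^(v) = nu * R_i[v, v] on the view's ROIs
is Wishart(nu, Sigma_{v,k}) given its cluster k.  The cluster scale
Sigma_{v,k} carries a conjugate inverse-Wishart prior IW(nu_0, Psi_0)
with nu_0 = d_v + nu0_offset and Psi_0 = psi0_scale * (nu_0 - d_v - 1) I,
so the prior mean scale is psi0_scale * I — the natural choice for
whitened correlation matrices.  Integrating Sigma out gives the
closed-form cluster marginal likelihood

    log p(S_1..S_m) = ((nu - d - 1)/2) sum_i log|S_i| - m log Gamma_d(nu/2)
                      + (nu_0/2) log|Psi_0| + log Gamma_d(nu_m/2)
                      - log Gamma_d(nu_0/2) - (nu_m/2) log|Psi_m|,

with nu_m = nu_0 + m nu and Psi_m = Psi_0 + sum_i S_i.

Partition scoring.  The joint model evaluates the *full* p x p scatter
under a Wishart with block-diagonal scale, which factorizes into
per-view conjugate integrals times a per-subject base measure
(|S_i|, Gamma_p and 2-power factors) that does not depend on the
partition.  Scores used to compare partitions therefore drop the
per-observation factors of the standalone marginal above and keep

    M0(v, k) = (nu_0/2) log|Psi_0| - log Gamma_d(nu_0/2)
               + log Gamma_d(nu_m/2) - (nu_m/2) log|Psi_m|
               + (m nu d / 2) log 2,

whose sum over views equals the full joint up to a constant.  Summing
the standalone marginals instead would silently reward discarding
off-block statistics and drive the search to single-ROI views no
matter the data.  Within a fixed view the two forms give identical
subject-reassignment decisions.

Inference is a greedy MAP search over both partitions (see ``_engine``)
restarted from many random initializations; the final model is chosen
by the stability heuristic: among the top-scoring models, find the pair
whose ROI view partitions agree most by ARI and keep the higher-scoring
member of that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np
from scipy.special import gammaln, multigammaln

from ._engine import Backend, ClusterState, GreedySearch, ViewData, crp_log_prior
from .fc_data import FCDataset, RoiSet

__all__ = [
    "ModelHyperparams",
    "ViewPartition",
    "ClusterAssignment",
    "WishartClusterStats",
    "MultiViewModel",
    "ModelSelectionReport",
    "crp_log_prior",
    "cluster_log_marginal",
    "model_log_posterior",
    "greedy_fit",
    "fit_multistart",
    "adjusted_rand_index",
    "select_model",
    "score_from_scratch",
]


@dataclass(frozen=True)
class ModelHyperparams:
    """Hyperparameters of the multi-view Wishart mixture.

    dof is the Wishart degrees of freedom of the observed scatters
    (number of fMRI volumes minus one for real data); nu0_offset and
    psi0_scale define the per-view inverse-Wishart prior as documented
    in the module docstring.
    """

    dof: float
    alpha_view: float = 1.0
    alpha_cluster: float = 1.0
    nu0_offset: float = 2.0
    psi0_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_view <= 0 or self.alpha_cluster <= 0:
            raise ValueError("CRP concentrations must be positive")
        if self.nu0_offset <= 1:
            raise ValueError("nu0_offset must exceed 1 so that Psi_0 is PD")

    def nu0(self, d: int) -> float:
        return d + self.nu0_offset

    def psi0_diag(self, d: int) -> float:
        return self.psi0_scale * (self.nu0(d) - d - 1.0)


@dataclass(frozen=True)
class ViewPartition:
    view_of_roi: np.ndarray

    @property
    def n_views(self) -> int:
        return int(np.max(self.view_of_roi)) + 1

    def rois_of_view(self, v: int) -> np.ndarray:
        return np.where(np.asarray(self.view_of_roi) == v)[0]

    def sizes(self) -> list[int]:
        return [len(self.rois_of_view(v)) for v in range(self.n_views)]


@dataclass(frozen=True)
class ClusterAssignment:
    labels_per_view: tuple[np.ndarray, ...]

    def labels(self, v: int) -> np.ndarray:
        return self.labels_per_view[v]

    def sizes(self, v: int) -> list[int]:
        _, counts = np.unique(self.labels_per_view[v], return_counts=True)
        return counts.tolist()


@dataclass
class WishartClusterStats:
    member_count: int
    scatter_sum: np.ndarray
    logdet_sum: float


@dataclass
class MultiViewModel:
    hyper: ModelHyperparams
    partition: ViewPartition
    clusters: ClusterAssignment
    stats: tuple[tuple[WishartClusterStats, ...], ...]  # [view][cluster]
    score: float
    roi_set: RoiSet | None = None
    score_trace: tuple[float, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "hyper": {
                    "dof": self.hyper.dof,
                    "alpha_view": self.hyper.alpha_view,
                    "alpha_cluster": self.hyper.alpha_cluster,
                    "nu0_offset": self.hyper.nu0_offset,
                    "psi0_scale": self.hyper.psi0_scale,
                },
                "view_of_roi": np.asarray(self.partition.view_of_roi).tolist(),
                "labels_per_view": [
                    np.asarray(l).tolist() for l in self.clusters.labels_per_view
                ],
                "stats": [
                    [
                        {
                            "member_count": s.member_count,
                            "scatter_sum": s.scatter_sum.tolist(),
                            "logdet_sum": s.logdet_sum,
                        }
                        for s in view
                    ]
                    for view in self.stats
                ],
                "score": self.score,
                "roi_labels": list(self.roi_set.labels) if self.roi_set else None,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MultiViewModel":
        d = json.loads(text)
        hyper = ModelHyperparams(**d["hyper"])
        stats = tuple(
            tuple(
                WishartClusterStats(
                    member_count=s["member_count"],
                    scatter_sum=np.asarray(s["scatter_sum"]),
                    logdet_sum=s["logdet_sum"],
                )
                for s in view
            )
            for view in d["stats"]
        )
        return cls(
            hyper=hyper,
            partition=ViewPartition(np.asarray(d["view_of_roi"], dtype=int)),
            clusters=ClusterAssignment(
                tuple(np.asarray(l, dtype=int) for l in d["labels_per_view"])
            ),
            stats=stats,
            score=d["score"],
            roi_set=RoiSet(tuple(d["roi_labels"])) if d["roi_labels"] else None,
        )


@dataclass(frozen=True)
class ModelSelectionReport:
    ranked_scores: tuple[float, ...]
    top_set: tuple[int, ...]
    pairwise_ari: np.ndarray
    chosen: int


# ---------------------------------------------------------------------------
# marginal likelihood


def cluster_log_marginal(
    stats: WishartClusterStats, d: int, hyper: ModelHyperparams
) -> float:
    """Collapsed log marginal likelihood of one cluster's scatters."""
    m = stats.member_count
    if m == 0:
        return 0.0
    nu = hyper.dof
    if nu <= d - 1:
        raise ValueError(f"dof={nu} undefined for view dimension d={d}")
    nu0 = hyper.nu0(d)
    psi0 = hyper.psi0_diag(d)
    nu_m = nu0 + m * nu
    psi_m = stats.scatter_sum + psi0 * np.eye(d)
    sign, logdet_psi_m = np.linalg.slogdet(psi_m)
    if sign <= 0:
        raise ValueError("Psi_m is not positive definite")
    return float(
        0.5 * (nu - d - 1) * stats.logdet_sum
        - m * multigammaln(nu / 2.0, d)
        + 0.5 * nu0 * d * math.log(psi0)
        + multigammaln(nu_m / 2.0, d)
        - multigammaln(nu0 / 2.0, d)
        - 0.5 * nu_m * logdet_psi_m
    )


def _block_marginal_terms(
    m: int, logdet_psi_m: float, d: int, hyper: ModelHyperparams
) -> float:
    """Partition-comparable cluster marginal M0 (module docstring)."""
    if m == 0:
        return 0.0
    nu = hyper.dof
    nu0 = hyper.nu0(d)
    psi0 = hyper.psi0_diag(d)
    nu_m = nu0 + m * nu
    return float(
        0.5 * nu0 * d * math.log(psi0)
        - multigammaln(nu0 / 2.0, d)
        + multigammaln(nu_m / 2.0, d)
        - 0.5 * nu_m * logdet_psi_m
        + 0.5 * m * nu * d * math.log(2.0)
    )


def partition_cluster_marginal(
    stats: WishartClusterStats, d: int, hyper: ModelHyperparams
) -> float:
    """M0 for one cluster from its sufficient statistics."""
    if stats.member_count == 0:
        return 0.0
    psi_m = stats.scatter_sum + hyper.psi0_diag(d) * np.eye(d)
    sign, logdet = np.linalg.slogdet(psi_m)
    if sign <= 0:
        raise ValueError("Psi_m is not positive definite")
    return _block_marginal_terms(stats.member_count, logdet, d, hyper)


def model_log_posterior(model: MultiViewModel) -> float:
    """Collapsed joint log posterior (up to a constant) from cached stats."""
    part, clus, hyper = model.partition, model.clusters, model.hyper
    p = len(np.asarray(part.view_of_roi))
    n = len(clus.labels_per_view[0])
    s = crp_log_prior(part.sizes(), hyper.alpha_view, p)
    for v in range(part.n_views):
        d = len(part.rois_of_view(v))
        s += crp_log_prior(clus.sizes(v), hyper.alpha_cluster, n)
        for st in model.stats[v]:
            s += partition_cluster_marginal(st, d, hyper)
    return s


# ---------------------------------------------------------------------------
# Wishart likelihood backend for the greedy engine


class _WishartView(ViewData):
    def __init__(self, backend: "WishartBackend", items: tuple[int, ...]):
        self.items = items
        self.d = len(items)
        idx = np.asarray(items)
        self.sub = backend.scatters[:, idx[:, None], idx[None, :]]
        sign, self.logdets = np.linalg.slogdet(self.sub)
        if (sign <= 0).any():
            bad = int(np.where(sign <= 0)[0][0])
            raise ValueError(
                f"subject index {bad}: scatter submatrix on items {items} "
                "is not positive definite; regularize the correlations first"
            )
        h = backend.hyper
        self.nu = h.dof
        self.nu0 = h.nu0(self.d)
        self.psi0 = h.psi0_diag(self.d)
        self._lgam_nu = multigammaln(self.nu / 2.0, self.d)
        self._lgam_cache: dict[int, float] = {}
        self._eye = np.eye(self.d)

    def lgam_m(self, m: int) -> float:
        val = self._lgam_cache.get(m)
        if val is None:
            val = multigammaln((self.nu0 + m * self.nu) / 2.0, self.d)
            self._lgam_cache[m] = val
        return val

    def new_cluster(self) -> "_WishartCluster":
        return _WishartCluster(self)

    def block_marginal(self, m: int, logdet_psi_m: float) -> float:
        if m == 0:
            return 0.0
        nu_m = self.nu0 + m * self.nu
        return (
            0.5 * self.nu0 * self.d * math.log(self.psi0)
            - self.lgam_m(0)
            + self.lgam_m(m)
            - 0.5 * nu_m * logdet_psi_m
            + 0.5 * m * self.nu * self.d * math.log(2.0)
        )

    def frozen_marginal_sum(self, labels: np.ndarray) -> float:
        total = 0.0
        for lab in np.unique(labels):
            mask = labels == lab
            psi_m = self.psi0 * self._eye + self.sub[mask].sum(axis=0)
            _, logdet_psi_m = np.linalg.slogdet(psi_m)
            total += self.block_marginal(int(mask.sum()), logdet_psi_m)
        return total


class _WishartCluster(ClusterState):
    def __init__(self, view: _WishartView):
        self.view = view
        self.m = 0
        self.scatter_sum = np.zeros((view.d, view.d))
        self.logdet_sum = 0.0
        self._logdet_psi_m: float | None = None

    def _psi_m(self) -> np.ndarray:
        return self.view.psi0 * self.view._eye + self.scatter_sum

    def logdet_psi_m(self) -> float:
        if self._logdet_psi_m is None:
            _, self._logdet_psi_m = np.linalg.slogdet(self._psi_m())
        return self._logdet_psi_m

    def add(self, i: int) -> None:
        self.scatter_sum += self.view.sub[i]
        self.logdet_sum += self.view.logdets[i]
        self.m += 1
        self._logdet_psi_m = None

    def remove(self, i: int) -> None:
        self.scatter_sum -= self.view.sub[i]
        self.logdet_sum -= self.view.logdets[i]
        self.m -= 1
        self._logdet_psi_m = None

    def log_marginal(self) -> float:
        if self.m == 0:
            return 0.0
        return float(self.view.block_marginal(self.m, self.logdet_psi_m()))

    def predictive_delta(self, i: int) -> float:
        v = self.view
        _, logdet_next = np.linalg.slogdet(self._psi_m() + v.sub[i])
        return float(
            v.block_marginal(self.m + 1, logdet_next)
            - v.block_marginal(self.m, self.logdet_psi_m())
        )


class WishartBackend(Backend):
    """Scatter data + hyperparameters for the greedy engine."""

    def __init__(self, dataset: FCDataset, hyper: ModelHyperparams):
        self.scatters = hyper.dof * dataset.stack()
        self.n_items = dataset.p
        self.n_subjects = dataset.n_subjects
        self.hyper = hyper
        # Wishart density undefined for view dimension d > nu - 1.
        self.max_view_dim = min(dataset.p, int(math.floor(hyper.dof)) - 1)
        self._view_cache: dict[tuple[int, ...], _WishartView] = {}

    def make_view(self, items: tuple[int, ...]) -> _WishartView:
        view = self._view_cache.get(items)
        if view is None:
            view = _WishartView(self, items)
            if len(self._view_cache) > 512:
                self._view_cache.clear()
            self._view_cache[items] = view
        return view


# ---------------------------------------------------------------------------
# fitting


def _model_from_search(
    search: GreedySearch, dataset: FCDataset, hyper: ModelHyperparams
) -> MultiViewModel:
    item_of, labels = search.partitions()
    partition = ViewPartition(item_of)
    assignment = ClusterAssignment(
        tuple(labels[v] for v in range(len(labels)))
    )
    scatters = hyper.dof * dataset.stack()
    stats = _stats_from_partition(scatters, partition, assignment)
    model = MultiViewModel(
        hyper=hyper,
        partition=partition,
        clusters=assignment,
        stats=stats,
        score=search.score(),
        roi_set=dataset.roi_set,
        score_trace=tuple(search.score_trace),
    )
    return model


def _stats_from_partition(
    scatters: np.ndarray, partition: ViewPartition, assignment: ClusterAssignment
) -> tuple[tuple[WishartClusterStats, ...], ...]:
    out = []
    for v in range(partition.n_views):
        idx = partition.rois_of_view(v)
        sub = scatters[:, idx[:, None], idx[None, :]]
        _, logdets = np.linalg.slogdet(sub)
        labels = assignment.labels(v)
        view_stats = []
        for lab in np.unique(labels):
            mask = labels == lab
            view_stats.append(
                WishartClusterStats(
                    member_count=int(mask.sum()),
                    scatter_sum=sub[mask].sum(axis=0),
                    logdet_sum=float(logdets[mask].sum()),
                )
            )
        out.append(tuple(view_stats))
    return tuple(out)


def score_from_scratch(
    dataset: FCDataset,
    hyper: ModelHyperparams,
    partition: ViewPartition,
    assignment: ClusterAssignment,
) -> float:
    """Recompute the collapsed joint log posterior from raw data."""
    scatters = hyper.dof * dataset.stack()
    stats = _stats_from_partition(scatters, partition, assignment)
    model = MultiViewModel(hyper, partition, assignment, stats, score=0.0)
    return model_log_posterior(model)


def greedy_fit(
    dataset: FCDataset,
    hyper: ModelHyperparams | None = None,
    max_sweeps: int = 50,
    seed: int = 0,
    init: tuple[np.ndarray, dict[int, np.ndarray]] | None = None,
) -> MultiViewModel:
    """One greedy MAP run on a whitened + regularized dataset."""
    hyper = hyper or ModelHyperparams(dof=dataset.dof)
    backend = WishartBackend(dataset, hyper)
    search = GreedySearch(
        backend,
        alpha_view=hyper.alpha_view,
        alpha_cluster=hyper.alpha_cluster,
        max_sweeps=max_sweeps,
        seed=seed,
    )
    if init is not None:
        search.init_from(*init)
    search.fit()
    return _model_from_search(search, dataset, hyper)


def fit_multistart(
    dataset: FCDataset,
    hyper: ModelHyperparams | None = None,
    n_init: int = 100,
    max_sweeps: int = 50,
    seed: int = 0,
) -> list[MultiViewModel]:
    """Independent greedy fits from ``n_init`` derived seeds, in order."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    child_seeds = derive_seeds(seed, n_init)
    return [
        greedy_fit(dataset, hyper, max_sweeps=max_sweeps, seed=s)
        for s in child_seeds
    ]


def derive_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


# ---------------------------------------------------------------------------
# model selection


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement via pair counting."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be equal-length 1-D")
    n = a.size
    if n < 2:
        raise ValueError("need at least two elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def select_model(
    models: list[MultiViewModel], top_k: int = 10
) -> ModelSelectionReport:
    """Stability-based selection among multistart models.

    Rank by score, keep the top ``top_k``, compute pairwise ARI of the
    ROI view-membership labelings, find the max-ARI pair and choose its
    higher-scoring member (ties by lower model index).
    """
    if not models:
        raise ValueError("no models to select from")
    scores = np.array([m.score for m in models])
    order = np.argsort(-scores, kind="stable")
    if len(models) == 1:
        return ModelSelectionReport(
            ranked_scores=(float(scores[0]),),
            top_set=(0,),
            pairwise_ari=np.zeros((1, 1)),
            chosen=0,
        )
    top = order[: min(top_k, len(models))]
    t = len(top)
    ari = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            val = adjusted_rand_index(
                models[top[i]].partition.view_of_roi,
                models[top[j]].partition.view_of_roi,
            )
            ari[i, j] = ari[j, i] = val
    best_pair, best_val = (0, 1), -np.inf
    for i in range(t):
        for j in range(i + 1, t):
            if ari[i, j] > best_val:
                best_pair, best_val = (i, j), ari[i, j]
    i, j = best_pair
    mi, mj = int(top[i]), int(top[j])
    if scores[mi] > scores[mj]:
        chosen = mi
    elif scores[mj] > scores[mi]:
        chosen = mj
    else:
        chosen = min(mi, mj)
    return ModelSelectionReport(
        ranked_scores=tuple(float(scores[k]) for k in order),
        top_set=tuple(int(k) for k in top),
        pairwise_ari=ari,
        chosen=chosen,
    )
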