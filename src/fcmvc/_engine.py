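"""Greedy MAP search over joint (item partition, per-view subject clusters).

This is the optimization core shared by the ROI-based Wishart model and
the FC-based Gaussian baseline.  The latent structure is a Chinese
restaurant process (CRP) partition of *items* (ROIs or vectorized-FC
features) into views, and, within each view, a CRP partition of
*subjects* into clusters.  A likelihood backend supplies, for any item
subset, the collapsed (conjugate) log marginal likelihood of a subject
cluster; the engine owns the CRP prior terms, the sweep schedule, and
the bookkeeping.

The objective is the collapsed joint log posterior (up to a constant):

    crp(view sizes) + sum_v [ crp(cluster sizes in v) + sum_k marginal(v, k) ]

Sweep schedule, iterated to convergence or ``max_sweeps``:

1. subject sweep: per view, each subject is removed and reassigned to
   the argmax over existing clusters (CRP weight m_k) and a new cluster
   (weight alpha) of CRP weight x posterior-predictive marginal;
2. item sweep: each item is tentatively moved to every other view and a
   new singleton view, scoring only the affected views with cluster
   assignments frozen; the best strictly improving move is accepted and
   followed by a subject sweep on the affected views.

Ties keep the incumbent assignment; among non-incumbent ties the lowest
id wins, so runs are deterministic given the initialization seed.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

_TIE_TOL = 1e-10
_IMPROVE_TOL = 1e-9


def crp_log_prior(group_sizes, alpha: float, n: int) -> float:
    """Log CRP probability of a partition of n elements with given sizes.

    log[ alpha^K * prod_k (n_k - 1)! * Gamma(alpha) / Gamma(alpha + n) ].
    """
    sizes = np.asarray(group_sizes)
    if sizes.size == 0 or (sizes <= 0).any():
        raise ValueError("group sizes must be positive")
    if int(sizes.sum()) != n:
        raise ValueError(f"group sizes sum to {sizes.sum()}, expected {n}")
    if alpha <= 0:
        raise ValueError("CRP concentration must be positive")
    K = sizes.size
    return float(
        K * np.log(alpha)
        + gammaln(sizes).sum()
        + gammaln(alpha)
        - gammaln(alpha + n)
    )


class ClusterState(ABC):
    """Sufficient statistics of one subject cluster within one view."""

    m: int

    @abstractmethod
    def add(self, i: int) -> None: ...

    @abstractmethod
    def remove(self, i: int) -> None: ...

    @abstractmethod
    def log_marginal(self) -> float: ...

    @abstractmethod
    def predictive_delta(self, i: int) -> float:
        """log_marginal with subject i added, minus current log_marginal."""


class ViewData(ABC):
    """Per-view precomputation for a fixed item subset."""

    items: tuple[int, ...]

    @abstractmethod
    def new_cluster(self) -> ClusterState: ...

    def frozen_marginal_sum(self, labels: np.ndarray) -> float:
        total = 0.0
        for lab in np.unique(labels):
            c = self.new_cluster()
            for i in np.where(labels == lab)[0]:
                c.add(int(i))
            total += c.log_marginal()
        return total


class Backend(ABC):
    n_items: int
    n_subjects: int
    #: Largest admissible view dimension (None = unbounded).
    max_view_dim: int | None = None

    @abstractmethod
    def make_view(self, items: tuple[int, ...]) -> ViewData: ...


@dataclass
class _ViewState:
    items: list[int]
    data: ViewData
    labels: np.ndarray  # subject -> cluster id
    clusters: dict[int, ClusterState]
    next_cluster_id: int

    def cluster_sizes(self) -> list[int]:
        return [c.m for c in self.clusters.values()]

    def marginal_sum(self) -> float:
        return sum(c.log_marginal() for c in self.clusters.values())


def _crp_draw(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    sizes: list[int] = []
    for i in range(n):
        weights = np.array(sizes + [alpha], dtype=float)
        k = rng.choice(len(weights), p=weights / weights.sum())
        if k == len(sizes):
            sizes.append(1)
        else:
            sizes[k] += 1
        labels[i] = k
    return labels


class GreedySearch:
    """One greedy MAP run from one random initialization."""

    def __init__(
        self,
        backend: Backend,
        alpha_view: float = 1.0,
        alpha_cluster: float = 1.0,
        max_sweeps: int = 50,
        seed: int = 0,
    ):
        self.backend = backend
        self.alpha_view = alpha_view
        self.alpha_cluster = alpha_cluster
        self.max_sweeps = max_sweeps
        self.rng = np.random.default_rng(seed)
        self.views: dict[int, _ViewState] = {}
        self.next_view_id = 0
        self.item_of = np.full(backend.n_items, -1, dtype=int)
        self.score_trace: list[float] = []

    # -- construction -------------------------------------------------------

    def _build_view(self, items: list[int], labels: np.ndarray) -> _ViewState:
        data = self.backend.make_view(tuple(sorted(items)))
        clusters: dict[int, ClusterState] = {}
        for lab in np.unique(labels):
            c = data.new_cluster()
            for i in np.where(labels == lab)[0]:
                c.add(int(i))
            clusters[int(lab)] = c
        return _ViewState(
            items=sorted(items),
            data=data,
            labels=labels.copy(),
            clusters=clusters,
            next_cluster_id=int(labels.max()) + 1,
        )

    def init_random(self) -> None:
        cap = self.backend.max_view_dim or self.backend.n_items
        item_labels = _crp_draw(self.backend.n_items, self.alpha_view, self.rng)
        # Split any CRP view that exceeds the admissible dimension.
        sizes: dict[int, int] = {}
        next_lab = int(item_labels.max()) + 1
        for j in range(self.backend.n_items):
            lab = int(item_labels[j])
            if sizes.get(lab, 0) >= cap:
                item_labels[j] = next_lab
                sizes[next_lab] = 1
                next_lab += 1
            else:
                sizes[lab] = sizes.get(lab, 0) + 1
        for lab in np.unique(item_labels):
            items = list(np.where(item_labels == lab)[0])
            subj = _crp_draw(self.backend.n_subjects, self.alpha_cluster, self.rng)
            vid = self.next_view_id
            self.next_view_id += 1
            self.views[vid] = self._build_view(items, subj)
            self.item_of[items] = vid

    def init_from(self, item_of: np.ndarray, labels_per_view: dict[int, np.ndarray]) -> None:
        for vid in sorted(labels_per_view):
            items = list(np.where(np.asarray(item_of) == vid)[0])
            if not items:
                raise ValueError(f"view {vid} owns no items")
            new_vid = self.next_view_id
            self.next_view_id += 1
            self.views[new_vid] = self._build_view(
                items, np.asarray(labels_per_view[vid], dtype=int)
            )
            self.item_of[items] = new_vid

    # -- scoring ------------------------------------------------------------

    def score(self) -> float:
        view_sizes = [len(v.items) for v in self.views.values()]
        s = crp_log_prior(view_sizes, self.alpha_view, self.backend.n_items)
        for v in self.views.values():
            s += crp_log_prior(
                v.cluster_sizes(), self.alpha_cluster, self.backend.n_subjects
            )
            s += v.marginal_sum()
        return s

    def _frozen_view_score(self, items: list[int], labels: np.ndarray) -> float:
        """CRP + marginal score of a candidate view with frozen assignments."""
        data = self.backend.make_view(tuple(sorted(items)))
        sizes = np.unique(labels, return_counts=True)[1]
        return (
            crp_log_prior(sizes, self.alpha_cluster, self.backend.n_subjects)
            + data.frozen_marginal_sum(labels)
        )

    def _current_view_score(self, v: _ViewState) -> float:
        return (
            crp_log_prior(
                v.cluster_sizes(), self.alpha_cluster, self.backend.n_subjects
            )
            + v.marginal_sum()
        )

    # -- subject sweep ------------------------------------------------------

    def subject_sweep(self, vid: int) -> int:
        v = self.views[vid]
        changed = 0
        for i in range(self.backend.n_subjects):
            orig = int(v.labels[i])
            state = v.clusters[orig]
            state.remove(i)
            vacated = state.m == 0
            if vacated:
                del v.clusters[orig]
            best_id, best_val = None, -np.inf
            for cid in sorted(v.clusters):
                c = v.clusters[cid]
                val = np.log(c.m) + c.predictive_delta(i)
                if val > best_val + _TIE_TOL or (
                    val > best_val - _TIE_TOL and cid == orig
                ):
                    best_id, best_val = cid, val
            empty = v.data.new_cluster()
            val_new = np.log(self.alpha_cluster) + empty.predictive_delta(i)
            incumbent_is_new = vacated
            if val_new > best_val + _TIE_TOL or (
                incumbent_is_new and val_new > best_val - _TIE_TOL
            ):
                new_id = orig if vacated else v.next_cluster_id
                if not vacated:
                    v.next_cluster_id += 1
                empty.add(i)
                v.clusters[new_id] = empty
                v.labels[i] = new_id
                if new_id != orig:
                    changed += 1
            else:
                v.clusters[best_id].add(i)
                v.labels[i] = best_id
                if best_id != orig:
                    changed += 1
        return changed

    # -- item sweep ---------------------------------------------------------

    def item_sweep(self) -> int:
        cap = self.backend.max_view_dim or self.backend.n_items
        moves = 0
        for r in range(self.backend.n_items):
            u = int(self.item_of[r])
            vu = self.views[u]
            view_sizes = {vid: len(v.items) for vid, v in self.views.items()}
            score_u_cur = self._current_view_score(vu)
            items_u_without = [j for j in vu.items if j != r]
            if items_u_without:
                score_u_without = self._frozen_view_score(items_u_without, vu.labels)
            else:
                score_u_without = 0.0  # view u disappears

            def crp_items(sizes: list[int]) -> float:
                return crp_log_prior(sizes, self.alpha_view, self.backend.n_items)

            cur_sizes = list(view_sizes.values())
            crp_cur = crp_items(cur_sizes)

            candidates: list[tuple[float, int]] = []  # (delta, dest or -1 for new)
            for w in sorted(self.views):
                if w == u:
                    continue
                if view_sizes[w] + 1 > cap:
                    continue
                sizes = []
                for vid, s in view_sizes.items():
                    if vid == u:
                        if s > 1:
                            sizes.append(s - 1)
                    elif vid == w:
                        sizes.append(s + 1)
                    else:
                        sizes.append(s)
                vw = self.views[w]
                score_w_cur = self._current_view_score(vw)
                score_w_with = self._frozen_view_score(
                    vw.items + [r], vw.labels
                )
                delta = (
                    crp_items(sizes)
                    - crp_cur
                    + (score_u_without - score_u_cur)
                    + (score_w_with - score_w_cur)
                )
                candidates.append((delta, w))
            # new singleton view (all subjects in one cluster)
            if len(vu.items) > 1:
                sizes = [
                    (s - 1 if vid == u else s) for vid, s in view_sizes.items()
                ] + [1]
                score_new = self._frozen_view_score(
                    [r], np.zeros(self.backend.n_subjects, dtype=int)
                )
                delta = (
                    crp_items(sizes)
                    - crp_cur
                    + (score_u_without - score_u_cur)
                    + score_new
                )
                candidates.append((delta, -1))

            if not candidates:
                continue
            best_delta, best_dest = max(candidates, key=lambda t: (t[0], -t[1]))
            if best_delta <= _IMPROVE_TOL:
                continue
            # apply the move
            moves += 1
            affected = []
            if items_u_without:
                self.views[u] = self._build_view(items_u_without, vu.labels)
                affected.append(u)
            else:
                del self.views[u]
            if best_dest == -1:
                vid = self.next_view_id
                self.next_view_id += 1
                self.views[vid] = self._build_view(
                    [r], np.zeros(self.backend.n_subjects, dtype=int)
                )
                self.item_of[r] = vid
                affected.append(vid)
            else:
                vw = self.views[best_dest]
                self.views[best_dest] = self._build_view(
                    vw.items + [r], vw.labels
                )
                self.item_of[r] = best_dest
                affected.append(best_dest)
            for vid in affected:
                self.subject_sweep(vid)
        return moves

    # -- main loop ----------------------------------------------------------

    def fit(self) -> "GreedySearch":
        if not self.views:
            self.init_random()
        self.score_trace.append(self.score())
        for _ in range(self.max_sweeps):
            changed = 0
            for vid in sorted(self.views):
                changed += self.subject_sweep(vid)
            moved = self.item_sweep()
            self.score_trace.append(self.score())
            if changed == 0 and moved == 0:
                break
        return self

    # -- export -------------------------------------------------------------

    def partitions(self) -> tuple[np.ndarray, dict[int, np.ndarray]]:
        """Item partition and per-view subject labels, relabeled densely.

        Views are numbered by ascending smallest item index; clusters per
        view by ascending first occurrence in subject order.
        """
        order = sorted(self.views, key=lambda vid: min(self.views[vid].items))
        item_of = np.zeros(self.backend.n_items, dtype=int)
        labels_out: dict[int, np.ndarray] = {}
        for new_vid, vid in enumerate(order):
            v = self.views[vid]
            item_of[v.items] = new_vid
            labels = v.labels
            remap: dict[int, int] = {}
            dense = np.zeros_like(labels)
            for i, lab in enumerate(labels):
                if int(lab) not in remap:
                    remap[int(lab)] = len(remap)
                dense[i] = remap[int(lab)]
            labels_out[new_vid] = dense
        return item_of, labels_out
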