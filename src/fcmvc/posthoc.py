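"""Validation statistics for cluster solutions.

Covers the full post-hoc surface: cluster x diagnosis contingency
tables with small-cluster filtering, Pearson chi-square tests (no
continuity correction), Cramér's V effect sizes, Kruskal-Wallis tests,
edge-wise Cohen's d screening within a view, the intersection of
"commonly important" edges, and classical (Torgerson) multidimensional
scaling of cluster-center matrices with a fitted continuum axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable:
    counts: pd.DataFrame  # rows: clusters, columns: diagnoses

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def disorder_wise_proportions(self) -> pd.DataFrame:
        """Each diagnosis column normalized to sum to 1."""
        c = self.counts.astype(float)
        return c / c.sum(axis=0)

    def cluster_wise_proportions(self) -> pd.DataFrame:
        """Each cluster row normalized to sum to 1."""
        c = self.counts.astype(float)
        return c.div(c.sum(axis=1), axis=0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    effect_size: float | None = None


@dataclass(frozen=True)
class EffectSizeReport:
    view_id: int
    cluster_pair: tuple[int, int]
    edges: tuple[tuple[int, int], ...]  # ROI index pairs within the view set
    d_values: np.ndarray
    threshold: float = 0.8

    def flagged(self) -> set[tuple[int, int]]:
        return {
            e for e, d in zip(self.edges, self.d_values) if abs(d) > self.threshold
        }


@dataclass(frozen=True)
class MdsEmbedding:
    coordinates: np.ndarray  # (k, 2)
    eigenvalues: np.ndarray
    center_definition: str = "entrywise mean correlation matrix"
    cluster_ids: tuple[int, ...] = ()


def crosstab(
    assignments,
    diagnoses,
    min_cluster_size: int = 10,
) -> ContingencyTable:
    """Cluster x diagnosis counts, dropping clusters below the size floor.

    ``assignments`` and ``diagnoses`` are aligned per-subject sequences.
    Small clusters (fewer than ``min_cluster_size`` subjects) are removed
    from the table, mirroring the convention of reporting only clusters
    large enough to characterize.
    """
    s_clu = pd.Series(list(assignments), name="cluster")
    s_dia = pd.Series(list(diagnoses), name="diagnosis")
    if len(s_clu) != len(s_dia):
        raise ValueError("assignments and diagnoses must be aligned")
    table = pd.crosstab(s_clu, s_dia)
    keep = table.sum(axis=1) >= min_cluster_size
    return ContingencyTable(table.loc[keep])


def _as_counts(table: ContingencyTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts.to_numpy()
    if isinstance(table, pd.DataFrame):
        return table.to_numpy()
    return np.asarray(table)


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = _as_counts(table)
    if counts.sum() <= 0:
        raise ValueError("contingency table is empty")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any():
        raise ValueError(f"all-zero row at index {int(np.where(row == 0)[0][0])}")
    if (col == 0).any():
        raise ValueError(f"all-zero column at index {int(np.where(col == 0)[0][0])}")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(float(chi2), int(dof), float(p))


def cramers_v(table) -> float:
    """V = sqrt(chi2 / (N * (min(r, c) - 1)))."""
    counts = _as_counts(table)
    res = pearson_chi2(counts)
    r, c = counts.shape
    return float(np.sqrt(res.statistic / (counts.sum() * (min(r, c) - 1))))


def kruskal_wallis(groups) -> TestResult:
    """Rank-based H test (tie-corrected) across two or more samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        # Every observation identical: H = 0 by convention.
        return TestResult(0.0, len(groups) - 1, 1.0)
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), len(groups) - 1, float(p))


def view_edges(view_rois) -> list[tuple[int, int]]:
    idx = list(view_rois)
    return [(idx[a], idx[b]) for a in range(len(idx)) for b in range(a + 1, len(idx))]


def cohens_d_edges(
    dataset,
    view_rois,
    cluster_a_members,
    cluster_b_members,
    view_id: int = 0,
    cluster_pair: tuple[int, int] = (0, 1),
    threshold: float = 0.8,
) -> EffectSizeReport:
    """Pooled-SD standardized mean FC difference for every within-view edge.

    ``dataset`` supplies the correlation matrices in the space the
    clustering saw (whitened + regularized by default; pass raw data to
    screen raw correlations instead).
    """
    a = np.asarray(cluster_a_members)
    b = np.asarray(cluster_b_members)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both clusters need at least two members")
    stacked = dataset.stack()
    edges = view_edges(view_rois)
    rows = np.array([e[0] for e in edges])
    cols = np.array([e[1] for e in edges])
    xa = stacked[np.ix_(a)][:, rows, cols]
    xb = stacked[np.ix_(b)][:, rows, cols]
    na, nb = len(a), len(b)
    mean_diff = xa.mean(axis=0) - xb.mean(axis=0)
    pooled = np.sqrt(
        ((na - 1) * xa.var(axis=0, ddof=1) + (nb - 1) * xb.var(axis=0, ddof=1))
        / (na + nb - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, mean_diff / pooled, 0.0)
    return EffectSizeReport(
        view_id=view_id,
        cluster_pair=cluster_pair,
        edges=tuple(edges),
        d_values=d,
        threshold=threshold,
    )


def common_important_edges(
    reports: list[EffectSizeReport], threshold: float = 0.8
) -> set[tuple[int, int]]:
    """Edges flagged (|d| > threshold) in every pairwise report."""
    if not reports:
        raise ValueError("need at least one report")
    sets = [
        {e for e, d in zip(r.edges, r.d_values) if abs(d) > threshold}
        for r in reports
    ]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def mds_cluster_centers(
    dataset, assignments, clusters=None
) -> MdsEmbedding:
    """Classical MDS of cluster-center matrices.

    Centers are entrywise mean correlation matrices per cluster;
    distances are Frobenius (Euclidean on the vectorized matrices);
    the embedding comes from double-centering B = -1/2 J D^2 J and the
    top-2 eigenpairs, with each coordinate column's first nonzero
    loading made positive.
    """
    labels = np.asarray(assignments)
    if clusters is None:
        clusters = sorted(np.unique(labels).tolist())
    clusters = list(clusters)
    stacked = dataset.stack()
    centers = []
    for c in clusters:
        mask = labels == c
        if not mask.any():
            raise ValueError(f"cluster {c} has no members")
        centers.append(stacked[mask].mean(axis=0).ravel())
    X = np.array(centers)
    k = len(clusters)
    D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ D2 @ J
    lam, U = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    coords = U[:, :2] * np.sqrt(np.clip(lam[:2], 0.0, None))
    for j in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, j]) > 1e-12)[0]
        if nz.size and coords[nz[0], j] < 0:
            coords[:, j] = -coords[:, j]
    coords = coords - coords.mean(axis=0)
    return MdsEmbedding(
        coordinates=coords, eigenvalues=lam, cluster_ids=tuple(clusters)
    )


def continuum_axis(
    embedding: MdsEmbedding, subset
) -> tuple[float, float, np.ndarray]:
    """OLS line y = slope*x + intercept through a subset of cluster centers.

    Returns (slope, intercept, residuals-for-all-embedded-points).
    """
    ids = list(embedding.cluster_ids)
    pos = [ids.index(c) for c in subset]
    if len(pos) < 2:
        raise ValueError("continuum axis needs at least two clusters")
    x = embedding.coordinates[pos, 0]
    y = embedding.coordinates[pos, 1]
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate axis: subset points share one x coordinate")
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    residuals = embedding.coordinates[:, 1] - (
        slope * embedding.coordinates[:, 0] + intercept
    )
    return slope, intercept, residuals
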