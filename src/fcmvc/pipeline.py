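"""Discovery -> model selection -> validation orchestration.

Runs the full analysis on one dataset: self-whitening, diagonal
regularization, multistart greedy fitting, stability-based model
selection, relabeling by the reporting convention (views in ascending
order of their number of subject clusters, clusters in descending order
of size, both 1-based in reports), per-view cluster-diagnosis
association tests with Bonferroni correction, and out-of-sample
validation of a chosen view on an independent dataset under both
whitening modes.

Artifacts are deterministic given the master seed; every JSON artifact
embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fc_data import FCDataset, regularize_dataset
from .multiview import (
    ClusterAssignment,
    ModelHyperparams,
    MultiViewModel,
    ViewPartition,
    fit_multistart,
    select_model,
)
from .posthoc import ContingencyTable, cramers_v, crosstab, pearson_chi2
from .whitening import fit_whitening, apply_whitening


@dataclass(frozen=True)
class RunConfig:
    seed: int
    n_init: int = 100
    max_sweeps: int = 50
    top_k: int = 10
    epsilon: float = 0.05
    min_cluster_size: int = 10
    alpha_view: float = 1.0
    alpha_cluster: float = 1.0
    nu0_offset: float = 2.0
    psi0_scale: float = 1.0
    output_dir: str | None = None

    def hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def relabel_model(model: MultiViewModel) -> MultiViewModel:
    """Apply the reporting convention to view and cluster ids.

    Views are renumbered in ascending order of their number of subject
    clusters (ties by ascending smallest ROI index); within each view,
    clusters are renumbered in descending order of member count (ties
    by original id).  Ids stay 0-based internally; reports add 1.
    """
    part, clus = model.partition, model.clusters
    n_views = part.n_views
    keys = []
    for v in range(n_views):
        n_clusters = len(np.unique(clus.labels(v)))
        keys.append((n_clusters, int(part.rois_of_view(v).min()), v))
    order = [v for _, _, v in sorted(keys)]
    view_map = {old: new for new, old in enumerate(order)}
    new_view_of_roi = np.array(
        [view_map[int(v)] for v in np.asarray(part.view_of_roi)]
    )
    new_labels = []
    for new_v, old_v in enumerate(order):
        labels = np.asarray(clus.labels(old_v))
        ids, counts = np.unique(labels, return_counts=True)
        cluster_order = ids[np.argsort(-counts, kind="stable")]
        cmap = {int(old): new for new, old in enumerate(cluster_order)}
        new_labels.append(np.array([cmap[int(l)] for l in labels]))
    partition = ViewPartition(new_view_of_roi)
    assignment = ClusterAssignment(tuple(new_labels))
    # Rebuild stats by permuting the cached per-view tuples.
    new_stats = []
    for new_v, old_v in enumerate(order):
        labels = np.asarray(clus.labels(old_v))
        ids, counts = np.unique(labels, return_counts=True)
        cluster_order = ids[np.argsort(-counts, kind="stable")]
        old_stats = model.stats[old_v]
        new_stats.append(tuple(old_stats[int(c)] for c in cluster_order))
    return MultiViewModel(
        hyper=model.hyper,
        partition=partition,
        clusters=assignment,
        stats=tuple(new_stats),
        score=model.score,
        roi_set=model.roi_set,
        score_trace=model.score_trace,
    )


def association_table(
    model: MultiViewModel, diagnoses, min_cluster_size: int = 10
) -> pd.DataFrame:
    """Per-view chi-square association between clusters and diagnoses.

    Clusters below the size floor are dropped before testing; the
    Bonferroni threshold is 0.05 / n_views.
    """
    rows = []
    n_views = model.partition.n_views
    for v in range(n_views):
        labels = model.clusters.labels(v)
        table = crosstab(labels, diagnoses, min_cluster_size=min_cluster_size)
        counts = table.counts.loc[:, (table.counts.sum(axis=0) > 0)]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            rows.append(
                {"view": v + 1, "chi2": np.nan, "df": np.nan, "p": 1.0,
                 "n_clusters_tested": counts.shape[0]}
            )
            continue
        res = pearson_chi2(counts.to_numpy())
        rows.append(
            {"view": v + 1, "chi2": res.statistic, "df": res.df, "p": res.p_value,
             "n_clusters_tested": counts.shape[0]}
        )
    df = pd.DataFrame(rows)
    df["bonferroni_significant"] = df["p"] < 0.05 / n_views
    return df


@dataclass
class DiscoveryBundle:
    model: MultiViewModel
    selection_chosen: int
    association: pd.DataFrame
    selected_view: int  # 0-based
    view_summary: pd.DataFrame
    cluster_diagnosis_table: ContingencyTable
    config_hash: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "selected_view": int(self.selected_view),
                "selection_chosen": int(self.selection_chosen),
                "model": json.loads(self.model.to_json()),
                "association": self.association.to_dict(orient="records"),
                "view_summary": self.view_summary.to_dict(orient="records"),
            },
            sort_keys=True,
        )


def run_discovery(dataset: FCDataset, config: RunConfig) -> DiscoveryBundle:
    """Whiten, regularize, fit, select, relabel, and test associations."""
    hyper = ModelHyperparams(
        dof=dataset.dof,
        alpha_view=config.alpha_view,
        alpha_cluster=config.alpha_cluster,
        nu0_offset=config.nu0_offset,
        psi0_scale=config.psi0_scale,
    )
    transform = fit_whitening(dataset, reference_label="self")
    prepared = regularize_dataset(apply_whitening(transform, dataset), config.epsilon)
    prepared = FCDataset(
        prepared.roi_set, prepared.matrices, prepared.metadata,
        dof=dataset.dof, provenance=prepared.provenance,
    )
    models = fit_multistart(
        prepared, hyper, n_init=config.n_init,
        max_sweeps=config.max_sweeps, seed=config.seed,
    )
    report = select_model(models, top_k=config.top_k)
    model = relabel_model(models[report.chosen])
    diagnoses = dataset.diagnoses
    assoc = association_table(model, diagnoses, config.min_cluster_size)
    selected_view = int(assoc.loc[assoc["p"].idxmin(), "view"]) - 1
    labels = model.clusters.labels(selected_view)
    table = crosstab(labels + 1, diagnoses, min_cluster_size=config.min_cluster_size)
    view_summary = pd.DataFrame(
        {
            "view": np.arange(model.partition.n_views) + 1,
            "n_rois": model.partition.sizes(),
            "n_clusters": [
                len(np.unique(model.clusters.labels(v)))
                for v in range(model.partition.n_views)
            ],
        }
    )
    return DiscoveryBundle(
        model=model,
        selection_chosen=report.chosen,
        association=assoc,
        selected_view=selected_view,
        view_summary=view_summary,
        cluster_diagnosis_table=table,
        config_hash=config.hash(),
        seed=config.seed,
    )


@dataclass
class ValidationBundle:
    summaries: dict  # whitening mode -> cluster x diagnosis counts DataFrame
    comparison: pd.DataFrame  # per mode x diagnosis: chi2, p, V vs discovery
    config_hash: str
    seed: int


def compare_to_discovery(
    validation_summary: pd.DataFrame,
    discovery_table: ContingencyTable,
    clusters=(1, 2, 3, 4),
) -> pd.DataFrame:
    """Per-diagnosis 2 x len(clusters) comparison of validation vs discovery.

    For each diagnosis present in both tables with nonzero counts on
    the compared clusters, builds the two count vectors and reports the
    chi-square p-value and Cramér's V.
    """
    rows = []
    clusters = [c for c in clusters if c in discovery_table.counts.index]
    for diag in validation_summary.columns:
        if diag not in discovery_table.counts.columns:
            continue
        v_counts = np.array(
            [validation_summary.loc[c, diag] if c in validation_summary.index else 0
             for c in clusters]
        )
        d_counts = np.array([discovery_table.counts.loc[c, diag] for c in clusters])
        if v_counts.sum() == 0 or d_counts.sum() == 0:
            continue
        table = np.vstack([v_counts, d_counts])
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            continue
        res = pearson_chi2(table)
        rows.append(
            {
                "diagnosis": diag,
                "chi2": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "cramers_v": cramers_v(table),
            }
        )
    return pd.DataFrame(rows)


def run_validation(
    config: RunConfig,
    model: MultiViewModel,
    view_id: int,
    validation: FCDataset,
    discovery: FCDataset,
    discovery_table: ContingencyTable,
    clusters=(1, 2, 3, 4),
) -> ValidationBundle:
    """Classify a validation dataset under both whitening modes.

    "self" whitens the validation data with its own mean matrix;
    "discovery-reference" whitens it with the discovery mean — the
    deliberately mismatched mode that site bias should corrupt.
    """
    from .classification import classify_dataset

    summaries = {}
    comparisons = []
    discovery_transform = fit_whitening(discovery, reference_label="discovery")
    for mode, whitening in (
        ("self", "self"),
        ("discovery-reference", discovery_transform),
    ):
        _, summary = classify_dataset(
            model, view_id, validation, whitening=whitening, epsilon=config.epsilon
        )
        summaries[mode] = summary
        comp = compare_to_discovery(summary, discovery_table, clusters)
        comp.insert(0, "whitening", mode)
        comparisons.append(comp)
    return ValidationBundle(
        summaries=summaries,
        comparison=pd.concat(comparisons, ignore_index=True),
        config_hash=config.hash(),
        seed=config.seed,
    )


def write_bundle(bundle: DiscoveryBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "discovery.json").write_text(bundle.to_json())
    bundle.association.to_csv(out / "association.tsv", sep="\t", index=False)
    bundle.view_summary.to_csv(out / "view_summary.tsv", sep="\t", index=False)
    bundle.cluster_diagnosis_table.counts.to_csv(
        out / "cluster_diagnosis_counts.tsv", sep="\t"
    )
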