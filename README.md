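# fcmvc — multi-view Wishart mixture clustering of functional connectivity

`fcmvc` is a Python package for unsupervised, cross-disorder analysis
of resting-state functional-connectivity (FC) matrices. Instead of
clustering subjects once on all p(p−1)/2 connectivity values, it
partitions the ROIs themselves into **views** (subnetworks) and finds a
separate subject clustering in each view, so that different brain
subnetworks can carry different groupings of the same subjects — for
example, one subnetwork whose clusters track psychiatric diagnoses
while others track unrelated structure.

It is aimed at researchers working with ROI×ROI Pearson correlation
matrices (one per subject, e.g. 140 ROIs × several hundred subjects)
plus a subject metadata table (diagnosis, age, sex, site).

## Model

For a view v with ROI set of size d_v and a subject i in cluster k,
the scatter submatrix on the view's ROIs is modeled as

    S_i^(v) = ν · R_i[v, v]  ~  Wishart_{d_v}(ν, Σ_{v,k}),
    Σ_{v,k} ~ Inverse-Wishart(ν₀, Ψ₀),    ν₀ = d_v + 2,  Ψ₀ = I,

with Chinese-restaurant-process priors (concentration 1) over both the
ROI partition and the per-view subject partitions, so the numbers of
views and clusters are inferred from the data. Conjugacy gives a
closed-form cluster marginal likelihood; inference is collapsed greedy
MAP search with random restarts, and the final model is chosen by a
stability heuristic (max-ARI pair among the top-scoring restarts).
Before fitting, each matrix is whitened by the inverse square root of
a reference mean correlation matrix — which removes between-subnetwork
correlation on average — and regularized by a small diagonal load
(ε = 0.05). Fitted models classify new subjects by CRP-predictive
scores, including a nonparametric "NEW" outcome for patterns matching
no training cluster. Post-hoc statistics (χ², Cramér's V,
Kruskal–Wallis, edge-wise Cohen's d, classical MDS of cluster centers)
and two baselines (FC-based Gaussian multiple clustering, supervised
pairwise elastic-net classification) round out the pipeline. See
`docs/methods.md` for the full account.

## Worked example

Generate a synthetic dataset with two planted views (4 ROIs each,
carrying 2 and 3 subject clusters) where the second view's clusters
drive diagnosis, then run the discovery pipeline:

```python
from fcmvc.synthetic import SyntheticSpec, generate_dataset
from fcmvc.pipeline import RunConfig, run_discovery

spec = SyntheticSpec(
    n_subjects=120, roi_sizes_per_view=(4, 4), clusters_per_view=(2, 3),
    separation=1.5, dof=200.0, diagnosis_link_view=1, seed=13,
)
dataset, truth = generate_dataset(spec)
bundle = run_discovery(dataset, RunConfig(seed=5, n_init=10))
print(bundle.association)
print(bundle.cluster_diagnosis_table.counts)
```

This prints the per-view association table and the cluster×diagnosis
counts of the selected view:

```
   view       chi2  df             p  n_clusters_tested  bonferroni_significant
0     1    2.04291   2  3.600707e-01                  2                   False
1     2  163.50762   4  2.585589e-34                  3                    True

diagnosis  BD  HC  MDD
cluster
1           3   1   43
2           2  31    5
3          32   3    0
```

View 2 — the planted diagnosis-linked view — is flagged at the
Bonferroni level (p ≈ 2.6×10⁻³⁴) while view 1 is not, and its three
clusters separate the MDD-, HC- and BD-dominated subjects (clusters
are numbered by descending size). The fitted ROI partition matches the
planted one exactly (view ARI 1.0).

A command-line interface mirrors the library:
`fcmvc simulate | validate-data | whiten | fit | classify | run |
baseline-gmm | baseline-supervised`, each accepting `--seed`.

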