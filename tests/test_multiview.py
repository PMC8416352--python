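"""Core model: CRP prior, conjugate marginals, greedy search, selection."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln, logsumexp
from scipy.stats import invwishart
from sklearn.metrics import adjusted_rand_score

from fcmvc.fc_data import FCDataset, regularize_dataset
from fcmvc.multiview import (
    ClusterAssignment,
    ModelHyperparams,
    MultiViewModel,
    ViewPartition,
    WishartClusterStats,
    adjusted_rand_index,
    cluster_log_marginal,
    crp_log_prior,
    derive_seeds,
    fit_multistart,
    greedy_fit,
    model_log_posterior,
    partition_cluster_marginal,
    score_from_scratch,
    select_model,
)
from fcmvc.multiview import WishartBackend
from fcmvc.synthetic import SyntheticSpec, generate_dataset
from fcmvc.whitening import whiten_dataset


def set_partitions(elements):
    """All set partitions, by recursive insertion."""
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestCrpPrior:
    def test_single_block_closed_form(self):
        assert crp_log_prior([3], 1.0, 3) == pytest.approx(np.log(1 / 3))

    def test_all_singletons_closed_form(self):
        assert crp_log_prior([1, 1, 1], 1.0, 3) == pytest.approx(np.log(1 / 6))

    def test_normalizes_over_all_partitions_of_four(self):
        total = sum(
            np.exp(crp_log_prior([len(b) for b in part], 1.0, 4))
            for part in set_partitions([0, 1, 2, 3])
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            crp_log_prior([2, 2], 1.0, 5)


def _wish1_logpdf(s, nu, sigma):
    return (
        0.5 * (nu - 2) * np.log(s)
        - s / (2 * sigma)
        - 0.5 * nu * np.log(2 * sigma)
        - gammaln(nu / 2)
    )


class TestClusterMarginal:
    hyper = ModelHyperparams(dof=10.0)

    def test_empty_cluster_is_zero(self):
        stats = WishartClusterStats(0, np.zeros((3, 3)), 0.0)
        assert cluster_log_marginal(stats, 3, self.hyper) == 0.0
        assert partition_cluster_marginal(stats, 3, self.hyper) == 0.0

    def test_univariate_agrees_with_quadrature(self):
        """d=1: marginal equals the numerically integrated
        Wishart x inverse-Wishart mixture over the scale."""
        scatters = [8.0, 12.5, 9.3]
        nu = self.hyper.dof
        nu0 = self.hyper.nu0(1)
        psi0 = self.hyper.psi0_diag(1)
        a, b = nu0 / 2, psi0 / 2

        def integrand(sigma):
            log_iw = a * np.log(b) - gammaln(a) - (a + 1) * np.log(sigma) - b / sigma
            log_lik = sum(_wish1_logpdf(s, nu, sigma) for s in scatters)
            return np.exp(log_lik + log_iw)

        val, err = integrate.quad(integrand, 0, np.inf, limit=200)
        stats = WishartClusterStats(
            3, np.array([[sum(scatters)]]), float(np.sum(np.log(scatters)))
        )
        assert cluster_log_marginal(stats, 1, self.hyper) == pytest.approx(
            np.log(val), abs=1e-6
        )

    def test_bivariate_agrees_with_monte_carlo(self):
        """d=2, m=2: marginal within 3 SE of a prior-draw MC average."""
        S1 = np.array([[9.0, 3.0], [3.0, 12.0]])
        S2 = np.array([[11.0, -2.0], [-2.0, 8.0]])
        nu = self.hyper.dof
        nu0 = self.hyper.nu0(2)
        psi0 = self.hyper.psi0_diag(2)
        rng = np.random.default_rng(0)
        n_mc = 1_000_000
        draws = invwishart.rvs(df=nu0, scale=psi0 * np.eye(2), size=n_mc,
                               random_state=rng)
        inv = np.linalg.inv(draws)
        _, logdet_sigma = np.linalg.slogdet(draws)
        from scipy.special import multigammaln

        def loglik(S):
            _, ld = np.linalg.slogdet(S)
            tr = np.einsum("nij,ji->n", inv, S)
            return (
                0.5 * (nu - 3) * ld
                - 0.5 * tr
                - nu * np.log(2)
                - 0.5 * nu * logdet_sigma
                - multigammaln(nu / 2, 2)
            )

        ll = loglik(S1) + loglik(S2)
        est = logsumexp(ll) - np.log(n_mc)
        w = np.exp(ll - ll.max())
        se = w.std() / (w.mean() * np.sqrt(n_mc))
        _, ld1 = np.linalg.slogdet(S1)
        _, ld2 = np.linalg.slogdet(S2)
        stats = WishartClusterStats(2, S1 + S2, float(ld1 + ld2))
        impl = cluster_log_marginal(stats, 2, self.hyper)
        assert abs(est - impl) < 3 * se

    def test_predictive_matches_posterior_quadrature(self):
        """Conjugacy: marginal(m+1) - marginal(m) equals the posterior
        predictive density of the added scatter (d=1 quadrature)."""
        scatters = [8.0, 12.5, 9.3]
        s_new = 10.7
        nu = self.hyper.dof
        st_m = WishartClusterStats(
            3, np.array([[sum(scatters)]]), float(np.sum(np.log(scatters)))
        )
        st_m1 = WishartClusterStats(
            4,
            np.array([[sum(scatters) + s_new]]),
            float(np.sum(np.log(scatters)) + np.log(s_new)),
        )
        delta = cluster_log_marginal(st_m1, 1, self.hyper) - cluster_log_marginal(
            st_m, 1, self.hyper
        )
        nu_m = self.hyper.nu0(1) + 3 * nu
        psi_m = self.hyper.psi0_diag(1) + sum(scatters)
        a, b = nu_m / 2, psi_m / 2

        def integrand(sigma):
            log_post = a * np.log(b) - gammaln(a) - (a + 1) * np.log(sigma) - b / sigma
            return np.exp(_wish1_logpdf(s_new, nu, sigma) + log_post)

        val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
        assert delta == pytest.approx(np.log(val), abs=1e-6)


class TestModelPosterior:
    def test_single_view_single_cluster_composition(self, prepared_recovery):
        ds = prepared_recovery
        hyper = ModelHyperparams(dof=200.0)
        part = ViewPartition(np.zeros(ds.p, dtype=int))
        clus = ClusterAssignment((np.zeros(ds.n_subjects, dtype=int),))
        score = score_from_scratch(ds, hyper, part, clus)
        scatters = hyper.dof * ds.stack()
        _, logdets = np.linalg.slogdet(scatters)
        stats = WishartClusterStats(
            ds.n_subjects, scatters.sum(axis=0), float(logdets.sum())
        )
        expected = (
            crp_log_prior([ds.p], 1.0, ds.p)
            + crp_log_prior([ds.n_subjects], 1.0, ds.n_subjects)
            + partition_cluster_marginal(stats, ds.p, hyper)
        )
        assert score == pytest.approx(expected, abs=1e-8)

    def test_cluster_relabeling_leaves_score_unchanged(self, prepared_recovery):
        ds = prepared_recovery
        hyper = ModelHyperparams(dof=200.0)
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, ds.n_subjects)
        part = ViewPartition(np.zeros(ds.p, dtype=int))
        s1 = score_from_scratch(ds, hyper, part, ClusterAssignment((labels,)))
        s2 = score_from_scratch(ds, hyper, part, ClusterAssignment(((2 - labels),)))
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_incremental_stats_match_recomputation(self, prepared_recovery):
        """100 random add/remove moves keep cached cluster statistics and
        marginals in agreement with from-scratch evaluation."""
        ds = prepared_recovery
        hyper = ModelHyperparams(dof=200.0)
        backend = WishartBackend(ds, hyper)
        view = backend.make_view(tuple(range(4)))
        rng = np.random.default_rng(11)
        cluster = view.new_cluster()
        members: list[int] = []
        for _ in range(100):
            if members and rng.random() < 0.4:
                i = members.pop(rng.integers(len(members)))
                cluster.remove(i)
            else:
                candidates = [i for i in range(ds.n_subjects) if i not in members]
                i = candidates[rng.integers(len(candidates))]
                cluster.add(i)
                members.append(i)
            fresh = view.new_cluster()
            for i in members:
                fresh.add(i)
            assert cluster.log_marginal() == pytest.approx(
                fresh.log_marginal(), abs=1e-6
            )

    def test_fitted_score_matches_scratch_recomputation(
        self, prepared_recovery, recovery_model, recovery_hyper
    ):
        m = recovery_model
        assert model_log_posterior(m) == pytest.approx(m.score, abs=1e-6)
        assert score_from_scratch(
            prepared_recovery, recovery_hyper, m.partition, m.clusters
        ) == pytest.approx(m.score, abs=1e-6)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_singletons_vs_one_cluster_is_chance(self):
        assert adjusted_rand_index([0, 1, 2, 3], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_matches_brute_force_pair_counting(self):
        a = [1, 1, 2, 2, 3]
        b = [1, 1, 2, 3, 3]
        n = len(a)
        same_a = np.equal.outer(a, a)
        same_b = np.equal.outer(b, b)
        iu = np.triu_indices(n, 1)
        n11 = int((same_a[iu] & same_b[iu]).sum())
        n00 = int((~same_a[iu] & ~same_b[iu]).sum())
        n10 = int((same_a[iu] & ~same_b[iu]).sum())
        n01 = int((~same_a[iu] & same_b[iu]).sum())
        total = n * (n - 1) / 2
        expected_index = (n11 + n10) * (n11 + n01) / total
        max_index = 0.5 * ((n11 + n10) + (n11 + n01))
        brute = (n11 - expected_index) / (max_index - expected_index)
        assert adjusted_rand_index(a, b) == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 60)
        b = rng.integers(0, 3, 60)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


def _fake_model(view_of_roi, score):
    return MultiViewModel(
        hyper=ModelHyperparams(dof=50.0),
        partition=ViewPartition(np.asarray(view_of_roi)),
        clusters=ClusterAssignment((np.zeros(4, dtype=int),)),
        stats=((WishartClusterStats(0, np.zeros((1, 1)), 0.0),),),
        score=score,
    )


class TestSelectModel:
    def test_identical_pair_dominates(self):
        # five pairwise-distinct partitions, then one exactly repeated pair
        noise = [
            [0, 0, 0, 1, 1, 1],
            [0, 0, 1, 0, 1, 1],
            [0, 1, 0, 1, 0, 1],
            [0, 0, 1, 1, 2, 2],
            [0, 1, 1, 2, 2, 2],
        ]
        models = [_fake_model(p, float(-i)) for i, p in enumerate(noise)]
        twin = [0, 1, 0, 1, 2, 2]
        models.append(_fake_model(twin, -20.0))
        models.append(_fake_model(twin, -30.0))
        report = select_model(models, top_k=10)
        assert report.chosen == 5  # higher-scoring member of the ARI=1 pair

    def test_all_identical_picks_highest_score(self):
        models = [_fake_model([0, 0, 1, 1, 1, 2], -5.0 - i) for i in range(5)]
        report = select_model(models)
        assert report.chosen == 0

    def test_matches_brute_force_of_stated_rule(self):
        rng = np.random.default_rng(7)
        models = [
            _fake_model(rng.integers(0, 3, 6), float(rng.normal()))
            for _ in range(5)
        ]
        report = select_model(models, top_k=5)
        scores = np.array([m.score for m in models])
        order = np.argsort(-scores, kind="stable")
        best_pair, best_ari = None, -np.inf
        for i in range(5):
            for j in range(i + 1, 5):
                ari = adjusted_rand_score(
                    models[order[i]].partition.view_of_roi,
                    models[order[j]].partition.view_of_roi,
                )
                if ari > best_ari:
                    best_ari, best_pair = ari, (order[i], order[j])
        i, j = best_pair
        expected = int(i if scores[i] >= scores[j] else j)
        assert report.chosen == expected

    def test_single_model_trivial(self):
        report = select_model([_fake_model([0, 0, 0, 0, 1, 1], -1.0)])
        assert report.chosen == 0
        assert report.pairwise_ari.shape == (1, 1)


class TestGreedyFit:
    def test_recovers_planted_views_and_clusters(
        self, recovery_model, recovery_data, truth_view_map
    ):
        _, truth = recovery_data
        m = recovery_model
        assert adjusted_rand_index(m.partition.view_of_roi, truth.view_of_roi) == 1.0
        for v in range(m.partition.n_views):
            ari = adjusted_rand_index(
                m.clusters.labels(v), truth.cluster_of_subject[truth_view_map[v]]
            )
            assert ari >= 0.9

    def test_score_trace_monotone(self, recovery_model):
        trace = np.asarray(recovery_model.score_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_final_score_beats_planted_configuration_on_null_data(self):
        spec = SyntheticSpec(
            n_subjects=60, roi_sizes_per_view=(6,), clusters_per_view=(1,),
            separation=0.0, dof=200.0, seed=15,
        )
        ds, truth = generate_dataset(spec)
        prep = regularize_dataset(whiten_dataset(ds)[0], 0.05)
        hyper = ModelHyperparams(dof=200.0)
        model = greedy_fit(prep, hyper, seed=2)
        planted = score_from_scratch(
            prep, hyper,
            ViewPartition(truth.view_of_roi),
            ClusterAssignment(tuple(truth.cluster_of_subject)),
        )
        assert model.score >= planted - 1e-6

    def test_no_cluster_hallucination_without_structure(self):
        """delta=0 data: the largest cluster keeps >= 0.7 of subjects."""
        spec = SyntheticSpec(
            n_subjects=100, roi_sizes_per_view=(6, 6), clusters_per_view=(1, 1),
            separation=0.0, dof=200.0, seed=11,
        )
        ds, _ = generate_dataset(spec)
        prep = regularize_dataset(whiten_dataset(ds)[0], 0.05)
        model = greedy_fit(prep, ModelHyperparams(dof=200.0), seed=5)
        for v in range(model.partition.n_views):
            _, counts = np.unique(model.clusters.labels(v), return_counts=True)
            assert counts.max() / 100 >= 0.7

    def test_exchangeability_under_joint_permutation(
        self, prepared_recovery, recovery_hyper, recovery_model
    ):
        """Shuffling subjects and ROIs consistently changes no score and
        yields the same partitions up to relabeling."""
        ds = prepared_recovery
        rng = np.random.default_rng(23)
        sperm = rng.permutation(ds.n_subjects)
        rperm = rng.permutation(ds.p)
        stacked = ds.stack()[sperm][:, rperm[:, None], rperm[None, :]]
        from fcmvc.fc_data import CorrelationMatrix, RoiSet

        roi = RoiSet(tuple(ds.roi_set.labels[j] for j in rperm))
        mats = tuple(
            CorrelationMatrix(ds.subject_ids[sperm[i]], stacked[i])
            for i in range(ds.n_subjects)
        )
        recs = tuple(ds.metadata[i] for i in sperm)
        shuffled = FCDataset(roi, mats, recs, dof=ds.dof, provenance=ds.provenance)
        m0 = recovery_model
        # evaluate the permuted copy of the fitted configuration
        part = ViewPartition(np.asarray(m0.partition.view_of_roi)[rperm])
        clus = ClusterAssignment(
            tuple(np.asarray(m0.clusters.labels(v))[sperm]
                  for v in range(m0.partition.n_views))
        )
        s = score_from_scratch(shuffled, recovery_hyper, part, clus)
        assert s == pytest.approx(m0.score, abs=1e-8)
        m1 = greedy_fit(shuffled, recovery_hyper, seed=7)
        assert adjusted_rand_index(m1.partition.view_of_roi, part.view_of_roi) == 1.0


class TestMultistart:
    def test_single_init_equals_greedy_with_derived_seed(
        self, prepared_recovery, recovery_hyper
    ):
        models = fit_multistart(prepared_recovery, recovery_hyper, n_init=1, seed=42)
        direct = greedy_fit(
            prepared_recovery, recovery_hyper, seed=derive_seeds(42, 1)[0]
        )
        assert models[0].score == direct.score
        np.testing.assert_array_equal(
            models[0].partition.view_of_roi, direct.partition.view_of_roi
        )

    def test_same_master_seed_reproduces_score_sequence(
        self, prepared_recovery, recovery_hyper
    ):
        a = fit_multistart(prepared_recovery, recovery_hyper, n_init=4, seed=5)
        b = fit_multistart(prepared_recovery, recovery_hyper, n_init=4, seed=5)
        assert [m.score for m in a] == [m.score for m in b]

    def test_best_of_ten_at_least_best_of_one(
        self, prepared_recovery, recovery_hyper
    ):
        ten = fit_multistart(prepared_recovery, recovery_hyper, n_init=10, seed=5)
        one = fit_multistart(prepared_recovery, recovery_hyper, n_init=1, seed=5)
        assert max(m.score for m in ten) >= max(m.score for m in one)
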