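import numpy as np
import pytest

from rcsp.graph import CausalGraph, SemParameters, relatives
from rcsp.simulate import (
    LatentMatrix,
    MappingEfficiencies,
    choose_target,
    measure_counts,
    oracle_rcs,
    perturbseq_design,
    sample_dag,
    sample_sem,
    sample_weights,
    sign_agreement_experiment,
    simulate_bulk,
    simulate_latent,
    simulate_perturbseq,
    softplus,
)


class TestSampleDag:
    def test_zero_probability_gives_empty_graph(self):
        assert sample_dag(2, 0.0, seed=0).edges == frozenset()

    def test_mean_neighborhood_size_calibrated(self):
        # Bernoulli(2/(p-1)) on the upper triangle -> expected degree ~ 2
        degrees = []
        for seed in range(5):
            g = sample_dag(600, 2 / 598, seed=seed)
            degrees.append(2 * len(g.edges) / 600)
        assert abs(np.mean(degrees) - 2.0) < 0.15

    def test_edge_count_within_binomial_bounds(self):
        n, prob = 600, 2 / 598
        n_pairs = n * (n - 1) // 2
        expected = n_pairs * prob
        sd = np.sqrt(n_pairs * prob * (1 - prob))
        count = len(sample_dag(n, prob, seed=11).edges)
        assert abs(count - expected) < 4 * sd

    def test_deterministic_given_seed(self):
        assert sample_dag(50, 0.1, seed=7).edges == sample_dag(50, 0.1, seed=7).edges


class TestSampleWeights:
    def test_empty_graph_zero_weights(self):
        sem = sample_weights(CausalGraph(4, frozenset()), seed=0)
        assert not sem.weights.any()

    def test_magnitudes_in_two_interval_support(self):
        g = sample_dag(40, 0.2, seed=1)
        sem = sample_weights(g, seed=2)
        mags = np.abs(sem.weights[sem.weights != 0])
        assert mags.size and np.all((mags >= 0.25) & (mags <= 1.0))
        assert np.all(sem.error_scale == 0.5)

    def test_bit_identical_on_rerun(self):
        g = sample_dag(20, 0.2, seed=3)
        np.testing.assert_array_equal(
            sample_weights(g, seed=4).weights, sample_weights(g, seed=4).weights
        )


class TestChooseTarget:
    def test_chain_target_is_sink(self):
        g = CausalGraph(3, frozenset({(0, 1), (1, 2)}))
        assert choose_target(g, seed=0) == 2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            choose_target(CausalGraph(3, frozenset()), seed=0)

    def test_star_target_uniform_over_leaves(self):
        g = CausalGraph(4, frozenset({(0, 1), (0, 2), (0, 3)}))
        rng = np.random.default_rng(5)
        picks = np.array([choose_target(g, rng) for _ in range(3000)])
        freqs = np.bincount(picks, minlength=4)[1:] / 3000
        assert np.all(np.abs(freqs - 1 / 3) < 0.03)


class TestSimulateLatent:
    def test_no_edges_values_equal_errors(self):
        sem = sample_weights(CausalGraph(3, frozenset()), seed=0)
        lat = simulate_latent(sem, 5, seed=1)
        np.testing.assert_array_equal(lat.values, lat.errors)

    def test_hand_propagation_on_chain(self, chain_sem):
        lat = simulate_latent(chain_sem, 1, seed=2)
        e = lat.errors[0]
        np.testing.assert_allclose(
            lat.values[0], [e[0], 0.5 * e[0] + e[1], 0.5 * e[0] + e[1] + e[2]]
        )

    def test_knockdown_offset_propagates_downstream(self, chain_sem):
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        lat = simulate_latent(chain_sem, 1, seed=rng_a)
        kd = simulate_latent(chain_sem, 1, intervention=0, seed=rng_b)
        np.testing.assert_allclose(kd.values[0, 0], lat.values[0, 0] - 2.0)
        np.testing.assert_allclose(kd.values[0, 1], lat.values[0, 1] - 2.0 * 0.5)

    def test_softplus_variant_is_positive_and_nonlinear(self, chain_sem):
        lat = simulate_latent(chain_sem, 200, seed=4, variant="softplus")
        genes = [0, 1]
        assert np.all(lat.values[:, genes] > 0)
        # child uses the softplus-transformed parent value
        expect = 0.5 * softplus(lat.errors[:, 0]) + lat.errors[:, 1]
        np.testing.assert_allclose(lat.values[:, 1], softplus(expect))

    def test_interventions_shift_descendant_means(self):
        from scipy import stats

        sem = sample_sem(12, 0.3, seed=6)
        genes = list(sem.gene_indices())
        src = genes[0]
        ctrl = simulate_latent(sem, 10_000, seed=7)
        kd = simulate_latent(sem, 10_000, intervention=src, seed=8)
        m = np.linalg.inv(np.eye(sem.n_vertices) - sem.weights)
        for dst in relatives(sem.graph, src, "descendants"):
            if abs(m[src, dst]) < 1e-12:
                continue
            p = stats.ttest_ind(ctrl.values[:, dst], kd.values[:, dst]).pvalue
            assert p < 0.001


class TestMeasureCounts:
    def test_softplus_zero_rate(self):
        pi = MappingEfficiencies(np.ones((1, 1)))
        latent = np.zeros((100_000, 1))
        counts = measure_counts(latent, pi, np.zeros(100_000, dtype=int), seed=9)
        rate = np.log(2.0)
        assert abs(counts.mean() - rate) < 3 * np.sqrt(rate / 100_000)

    def test_conditional_dispersion_is_poisson(self):
        pi = MappingEfficiencies(np.full((1, 1), 25.0))
        latent = np.full((100_000, 1), 0.8)
        counts = measure_counts(latent, pi, np.zeros(100_000, dtype=int), seed=10)
        ratio = counts.var() / counts.mean()
        assert 0.97 <= ratio <= 1.03

    def test_rate_vanishes_for_very_negative_latent(self):
        pi = MappingEfficiencies(np.ones((1, 1)))
        latent = np.full((1000, 1), -40.0)
        counts = measure_counts(latent, pi, np.zeros(1000, dtype=int), seed=11)
        assert not counts.any()

    def test_nonpositive_pi_rejected(self):
        with pytest.raises(ValueError):
            MappingEfficiencies(np.zeros((1, 1)))


class TestSimulateBulk:
    def test_shapes_and_defaults(self, random_sem):
        bulk, latent = simulate_bulk(random_sem, 50, seed=12)
        assert bulk.counts.shape == (50, 20)
        assert latent.values.shape == (50, 21)
        np.testing.assert_array_equal(
            bulk.y, latent.values[:, random_sem.target_index]
        )

    def test_identical_given_seed(self, random_sem):
        a, _ = simulate_bulk(random_sem, 30, seed=13)
        b, _ = simulate_bulk(random_sem, 30, seed=13)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.y, b.y)


class TestPerturbseq:
    def test_full_protocol_design_cell_count(self):
        design = perturbseq_design(2500, cells_per_condition=200)
        assert design["n_conditions"] == 2501
        assert design["total_cells"] == 500_200

    def test_control_only_when_no_conditions(self, random_sem):
        data = simulate_perturbseq(random_sem, 20, 4, seed=14, conditions=[])
        assert data.n_cells == 20
        assert np.all(data.perturbation == -1)

    def test_knockdown_lowers_own_mean_count(self, chain_sem):
        data = simulate_perturbseq(chain_sem, 200, 1, seed=15)
        ctrl = data.counts[data.perturbation == -1]
        kd0 = data.counts[data.perturbation == 0]
        assert kd0[:, 0].mean() < ctrl[:, 0].mean()

    def test_batches_balanced_within_conditions(self, random_sem):
        data = simulate_perturbseq(random_sem, 30, 3, seed=16, conditions=[0, 1])
        for label in (-1, 0, 1):
            counts = np.bincount(data.batch[data.perturbation == label], minlength=3)
            assert np.all(counts == 10)


class TestOracleRcs:
    def test_hand_gaussian_conditioning(self, chain_sem):
        lat = LatentMatrix(
            values=np.array([[0.6, 0.9, 1.0]]), errors=np.array([[0.6, 0.6, 0.1]])
        )
        truth = oracle_rcs(chain_sem, lat)
        # Gamma_2 = x2 - 0.5*x1 ; Gamma_1 = tau_1 * e_1 = 0.5*0.6
        np.testing.assert_allclose(truth.gamma_true[0], [0.3, 0.6])
        np.testing.assert_allclose(truth.phi_true, np.abs(truth.gamma_true))

    def test_non_ancestor_columns_exactly_zero(self):
        sem = sample_sem(15, 0.25, seed=17)
        lat = simulate_latent(sem, 40, seed=18)
        truth = oracle_rcs(sem, lat)
        anc = relatives(sem.graph, sem.target_index, "ancestors")
        for pos, g in enumerate(sem.gene_indices()):
            if g not in anc:
                assert not truth.gamma_true[:, pos].any()

    def test_linear_in_deviation_from_conditional_mean(self, chain_sem):
        lat1 = LatentMatrix(
            values=np.array([[0.6, 0.9, 0.0]]), errors=np.array([[0.6, 0.6, 0.0]])
        )
        # doubling both deviations doubles Gamma
        lat2 = LatentMatrix(
            values=np.array([[1.2, 1.8, 0.0]]), errors=np.array([[1.2, 1.2, 0.0]])
        )
        g1 = oracle_rcs(chain_sem, lat1).gamma_true
        g2 = oracle_rcs(chain_sem, lat2).gamma_true
        np.testing.assert_allclose(g2, 2 * g1)

    def test_matches_nearest_neighbour_monte_carlo(self):
        """Independent brute-force check: conditional means by local-linear
        k-NN smoothing of a large simulant."""

        def local_linear(pts, y, q, k):
            d = np.sum((pts - q) ** 2, axis=1)
            idx = np.argpartition(d, k)[:k]
            design = np.column_stack([np.ones(k), pts[idx] - q])
            coef, *_ = np.linalg.lstsq(design, y[idx], rcond=None)
            return coef[0]

        sem = sample_sem(6, 0.5, seed=19)
        lat = simulate_latent(sem, 6, seed=20)
        truth = oracle_rcs(sem, lat)
        sim = simulate_latent(sem, 400_000, seed=21)
        y_sim = sim.values[:, sem.target_index]
        genes = list(sem.gene_indices())
        anc_y = relatives(sem.graph, sem.target_index, "ancestors")
        checked = 0
        for pos, g in enumerate(genes):
            if g not in anc_y:
                continue
            pa = sorted(sem.graph.parents(int(g)))
            scale = np.std(sim.values[:, pa + [g]], axis=0)
            pts1 = sim.values[:, pa + [g]] / scale
            for j in range(lat.values.shape[0]):
                q = lat.values[j, pa + [g]] / scale
                e1 = local_linear(pts1, y_sim, q, 4000)
                if pa:
                    e0 = local_linear(pts1[:, :-1], y_sim, q[:-1], 4000)
                else:
                    e0 = y_sim.mean()
                assert abs((e1 - e0) - truth.gamma_true[j, pos]) < 0.03
                checked += 1
        assert checked >= 6


class TestSignAgreement:
    def test_chain_graph_agrees_everywhere(self, chain_sem):
        # single directed path: Gamma and tau*E share the same path product
        assert sign_agreement_experiment(chain_sem, 100, seed=22, variant="linear") == 1.0

    def test_single_gene_sem(self):
        g = CausalGraph(2, frozenset({(0, 1)}))
        w = np.zeros((2, 2))
        w[0, 1] = 0.8
        sem = SemParameters(g, w, np.full(2, 0.5), target_index=1)
        assert sign_agreement_experiment(sem, 50, seed=23, variant="linear") == 1.0

    def test_no_eligible_genes_rejected(self):
        g = CausalGraph(3, frozenset({(1, 2)}))
        w = np.zeros((3, 3))
        w[1, 2] = 0.5
        sem = SemParameters(g, w, np.full(3, 0.5), target_index=2)
        # gene 0 is disconnected; gene 1 is eligible, so this must succeed
        assert sign_agreement_experiment(sem, 30, seed=24, variant="linear") == 1.0

    def test_softplus_protocol_agreement_high(self):
        sem = sample_sem(31, 2 / 29, seed=25)
        frac = sign_agreement_experiment(
            sem, 60, seed=26, variant="softplus", n_mc=300
        )
        assert 0.9 <= frac <= 1.0

    def test_forward_mc_oracle_exact_in_linear_limit(self):
        """With common random numbers the forward Monte-Carlo oracle's
        noise cancels exactly when the SEM is linear: it must reproduce
        the closed form to machine precision."""
        from rcsp.simulate import _forward_mc_effect, oracle_rcs

        sem = sample_sem(13, 0.25, seed=27)
        lat = simulate_latent(sem, 20, seed=28, variant="linear")
        truth = oracle_rcs(sem, lat)
        rng = np.random.default_rng(29)
        for pos, g in enumerate(sem.gene_indices()):
            if truth.tau[pos] == 0.0:
                continue
            gm = _forward_mc_effect(
                sem, lat, int(g), 200, rng, "ancestors", variant="linear"
            )
            np.testing.assert_allclose(gm, truth.gamma_true[:, pos], atol=1e-10)
            up = _forward_mc_effect(
                sem, lat, int(g), 200, rng, "root", variant="linear"
            )
            np.testing.assert_allclose(
                up, truth.tau[pos] * lat.errors[:, g], atol=1e-10
            )


class TestDepthRobustness:
    def test_latent_predictivity_gap_shrinks_with_depth(self):
        """Counts become as predictive of Y as the latents when the mapping
        efficiency (sequencing depth proxy) grows."""
        gaps = {scale: [] for scale in (1.0, 10.0, 100.0)}
        for seed in range(4):
            sem = sample_sem(11, 0.25, seed=30 + seed)
            genes = sem.gene_indices()
            for scale in gaps:
                bulk, lat = simulate_bulk(sem, 300, seed=50 + seed, pi_scale=scale)
                y = bulk.y
                latent_feats = lat.values[:, genes]
                r2 = []
                for feats in (latent_feats, np.asarray(bulk.counts, dtype=float)):
                    z = (feats - feats.mean(0)) / np.maximum(feats.std(0), 1e-12)
                    design = np.column_stack([np.ones(len(y)), z])
                    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                    r2.append(1 - np.var(y - design @ coef) / np.var(y))
                gaps[scale].append(r2[0] - r2[1])
        medians = [np.median(gaps[s]) for s in (1.0, 10.0, 100.0)]
        assert medians[0] >= medians[1] >= medians[2]
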