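import numpy as np
import pytest

from rcsp.containers import PerturbSeqData
from rcsp.discovery import surrogate_ancestors, surrogate_descendants, two_sided_ttest
from rcsp.graph import relatives
from rcsp.simulate import sample_sem, simulate_perturbseq


class TestWelchTTest:
    def test_identical_groups(self):
        stat, p = two_sided_ttest([1, 2, 3], [1, 2, 3])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_welch_example(self):
        # means 2 vs 4, each variance 1, n=3: t = -2 / sqrt(2/3), df = 4
        stat, p = two_sided_ttest([1, 2, 3], [3, 4, 5])
        assert stat == pytest.approx(-2.4495, abs=1e-4)
        assert p == pytest.approx(0.0705, abs=2e-3)

    def test_p_decreases_with_sample_size(self):
        rng = np.random.default_rng(0)
        pvals = []
        for n in (10, 40, 160):
            a = rng.normal(0, 1, n)
            b = rng.normal(1, 1, n)
            pvals.append(two_sided_ttest(a, b)[1])
        assert pvals[0] > pvals[1] > pvals[2]

    def test_degenerate_variance_reported_nonsignificant(self):
        with pytest.warns(UserWarning):
            stat, p = two_sided_ttest([1, 1, 1], [2, 2, 2])
        assert p == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            two_sided_ttest([1.0], [1, 2, 3])


def perturb_from_counts(ctrl, blocks):
    """Assemble a PerturbSeqData from a control block and per-gene blocks."""
    counts = np.vstack([ctrl] + blocks)
    labels = np.concatenate(
        [np.full(len(ctrl), -1)] + [np.full(len(b), i) for i, b in enumerate(blocks)]
    )
    return PerturbSeqData(
        counts=counts,
        perturbation=labels,
        batch=np.zeros(len(counts), dtype=int),
        gene_names=[f"G{i}" for i in range(counts.shape[1])],
    )


class TestSurrogateDescendants:
    def test_type_one_error_matches_alpha_under_null(self):
        # all conditions identical Poisson noise; correction off
        rng = np.random.default_rng(1)
        p, cells = 40, 100
        ctrl = rng.poisson(5.0, size=(cells, p))
        blocks = [rng.poisson(5.0, size=(cells, p)) for _ in range(p)]
        data = perturb_from_counts(ctrl, blocks)
        sets = surrogate_descendants(data, alpha=0.05, correction="none")
        fpr = np.nanmean(sets.pvalues <= 0.05)
        assert abs(fpr - 0.05) < 0.01  # 1600 tests

    def test_chain_recovers_descendant_closure(self):
        from rcsp.graph import CausalGraph, SemParameters

        g = CausalGraph(4, frozenset({(0, 1), (1, 2), (2, 3)}))
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 2] = 1.0
        w[2, 3] = 1.0
        sem = SemParameters(g, w, np.full(4, 0.5), target_index=3)
        data = simulate_perturbseq(sem, 200, 1, seed=2)
        sets = surrogate_descendants(data, alpha=0.05, correction="bh")
        assert sets.descendants[0] >= {0, 1, 2}

    def test_sink_gene_affects_only_itself(self):
        from rcsp.graph import CausalGraph, SemParameters

        g = CausalGraph(4, frozenset({(0, 1), (0, 3), (1, 3)}))
        w = np.zeros((4, 4))
        w[0, 1] = w[0, 3] = w[1, 3] = 0.9
        sem = SemParameters(g, w, np.full(4, 0.5), target_index=3)
        # gene 2 is disconnected: perturbing it moves nothing else
        data = simulate_perturbseq(sem, 200, 1, seed=3)
        sets = surrogate_descendants(data, alpha=0.05, correction="bh")
        assert sets.descendants[2] <= {2}

    def test_no_control_cells_rejected(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=(10, 3))
        with pytest.raises(ValueError):
            PerturbSeqData(
                counts=counts,
                perturbation=np.zeros(10, dtype=int),
                batch=np.zeros(10, dtype=int),
                gene_names=["a", "b", "c"],
            )

    def test_monotone_in_alpha_without_correction(self):
        rng = np.random.default_rng(5)
        p, cells = 15, 60
        ctrl = rng.poisson(4.0, size=(cells, p))
        blocks = [rng.poisson(4.0 + (i % 3), size=(cells, p)) for i in range(p)]
        data = perturb_from_counts(ctrl, blocks)
        small = surrogate_ancestors(surrogate_descendants(data, 0.01, "none"))
        large = surrogate_ancestors(surrogate_descendants(data, 0.10, "none"))
        for i in range(p):
            assert small.sa(i) <= large.sa(i)


class TestSurrogateAncestors:
    def test_set_inversion_by_hand(self):
        from rcsp.discovery import SurrogateSets

        sd = SurrogateSets(
            n_genes=3,
            descendants={0: {0, 1, 2}, 1: {1, 2}, 2: {2}},
            pvalues=np.zeros((3, 3)),
            alpha=0.05,
            correction="none",
        )
        sa = surrogate_ancestors(sd)
        assert sa.sa(2) == {0, 1}
        assert sa.sa(1) == {0}
        assert sa.sa(0) == set()

    def test_singleton_descendants_give_empty_ancestors(self):
        from rcsp.discovery import SurrogateSets

        sd = SurrogateSets(
            n_genes=3,
            descendants={i: {i} for i in range(3)},
            pvalues=np.zeros((3, 3)),
            alpha=0.05,
            correction="none",
        )
        sa = surrogate_ancestors(sd)
        assert all(sa.sa(i) == set() for i in range(3))

    def test_sd_sa_round_trip(self):
        from rcsp.discovery import SurrogateSets

        rng = np.random.default_rng(6)
        desc = {i: {i} | set(rng.choice(8, rng.integers(0, 4), replace=False).tolist()) for i in range(8)}
        sd = SurrogateSets(
            n_genes=8, descendants=desc, pvalues=np.zeros((8, 8)), alpha=0.05, correction="none"
        )
        sa = surrogate_ancestors(sd)
        for i in range(8):
            for j in sa.sa(i):
                assert i in desc[j]
        for j, dset in desc.items():
            for i in dset:
                if i != j:
                    assert j in sa.sa(i)


class TestRecallOnSimulatedScreens:
    def test_recall_of_strong_true_descendants_random_dags(self):
        """Recall >= 0.9 at per-test level alpha for descendant pairs whose
        total latent effect is at least 0.25, at 200 cells per condition."""
        hits = total = 0
        fp = fp_total = 0
        for seed in range(3):
            sem = sample_sem(51, 2 / 49, seed=100 + seed)
            m = np.linalg.inv(np.eye(sem.n_vertices) - sem.weights)
            data = simulate_perturbseq(sem, 200, 10, seed=200 + seed)
            sets = surrogate_descendants(data, alpha=0.05, correction="none")
            genes = list(sem.gene_indices())
            pos = {g: k for k, g in enumerate(genes)}
            for gi in genes:
                desc = relatives(sem.graph, gi, "descendants")
                for gk in genes:
                    if gk in desc and abs(m[gi, gk]) >= 0.25:
                        total += 1
                        hits += pos[gk] in sets.descendants[pos[gi]]
                    elif gk not in desc and gk != gi:
                        fp_total += 1
                        fp += pos[gk] in sets.descendants[pos[gi]]
        assert total >= 50
        assert hits / total >= 0.9
        assert fp / fp_total <= 0.08  # close to the nominal per-test alpha

    def test_recall_on_unit_weight_chain_with_bh(self):
        """On a chain with unit-magnitude weights every path product is 1;
        recall of the full reachability closure stays >= 0.9 even under
        the conservative BH correction."""
        from rcsp.graph import CausalGraph, SemParameters

        rng = np.random.default_rng(0)
        n = 51
        edges = frozenset((i, i + 1) for i in range(n - 1))
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = rng.choice([-1.0, 1.0])
        sem = SemParameters(
            CausalGraph(n, edges), w, np.full(n, 0.5), target_index=n - 1
        )
        data = simulate_perturbseq(sem, 200, 10, seed=9)
        sets = surrogate_descendants(data, alpha=0.05, correction="bh")
        hits = total = 0
        for gi in range(n - 1):
            for gk in range(gi, n - 1):
                total += 1
                hits += gk in sets.descendants[gi]
        assert hits / total >= 0.9
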