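"""Codon model: generator structure, transition matrices, pruning
likelihood vs exhaustive enumeration, fitting and reconstruction."""

import numpy as np
import pytest
from scipy.linalg import expm

from tswitch.codon_model import (
    CodonModelParams,
    MixtureModel,
    PhyloTree,
    build_rate_matrix,
    discretize_omega,
    encode_alignment,
    f3x4_frequencies,
    fit_parameters,
    pruning_loglik,
    reconstruct_ancestors,
)
from tswitch.codon_model import _NONSYN, _SINGLE, _TRANSITION
from tswitch.core_seq import SENSE_CODONS, CodonAlignment, NucSequence
from tswitch.simulator import simulate_alignment

from conftest import random_codon_seq


def exhaustive_quartet_loglik(tree_lengths, codes, model):
    """Oracle: marginalize ancestors by explicit summation, P(t) by expm.

    Topology ((A,B)u,(C,D)v)root with branch lengths (tA,tB,tu,tC,tD,tv).
    """
    tA, tB, tu, tC, tD, tv = tree_lengths
    n_sites = codes.shape[1]
    site_liks = np.zeros((model.n_categories, n_sites))
    for c, Q in enumerate(model.Qs):
        PA, PB, PU = expm(Q * tA), expm(Q * tB), expm(Q * tu)
        PC, PD, PV = expm(Q * tC), expm(Q * tD), expm(Q * tv)
        for s in range(n_sites):
            a, b, cc, d = codes[:, s]
            lik = 0.0
            for r in range(61):
                pu = sum(PU[r, u] * PA[u, a] * PB[u, b] for u in range(61))
                pv = sum(PV[r, v] * PC[v, cc] * PD[v, d] for v in range(61))
                lik += model.pi[r] * pu * pv
            site_liks[c, s] = lik
    return float(np.log(site_liks.mean(axis=0)).sum())


class TestRateMatrix:
    def test_omega_zero_silences_nonsynonymous_rates(self, small_params):
        Q = build_rate_matrix(small_params, 0.0, scale=False)
        assert np.all(Q[_NONSYN] == 0)

    def test_uniform_symmetric_case(self):
        p = CodonModelParams(kappa=1.0, omega_shape=1.0, omega_rate=1.0)
        Q = build_rate_matrix(p, 1.0, scale=False)
        vals = Q[_SINGLE]
        assert np.allclose(vals, vals[0])

    def test_detailed_balance(self, small_params):
        pi = small_params.codon_freqs
        Q = build_rate_matrix(small_params, 0.7)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rows_sum_to_zero_and_mean_rate_one(self, small_params):
        Q = build_rate_matrix(small_params, 0.5)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert np.isclose(-np.dot(small_params.codon_freqs, np.diag(Q)), 1.0)

    def test_negative_omega_rejected(self, small_params):
        with pytest.raises(ValueError):
            build_rate_matrix(small_params, -0.1)

    def test_transition_classification_spotchecks(self):
        i, j = SENSE_CODONS.index("AAA"), SENSE_CODONS.index("AAG")
        assert _TRANSITION[i, j]  # A<->G
        k = SENSE_CODONS.index("AAC")
        assert _SINGLE[i, k] and not _TRANSITION[i, k]


class TestTransitionMatrices:
    @pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 5.0, 50.0])
    def test_stochastic_rows(self, small_params, t):
        m = MixtureModel(small_params)
        P = m.transition_matrix(t, 1)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_pi_is_stationary(self, small_params):
        m = MixtureModel(small_params)
        P = m.transition_matrix(0.8, 0)
        assert np.allclose(small_params.codon_freqs @ P, small_params.codon_freqs, atol=1e-8)

    def test_matches_expm(self, small_params):
        m = MixtureModel(small_params)
        for c in range(m.n_categories):
            assert np.allclose(
                m.transition_matrix(0.3, c), expm(m.Qs[c] * 0.3), atol=1e-9
            )


def test_omega_discretization_means_average_to_gamma_mean():
    for shape, rate, k in [(0.5, 2.0, 8), (2.0, 1.0, 4), (1.0, 3.0, 1)]:
        means = discretize_omega(shape, rate, k)
        assert len(means) == k
        assert np.all(np.diff(means) >= 0)
        assert np.isclose(means.mean(), shape / rate, rtol=1e-6)


class TestPruning:
    def test_zero_branch_identical_sequences_closed_form(self, small_params, rng):
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        seq = random_codon_seq(rng, 12)
        aln = CodonAlignment([NucSequence("A", seq), NucSequence("B", seq)])
        ll = pruning_loglik(tree, aln, small_params)
        idx = [SENSE_CODONS.index(seq[3 * i : 3 * i + 3]) for i in range(12)]
        assert np.isclose(ll, np.log(small_params.codon_freqs[idx]).sum())

    def test_matches_exhaustive_enumeration_on_quartet(
        self, small_params, quartet_tree, rng
    ):
        aln = CodonAlignment(
            [NucSequence(t, random_codon_seq(rng, 10)) for t in "ABCD"]
        )
        ll = pruning_loglik(quartet_tree, aln, small_params)
        codes, _ = encode_alignment(aln, ["A", "B", "C", "D"])
        oracle = exhaustive_quartet_loglik(
            (0.1, 0.2, 0.05, 0.3, 0.15, 0.08), codes, MixtureModel(small_params)
        )
        assert abs(ll - oracle) < 1e-8

    def test_invariant_to_root_position_on_branch(self, small_params, rng):
        # same unrooted tree, root slid along the internal branch
        aln = CodonAlignment(
            [NucSequence(t, random_codon_seq(rng, 8)) for t in "ABCD"]
        )
        t1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.10,(C:0.3,D:0.15):0.02);")
        t2 = PhyloTree.from_newick("((A:0.1,B:0.2):0.03,(C:0.3,D:0.15):0.09);")
        assert np.isclose(
            pruning_loglik(t1, aln, small_params),
            pruning_loglik(t2, aln, small_params),
            atol=1e-9,
        )

    def test_missing_data_partial_likelihood(self, small_params, rng):
        # an all-missing row contributes nothing: loglik equals leaf-free marginal
        seq = random_codon_seq(rng, 6)
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        aln1 = CodonAlignment(
            [NucSequence("A", seq), NucSequence("B", "-" * len(seq))]
        )
        idx = [SENSE_CODONS.index(seq[3 * i : 3 * i + 3]) for i in range(6)]
        assert np.isclose(
            pruning_loglik(tree, aln1, small_params),
            np.log(small_params.codon_freqs[idx]).sum(),
            atol=1e-9,
        )


class TestFit:
    def test_loglik_never_decreases_from_init(self, rng):
        tree = PhyloTree.from_newick("((A:0.05,B:0.08):0.02,(C:0.06,D:0.04):0.03);")
        params = CodonModelParams(kappa=3.0, omega_shape=0.6, omega_rate=2.0, n_categories=2)
        aln = simulate_alignment(tree, params, root_length=80, seed=5)
        init = CodonModelParams(n_categories=2)
        fit = fit_parameters(tree, aln, n_categories=2, maxiter=15)
        assert fit.loglik >= pruning_loglik(tree, aln, init) - 1e-6

    def test_recovers_kappa_from_simulation(self):
        # data simulated under kappa=2, mean omega 0.3
        rng = np.random.default_rng(12)
        from tswitch.synthetic_data import random_tree

        tree = random_tree(50, rng, mean_branch=0.06)
        truth = CodonModelParams(
            kappa=2.0, omega_shape=1.2, omega_rate=4.0, n_categories=4
        )
        aln = simulate_alignment(tree, truth, root_length=500, seed=13)
        fit = fit_parameters(tree, aln, n_categories=4, maxiter=40)
        assert abs(fit.params.kappa - 2.0) / 2.0 < 0.2

    def test_identical_sequences_drive_lengths_to_lower_bound(self, rng):
        seq = random_codon_seq(rng, 30)
        tree = PhyloTree.from_newick("(A:0.2,B:0.3);")
        aln = CodonAlignment([NucSequence("A", seq), NucSequence("B", seq)])
        fit = fit_parameters(
            tree, aln, optimize_branch_lengths=True, n_categories=2, maxiter=40
        )
        assert fit.tree.lengths[fit.tree.leaf_index["A"]] < 1e-3


class TestReconstruction:
    def test_unanimous_star_tree(self, small_params):
        tree = PhyloTree.from_newick("(A:0.02,B:0.02,C:0.02);")
        aln = CodonAlignment([NucSequence(t, "ATG") for t in "ABC"])
        rec = reconstruct_ancestors(tree, aln, small_params)
        root_label = tree.labels[tree.root]
        assert rec.sequences[root_label] == "ATG"
        assert rec.max_posterior[root_label][0] > 0.99

    def test_matches_exhaustive_posterior_on_quartet(
        self, small_params, quartet_tree, rng
    ):
        aln = CodonAlignment(
            [NucSequence(t, random_codon_seq(rng, 10)) for t in "ABCD"]
        )
        rec = reconstruct_ancestors(
            quartet_tree, aln, small_params, include_posteriors=True
        )
        codes, _ = encode_alignment(aln, ["A", "B", "C", "D"])
        model = MixtureModel(small_params)
        # oracle posterior at the AB ancestor (node u) by explicit summation
        post = np.zeros((10, 61))
        for c, Q in enumerate(model.Qs):
            PA, PB, PU = expm(Q * 0.1), expm(Q * 0.2), expm(Q * 0.05)
            PC, PD, PV = expm(Q * 0.3), expm(Q * 0.15), expm(Q * 0.08)
            for s in range(10):
                a, b, cc, d = codes[:, s]
                pv = np.array(
                    [
                        sum(PV[r, v] * PC[v, cc] * PD[v, d] for v in range(61))
                        for r in range(61)
                    ]
                )
                for u in range(61):
                    joint = PA[u, a] * PB[u, b] * np.dot(
                        model.pi, PU[:, u] * pv
                    )
                    post[s, u] += joint
        post /= post.sum(axis=1, keepdims=True)
        ab_parent = quartet_tree.parent_label("A")  # node with A, B as children
        got = rec.posteriors[ab_parent]
        assert np.allclose(got, post, atol=1e-8)
        assert np.array_equal(got.argmax(axis=1), post.argmax(axis=1))

    def test_all_gap_column_reported_as_gap(self, small_params):
        tree = PhyloTree.from_newick("(A:0.05,B:0.05);")
        aln = CodonAlignment(
            [NucSequence("A", "---ATG"), NucSequence("B", "---ATG")]
        )
        rec = reconstruct_ancestors(tree, aln, small_params)
        assert rec.sequences[tree.labels[tree.root]] == "---ATG"

    def test_recovers_true_ancestors_on_short_branches(self):
        from tswitch.synthetic_data import default_params, random_tree

        rng = np.random.default_rng(30)
        tree = random_tree(12, rng, mean_branch=0.04, max_branch=0.1)
        params = default_params(n_categories=4)
        aln, truth = simulate_alignment(
            tree, params, root_length=150, seed=31, return_ancestors=True
        )
        rec = reconstruct_ancestors(tree, aln, params)
        total = correct = 0
        for label, true_seq in truth.items():
            got = rec.sequences[label]
            for k in range(0, len(true_seq), 3):
                total += 1
                correct += got[k : k + 3] == true_seq[k : k + 3]
        assert correct / total >= 0.95


class TestTreeUtilities:
    def test_patristic_and_closest_leaf(self):
        t = PhyloTree.from_newick("((A:0.1,B:0.2):0.3,C:0.9);", outgroup="C")
        assert np.isclose(t.patristic_distance("A", "B"), 0.3)
        assert np.isclose(t.patristic_distance("A", "C"), 1.3)
        assert t.closest_leaf("A", exclude={"C"}) == "B"

    def test_prune_preserves_path_lengths(self):
        t = PhyloTree.from_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.6);")
        p = t.prune_to(["A", "C", "D"])
        assert set(p.leaf_labels) == {"A", "C", "D"}
        assert np.isclose(
            p.patristic_distance("C", "D"), t.patristic_distance("C", "D")
        )

    def test_newick_roundtrip(self):
        t = PhyloTree.from_newick("((A:0.1,B:0.2):0.3,C_1:0.9);")
        back = PhyloTree.from_newick(t.to_newick())
        assert set(back.leaf_labels) == {"A", "B", "C_1"}
        assert np.isclose(back.patristic_distance("A", "C_1"), 1.3)
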