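"""Simulation along the tree and the conditional null-set loop."""

import numpy as np
import pytest
from scipy.stats import chisquare

from tswitch.codon_model import MixtureModel, PhyloTree, encode_alignment
from tswitch.core_seq import CodonAlignment, NucSequence
from tswitch.simulator import (
    NullSetError,
    build_null_set,
    count_bin_irs,
    simulate_alignment,
)

from conftest import random_codon_seq


class TestSimulate:
    def test_zero_branch_lengths_copy_the_root(self, small_params, rng):
        tree = PhyloTree.from_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        root = random_codon_seq(rng, 40)
        aln = simulate_alignment(tree, small_params, root_sequence=root, seed=1)
        for row in aln:
            assert row.residues == root

    def test_same_seed_is_byte_identical(self, small_params):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        a1 = simulate_alignment(tree, small_params, root_length=50, seed=7)
        a2 = simulate_alignment(tree, small_params, root_length=50, seed=7)
        assert [(r.id, r.residues) for r in a1] == [(r.id, r.residues) for r in a2]

    def test_long_branch_reaches_stationarity(self, small_params):
        # chi-square goodness of fit of leaf codon frequencies against pi
        tree = PhyloTree.from_newick("(A:50.0,B:0.0);")
        aln = simulate_alignment(tree, small_params, root_length=10000, seed=3)
        codes, _ = encode_alignment(aln, ["A"])
        counts = np.bincount(codes[0], minlength=61)
        expected = small_params.codon_freqs * codes.shape[1]
        stat, p = chisquare(counts, expected)
        assert p > 0.01

    def test_no_gaps_and_no_internal_stops(self, small_params):
        tree = PhyloTree.from_newick("((A:0.3,B:0.2):0.1,C:0.4);")
        aln = simulate_alignment(tree, small_params, root_length=200, seed=9)
        assert not any("-" in r.residues for r in aln)
        assert not aln.has_internal_stop()

    def test_invariant_sites_never_change(self, small_params):
        tree = PhyloTree.from_newick("(A:2.0,B:2.0);")
        root = random_codon_seq(np.random.default_rng(4), 50)
        inv = np.zeros(50, dtype=bool)
        inv[10:20] = True
        aln = simulate_alignment(
            tree, small_params, root_sequence=root, seed=2, invariant_sites=inv
        )
        for row in aln:
            assert row.residues[30:60] == root[30:60]

    def test_root_length_validation(self, small_params):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            simulate_alignment(tree, small_params, root_length=0, seed=0)
        with pytest.raises(ValueError):
            simulate_alignment(tree, small_params, seed=0)


class TestNullSet:
    def _gene(self, rng, n_codons=60):
        seq = random_codon_seq(rng, n_codons)
        return CodonAlignment(
            [NucSequence("A", seq), NucSequence("B", seq), NucSequence("OG", seq)]
        )

    def test_zero_real_count_accepts_everything(self, small_params, rng):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05):0.02,OG:0.2);", outgroup="OG")
        # a gene with no IRs in the bin: every simulation is acceptable
        aln = self._gene(rng)
        bin_arm = 15  # essentially never occurs at this length
        ns = build_null_set(
            aln, tree, small_params, bin_arm, n_null=5, seed=1, length_factor=4.0
        )
        assert ns.real_ir_count == 0
        assert ns.n_attempts == 5
        assert len(ns.replicates) == 5

    def test_replicate_counts_respect_the_condition(self, small_params, rng):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05):0.02,OG:0.2);", outgroup="OG")
        aln = self._gene(rng, n_codons=80)
        ns = build_null_set(
            aln, tree, small_params, 7, n_null=8, seed=2, length_factor=5.0
        )
        assert min(ns.ir_counts) >= ns.real_ir_count
        for rep, cnt in zip(ns.replicates, ns.ir_counts):
            assert (
                count_bin_irs(rep, 7, exclude={"OG"}) == cnt
            )

    def test_unattainable_bin_raises_naming_the_bin(self, small_params):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05):0.02,OG:0.2);", outgroup="OG")
        # plant an arm-16 IR so the real count is 1 but simulations of this
        # modest length essentially never contain one; poly-A flanks cannot
        # extend the arms
        insert = "ACAGCGCCCTTGTTCA" + "AATCA" + "TGAACAAGGGCGCTGT"
        seq = "A" * 30 + insert + "A" * 32
        aln = CodonAlignment(
            [NucSequence("A", seq), NucSequence("B", seq), NucSequence("OG", seq)]
        )
        with pytest.raises(NullSetError, match="arm bin 16"):
            build_null_set(
                aln,
                tree,
                small_params,
                16,
                n_null=3,
                max_attempts=6,
                seed=3,
                length_factor=4.0,
            )

    def test_determinism_of_the_ledger(self, small_params, rng):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05):0.02,OG:0.2);", outgroup="OG")
        aln = self._gene(rng)
        n1 = build_null_set(aln, tree, small_params, 7, n_null=4, seed=5)
        n2 = build_null_set(aln, tree, small_params, 7, n_null=4, seed=5)
        assert n1.seed_ledger == n2.seed_ledger
        assert [
            [r.residues for r in rep] for rep in n1.replicates
        ] == [[r.residues for r in rep] for rep in n2.replicates]
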