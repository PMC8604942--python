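"""Synthetic universes: planting primitives, determinism and ground truth."""

import numpy as np
import pytest

from tswitch.core_seq import reverse_complement
from tswitch.ir_finder import InvertedRepeat, find_perfect_irs
from tswitch.synthetic_data import (
    EventSpec,
    PlantingError,
    default_params,
    generate_universe,
    plant_arm_homogenization,
    plant_spacer_inversion,
    random_tree,
)


class TestPlanting:
    def test_homogenization_perfects_the_ir(self):
        left = "ATCCAGCTCG"
        right = reverse_complement(left)
        broken = right[:4] + "AAA" + right[7:]
        if broken == right:  # guard: ensure the break changed something
            broken = right[:4] + "CCC" + right[7:]
        seq = "GG" + left + "TTCA" + broken + "GG"
        ir = InvertedRepeat("x", 2, 10, 4)
        mutated, changed = plant_arm_homogenization(seq, ir)
        l, _, r = ir.slice_arms_spacer(mutated)
        assert reverse_complement(l) == r
        assert len(changed) >= 2
        runs = np.diff(changed)
        assert (runs == 1).any() or len(changed) >= 2

    def test_homogenization_on_perfect_ir_errors(self):
        left = "ATCCAGCTCG"
        seq = "GG" + left + "TTCA" + reverse_complement(left) + "GG"
        with pytest.raises(PlantingError):
            plant_arm_homogenization(seq, InvertedRepeat("x", 2, 10, 4))

    def test_homogenization_requires_contiguous_mismatches(self):
        left = "ATCCAGCTCG"
        right = list(reverse_complement(left))
        right[2] = "A" if right[2] != "A" else "C"
        right[7] = "A" if right[7] != "A" else "C"  # two isolated breaks
        seq = "GG" + left + "TTCA" + "".join(right) + "GG"
        with pytest.raises(PlantingError):
            plant_arm_homogenization(seq, InvertedRepeat("x", 2, 10, 4))

    def test_random_homogenizations_satisfy_revcomp(self, rng):
        for _ in range(20):
            left = "".join(rng.choice(list("ACGT"), size=9))
            right = list(reverse_complement(left))
            k = int(rng.integers(0, 7))
            for i in (k, k + 1, k + 2):
                right[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[right[i]]
            seq = "AA" + left + "TT" + "".join(right) + "AA"
            ir = InvertedRepeat("x", 2, 9, 2)
            mutated, _ = plant_arm_homogenization(seq, ir)
            l, _, r = ir.slice_arms_spacer(mutated)
            assert reverse_complement(l) == r

    @pytest.mark.parametrize(
        "spacer,expected", [("TACC", "GGTA"), ("AA", "TT")]
    )
    def test_inversion_matches_published_spacers(self, spacer, expected):
        left = "ATCCAGCTCC"
        seq = left + spacer + reverse_complement(left)
        ir = InvertedRepeat("x", 0, 10, len(spacer))
        mutated, changed = plant_spacer_inversion(seq, ir)
        s0, s1 = ir.spacer
        assert mutated[s0:s1] == expected
        assert len(changed) >= 2

    def test_double_inversion_restores_the_sequence(self):
        left = "ATCCAGCTCC"
        seq = left + "TACC" + reverse_complement(left)
        ir = InvertedRepeat("x", 0, 10, 4)
        once, _ = plant_spacer_inversion(seq, ir)
        twice, _ = plant_spacer_inversion(once, ir)
        assert twice == seq

    def test_palindromic_spacer_rejected(self):
        left = "ATCCAGCTCC"
        seq = left + "AT" + reverse_complement(left)
        with pytest.raises(PlantingError):
            plant_spacer_inversion(seq, InvertedRepeat("x", 0, 10, 2))


class TestTreeGeneration:
    def test_shape_and_outgroup(self):
        rng = np.random.default_rng(2)
        t = random_tree(12, rng, outgroup="OG")
        assert len(t.leaf_labels) == 13
        assert t.outgroup == "OG"
        assert np.isclose(t.terminal_branch_length("OG"), 0.25)

    def test_branch_length_bounds(self):
        rng = np.random.default_rng(3)
        t = random_tree(20, rng, min_branch=0.01, max_branch=0.12)
        ingroup = [x for x in t.leaf_labels if x != t.outgroup]
        for s in ingroup:
            assert 0.01 <= t.terminal_branch_length(s) <= 0.12


class TestUniverse:
    def test_fixed_seed_reproduces_everything(self):
        kw = dict(
            n_genes=4,
            n_taxa=6,
            gene_length_codons=60,
            event_spec=EventSpec(p_arm_homogenization=0.5, p_spacer_inversion=0.3),
            seed=11,
        )
        u1, u2 = generate_universe(**kw), generate_universe(**kw)
        assert u1.tree.to_newick() == u2.tree.to_newick()
        for g1, g2 in zip(u1.genes, u2.genes):
            assert [(r.id, r.residues) for r in g1.alignment] == [
                (r.id, r.residues) for r in g2.alignment
            ]
        assert u1.truth.to_json() == u2.truth.to_json()

    def test_zero_rate_universe_has_empty_ledger(self):
        u = generate_universe(
            n_genes=5, n_taxa=5, gene_length_codons=50, event_spec=EventSpec(), seed=1
        )
        assert u.truth.events == []

    def test_planted_events_are_rederivable_from_the_ledger(self):
        u = generate_universe(
            n_genes=8,
            n_taxa=8,
            gene_length_codons=80,
            event_spec=EventSpec(p_arm_homogenization=0.6, p_spacer_inversion=0.4),
            seed=5,
        )
        assert u.truth.events  # at these rates something must be planted
        for ev in u.truth.events:
            gene = next(g for g in u.genes if g.name == ev.gene)
            child = gene.alignment.row(ev.taxon).residues
            fp0, fp1 = ev.ir.footprint
            assert child[fp0:fp1] == ev.post_region
            # the parent node retains the ancestral form
            parent_label = u.tree.parent_label(ev.taxon)
            parent = gene.ancestors[parent_label]
            assert parent[fp0:fp1] == ev.pre_region
            diff_cols = [
                fp0 + i
                for i, (a, b) in enumerate(zip(ev.pre_region, ev.post_region))
                if a != b
            ]
            assert diff_cols == ev.changed_columns

    def test_planted_ir_is_detectable_in_the_carrier(self):
        u = generate_universe(
            n_genes=6,
            n_taxa=8,
            gene_length_codons=80,
            event_spec=EventSpec(p_arm_homogenization=1.0, arm_len=10),
            seed=9,
        )
        for ev in u.truth.events:
            gene = next(g for g in u.genes if g.name == ev.gene)
            child = gene.alignment.row(ev.taxon).residues
            irs = find_perfect_irs(child, min_arm=7, max_spacer=70)
            assert any(
                ir.left_arm[0] <= ev.changed_columns[0] < ir.footprint[1]
                for ir in irs
            )

    def test_no_internal_stops_anywhere(self):
        u = generate_universe(
            n_genes=6,
            n_taxa=6,
            gene_length_codons=70,
            event_spec=EventSpec(p_arm_homogenization=0.5, p_spacer_inversion=0.5),
            seed=13,
        )
        for g in u.genes:
            assert not g.alignment.has_internal_stop()
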