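"""MNM calling, IR association and the QC filters."""

import numpy as np
import pytest
from Bio import Align

from tswitch.codon_model import PhyloTree
from tswitch.core_seq import CodonAlignment, NucSequence
from tswitch.ir_finder import InvertedRepeat
from tswitch.mnm_caller import (
    IRAssociation,
    associate,
    call_mnms,
    msa_quality_scores,
    nw_score,
    prefilter_orthoset,
    qc_filter,
    runs_of_true,
    substitution_mask,
)


class TestPrefilter:
    def test_drops_sequences_over_the_n_threshold(self):
        seqs = [NucSequence(f"s{i}", "ACG" * 20) for i in range(4)]
        noisy = NucSequence("noisy", "N" * 21 + "ACG" * 13)
        kept = prefilter_orthoset(seqs + [noisy])
        assert [s.id for s in kept] == [f"s{i}" for i in range(4)]

    def test_exactly_twenty_ns_is_kept(self):
        s = NucSequence("edge", "N" * 20 + "ACG" * 10)
        assert prefilter_orthoset([s] * 4) != []

    def test_fewer_than_four_strains_rejects_the_set(self):
        seqs = [NucSequence(f"s{i}", "ACGACG") for i in range(3)]
        assert prefilter_orthoset(seqs) == []


def _tree_ab():
    return PhyloTree.from_newick("((A:0.05,B:0.05)anc:0.02,OG:0.2);", outgroup="OG")


class TestCallMnms:
    def _aln(self, a, b, og=None):
        og = og or b
        return CodonAlignment(
            [NucSequence("A", a), NucSequence("B", b), NucSequence("OG", og)]
        )

    def test_two_adjacent_substitutions_form_one_mnm(self):
        parent = "ATGTTTCCC"
        child = "ATGAATCCC"  # TT -> AA at columns 3-4
        aln = self._aln(child, parent)
        events = call_mnms(
            aln, _tree_ab(), {"anc": parent, "node0": parent}, exclude={"OG"}
        )
        mine = [e for e in events if e.taxon == "A"]
        assert len(mine) == 1
        assert (mine[0].start, mine[0].end) == (3, 5)
        assert mine[0].parent_alleles == "TT" and mine[0].child_alleles == "AA"

    def test_substitutions_two_apart_are_not_an_mnm(self):
        parent = "ATGTTTCCC"
        child = "ATGATACCC"  # columns 3 and 5 substituted, column 4 intact
        aln = self._aln(child, parent)
        events = call_mnms(
            aln, _tree_ab(), {"anc": parent, "node0": parent}, exclude={"OG"}
        )
        assert [e for e in events if e.taxon == "A"] == []

    def test_changes_on_different_branches_never_join(self):
        parent = "ATGTTTCCC"
        a = "ATGATTCCC"  # column 3 on branch A
        b = "ATGTATCCC"  # column 4 on branch B
        aln = CodonAlignment(
            [NucSequence("A", a), NucSequence("B", b), NucSequence("OG", parent)]
        )
        events = call_mnms(
            aln, _tree_ab(), {"anc": parent, "node0": parent}, exclude={"OG"}
        )
        assert events == []

    def test_gap_columns_break_runs_and_never_substitute(self):
        parent = "ATGTTTCCC"
        child = "ATGA-ACCC"
        aln = self._aln(child, parent)
        events = call_mnms(
            aln, _tree_ab(), {"anc": parent, "node0": parent}, exclude={"OG"}
        )
        assert events == []

    def test_missing_parent_raises(self):
        aln = self._aln("ATGTTTCCC", "ATGTTTCCC")
        with pytest.raises(KeyError):
            call_mnms(aln, _tree_ab(), {}, exclude={"OG"})

    def test_order_independent_and_maximal(self):
        parent = "AAAAAAAAA"
        child = "AAATTTAAA"
        aln = self._aln(child, parent)
        events = call_mnms(
            aln, _tree_ab(), {"anc": parent, "node0": parent}, exclude={"OG"}
        )
        ev = [e for e in events if e.taxon == "A"][0]
        assert (ev.start, ev.end) == (3, 6)  # maximal, not a sub-run


class TestAssociate:
    def _mnm(self, taxon, start, end):
        from tswitch.mnm_caller import MNMEvent

        return MNMEvent(taxon, start, end, "A" * (end - start), "T" * (end - start))

    def test_arm_and_spacer_association(self):
        ir = InvertedRepeat("A", 10, 8, 4)  # arms 10-18 / 22-30, spacer 18-22
        arm_hit = self._mnm("A", 16, 18)  # last two columns of the left arm
        spacer_hit = self._mnm("A", 19, 21)
        elsewhere = self._mnm("A", 50, 53)
        other_strain = self._mnm("B", 16, 18)
        out = associate(
            {"A": [ir]}, [arm_hit, spacer_hit, elsewhere, other_strain]
        )
        assert len(out) == 1
        assoc = out[0]
        assert assoc.mnms_on_arms == [arm_hit]
        assert assoc.mnms_on_spacer == [spacer_hit]

    def test_mnm_straddling_arm_and_spacer_gets_both_labels(self):
        ir = InvertedRepeat("A", 10, 8, 4)
        straddle = self._mnm("A", 17, 19)
        out = associate({"A": [ir]}, [straddle])
        assert out[0].mnms_on_arms == [straddle]
        assert out[0].mnms_on_spacer == [straddle]

    def test_no_association_no_output(self):
        ir = InvertedRepeat("A", 10, 8, 4)
        assert associate({"A": [ir]}, [self._mnm("A", 40, 42)]) == []


class TestNWScores:
    def test_identical_regions_score_difference_zero(self):
        region = "ATGAAATTTCCCGGGTAC" * 2
        nt, codon = msa_quality_scores(region, region)
        assert nt == codon == len(region)

    def test_nt_score_matches_biopython_global_aligner(self):
        rng = np.random.default_rng(8)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = 0
        aligner.extend_gap_score = 0
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=40))
            b = "".join(rng.choice(list("ACGT"), size=35))
            mine = nw_score(list(a), list(b), lambda x, y: 1.0 if x == y else -1.0)
            assert mine == aligner.score(a, b)

    def test_frameshift_inflates_nt_over_codon_score(self):
        # a 1-bp deletion shifts the frame: nucleotides still align well,
        # codon tokens do not
        a = "ATGAAATTTCCCGGGTACGATCATGAAATTTCCCGGGTAC"
        b = a[:7] + a[8:]  # drop one base
        nt, codon = msa_quality_scores(a, b)
        assert nt - codon > 15


class TestQCFilter:
    def _setup(self, branch="0.05", child=None, parent=None, n_codons=40):
        parent = parent or ("ATGAAATTTCCC" * 10)
        child = child or parent
        tree = PhyloTree.from_newick(
            f"((A:{branch},B:0.05)anc:0.02,OG:0.2);", outgroup="OG"
        )
        aln = CodonAlignment(
            [
                NucSequence("A", child),
                NucSequence("B", parent),
                NucSequence("OG", parent),
            ]
        )
        assoc = IRAssociation(ir=InvertedRepeat("A", 12, 8, 4), taxon="A")
        return assoc, aln, tree, {"anc": parent}

    def test_clean_region_is_kept(self):
        assoc, aln, tree, anc = self._setup()
        verdict = qc_filter(assoc, aln, tree, anc)
        assert verdict.keep

    def test_long_terminal_branch_rejected(self):
        assoc, aln, tree, anc = self._setup(branch="0.25")
        verdict = qc_filter(assoc, aln, tree, anc)
        assert (verdict.keep, verdict.reason) == (False, "branch_length")

    def test_indel_in_footprint_rejected(self):
        parent = "ATGAAATTTCCC" * 10
        child = parent[:15] + "-" + parent[16:]
        assoc, aln, tree, anc = self._setup(child=child, parent=parent)
        verdict = qc_filter(assoc, aln, tree, anc)
        assert (verdict.keep, verdict.reason) == (False, "indel")

    def test_low_column_confidence_rejected(self):
        assoc, aln, tree, anc = self._setup()
        conf = np.ones(aln.length)
        conf[14] = 0.5
        verdict = qc_filter(assoc, aln, tree, anc, column_confidence=conf)
        assert (verdict.keep, verdict.reason) == (False, "alignment_confidence")


def test_substitution_mask_and_runs():
    mask = substitution_mask("AAATTT-CA", "AAAAAT-CT")
    assert np.array_equal(np.flatnonzero(mask), [3, 4, 8])
    assert runs_of_true(mask) == [(3, 5)]
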