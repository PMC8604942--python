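"""Multinucleotide-mutation (MNM) calling on terminal branches.

An MNM is a maximal run of two or more strictly contiguous substituted
alignment columns between a strain and its immediate parent node, as
given by the ancestral reconstruction. Columns carrying a gap (or ``N``)
in either sequence never substitute and always break a run; neighbouring
changes on different branches are never joined. Only terminal branches
are scanned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_model import PhyloTree
from .core_seq import CodonAlignment, NucSequence
from .ir_finder import InvertedRepeat


@dataclass(frozen=True)
class MNMEvent:
    """A run of >= 2 contiguous substitutions on one terminal branch."""

    taxon: str
    start: int  # first substituted column (0-based)
    end: int  # past-the-end column
    parent_alleles: str
    child_alleles: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def columns(self) -> range:
        return range(self.start, self.end)

    def overlaps(self, interval: tuple[int, int]) -> bool:
        return self.start < interval[1] and interval[0] < self.end


@dataclass
class IRAssociation:
    """An IR together with the terminal-branch MNMs that touch it."""

    ir: InvertedRepeat
    taxon: str
    mnms_on_arms: list[MNMEvent] = field(default_factory=list)
    mnms_on_spacer: list[MNMEvent] = field(default_factory=list)

    @property
    def mnms(self) -> list[MNMEvent]:
        seen = []
        for m in self.mnms_on_arms + self.mnms_on_spacer:
            if m not in seen:
                seen.append(m)
        return seen


def prefilter_orthoset(
    sequences: list[NucSequence], max_n: int = 20, min_strains: int = 4
) -> list[NucSequence]:
    """Drop sequences with more than ``max_n`` Ns; reject the whole set
    (empty result) if fewer than ``min_strains`` survive."""
    kept = [s for s in sequences if s.residues.count("N") <= max_n]
    return kept if len(kept) >= min_strains else []


def substitution_mask(child: str, parent: str) -> np.ndarray:
    """Columns where child and parent differ with both well-defined."""
    a = np.frombuffer(child.encode(), dtype="S1")
    b = np.frombuffer(parent.encode(), dtype="S1")
    ok = ~np.isin(a, [b"-", b"N"]) & ~np.isin(b, [b"-", b"N"])
    return (a != b) & ok


def runs_of_true(mask: np.ndarray, min_run: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as half-open intervals."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def call_mnms(
    alignment: CodonAlignment,
    tree: PhyloTree,
    ancestors: dict[str, str],
    exclude: set[str] | None = None,
) -> list[MNMEvent]:
    """Call all MNMs between each leaf and its reconstructed parent.

    ``ancestors`` maps internal-node labels to nucleotide sequences on
    alignment coordinates. ``exclude`` skips leaves (e.g. the outgroup).
    """
    exclude = exclude or set()
    events: list[MNMEvent] = []
    for taxon in sorted(tree.leaf_labels):
        if taxon in exclude:
            continue
        parent_label = tree.parent_label(taxon)
        if parent_label not in ancestors:
            raise KeyError(
                f"no ancestral sequence for {parent_label!r}, parent of {taxon!r}"
            )
        child = alignment.row(taxon).residues
        parent = ancestors[parent_label]
        if len(parent) != len(child):
            raise ValueError("ancestor/leaf length mismatch")
        for s, e in runs_of_true(substitution_mask(child, parent)):
            events.append(
                MNMEvent(
                    taxon=taxon,
                    start=s,
                    end=e,
                    parent_alleles=parent[s:e],
                    child_alleles=child[s:e],
                )
            )
    return events


def associate(
    irs_by_strain: dict[str, list[InvertedRepeat]], mnms: list[MNMEvent]
) -> list[IRAssociation]:
    """Attach terminal-branch MNMs to the IRs of the same strain.

    Arm association requires >= 1 MNM column inside either arm; spacer
    association likewise for the spacer. Both labels are possible.
    """
    by_taxon: dict[str, list[MNMEvent]] = {}
    for m in mnms:
        by_taxon.setdefault(m.taxon, []).append(m)
    out: list[IRAssociation] = []
    for strain, irs in sorted(irs_by_strain.items()):
        for ir in irs:
            assoc = IRAssociation(ir=ir, taxon=strain)
            for m in by_taxon.get(strain, []):
                on_arm = m.overlaps(ir.left_arm) or m.overlaps(ir.right_arm)
                on_spacer = ir.spacer_len > 0 and m.overlaps(ir.spacer)
                if on_arm:
                    assoc.mnms_on_arms.append(m)
                if on_spacer:
                    assoc.mnms_on_spacer.append(m)
            if assoc.mnms_on_arms or assoc.mnms_on_spacer:
                out.append(assoc)
    return out


# ---------------------------------------------------------------------------
# quality-control filters


def nw_score(tokens_a, tokens_b, pair_score, gap: float = 0.0) -> float:
    """Global alignment score by dynamic programming (gaps cost ``gap``)."""
    n, m = len(tokens_a), len(tokens_b)
    prev = [gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [gap * i] + [0.0] * m
        ta = tokens_a[i - 1]
        for j in range(1, m + 1):
            cur[j] = max(
                prev[j - 1] + pair_score(ta, tokens_b[j - 1]),
                prev[j] + gap,
                cur[j - 1] + gap,
            )
        prev = cur
    return prev[m]


def _nt_pair(a: str, b: str) -> float:
    return 1.0 if a == b else -1.0


def _codon_pair(a: str, b: str) -> float:
    m = sum(x == y for x, y in zip(a, b))
    return 2.0 * m - 3.0  # +1 per matching, -1 per mismatching position


def _codon_tokens(s: str) -> list[str]:
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def msa_quality_scores(region_a: str, region_b: str) -> tuple[float, float]:
    """(nucleotide score, codon score) of fresh pairwise global alignments
    of the two gap-stripped region sequences.

    The nucleotide alignment scores match=1/mismatch=-1/gap=0 per base;
    the codon alignment treats triplets as indivisible tokens whose
    match/mismatch contributions are summed per base so the two scores
    share a scale. A frameshifting indel degrades the codon score only.
    """
    a = region_a.replace("-", "")
    b = region_b.replace("-", "")
    nt = nw_score(list(a), list(b), _nt_pair)
    codon = nw_score(_codon_tokens(a), _codon_tokens(b), _codon_pair)
    return nt, codon


@dataclass(frozen=True)
class QCVerdict:
    keep: bool
    reason: str = ""


def qc_filter(
    association: IRAssociation,
    alignment: CodonAlignment,
    tree: PhyloTree,
    ancestors: dict[str, str],
    branch_len_cutoff: float = 0.2,
    score_diff_threshold: float = 15.0,
    tail: int = 50,
    column_confidence: np.ndarray | None = None,
    confidence_cutoff: float = 0.95,
) -> QCVerdict:
    """Apply the saturation, indel and alignment-quality filters.

    Rejects when the terminal branch exceeds ``branch_len_cutoff``
    (mutation saturation), when the IR region carries an indel between the
    strain and its parent, or when the nucleotide- and codon-level scores
    of the strain/sister region alignment differ by more than
    ``score_diff_threshold`` (a frameshifted, untrustworthy codon MSA).
    An optional per-column confidence track is screened at
    ``confidence_cutoff``.
    """
    taxon = association.taxon
    if tree.terminal_branch_length(taxon) > branch_len_cutoff:
        return QCVerdict(False, "branch_length")
    fp0, fp1 = association.ir.footprint
    child = alignment.row(taxon).residues[fp0:fp1]
    parent_label = tree.parent_label(taxon)
    parent = ancestors.get(parent_label, "")
    parent_region = parent[fp0:fp1] if parent else ""
    if "-" in child or "-" in parent_region:
        return QCVerdict(False, "indel")
    if column_confidence is not None:
        if np.min(column_confidence[fp0:fp1]) < confidence_cutoff:
            return QCVerdict(False, "alignment_confidence")
    sister = tree.closest_leaf(taxon, exclude={tree.outgroup} if tree.outgroup else None)
    if sister is None:
        return QCVerdict(False, "no_sister")
    n = alignment.length
    r0 = (fp0 // 3) * 3
    r1 = min(n, fp1 + tail)
    r1 += (-r1) % 3
    r1 = min(n, r1)
    region_a = alignment.row(taxon).residues[r0:r1]
    region_b = alignment.row(sister).residues[r0:r1]
    nt, codon = msa_quality_scores(region_a, region_b)
    if abs(nt - codon) > score_diff_threshold:
        return QCVerdict(False, "msa_quality")
    return QCVerdict(True, "")
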