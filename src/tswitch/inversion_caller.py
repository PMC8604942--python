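"""Classification of template-switch events at an inverted repeat.

Given the parent (ancestral) and child (strain) sequences over one IR
footprint, an event is one of:

* ``spacer_inversion`` — the child spacer equals the reverse complement
  of the parent spacer and differs from it (the signature of
  intermolecular template switching during first-arm synthesis);
* ``arm_homogenization`` — the parent arms are imperfect as a pair while
  the child IR is perfect (one arm re-templated the other);
* ``combined`` — both signatures at once.

Only *complete* spacer inversions count; partial reverse-complement
matches remain ordinary MNMs and classify as ``None`` here unless the
arm test fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .codon_model import PhyloTree
from .core_seq import reverse_complement
from .ir_finder import InvertedRepeat

EventKind = Literal["arm_homogenization", "spacer_inversion", "combined"]


@dataclass
class TemplateSwitchEvent:
    """A classified template-switching event on one terminal branch."""

    gene: str
    taxon: str
    ir: InvertedRepeat
    kind: EventKind
    n_substitutions: int
    arm_diffs: int
    spacer_diffs: int
    parent_region: str
    child_region: str
    perfect_in_parent: bool  # arms already perfect before the event
    aa_changes: list = field(default_factory=list)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_event(
    parent_region: str,
    child_region: str,
    ir_in_child: InvertedRepeat,
    gene: str = "",
    taxon: str = "",
) -> TemplateSwitchEvent | None:
    """Classify the parent->child change across one IR footprint.

    Regions are equal-length, gap-free and cover exactly the footprint of
    ``ir_in_child`` (whose coordinates are taken relative to the region).
    Returns ``None`` when neither the spacer nor the arm signature holds.
    """
    if len(parent_region) != len(child_region):
        raise ValueError("parent and child regions differ in length")
    parent_region = parent_region.upper()
    child_region = child_region.upper()
    if len(parent_region) < ir_in_child.footprint[1]:
        raise ValueError("region shorter than the IR footprint")
    c_left, c_spacer, c_right = ir_in_child.slice_arms_spacer(child_region)
    p_left, p_spacer, p_right = ir_in_child.slice_arms_spacer(parent_region)
    if reverse_complement(c_left) != c_right:
        raise ValueError("child does not carry a perfect IR at the given coordinates")

    spacer_diffs = _hamming(p_spacer, c_spacer)
    arm_diffs = _hamming(p_left, c_left) + _hamming(p_right, c_right)
    inversion = (
        ir_in_child.spacer_len > 0
        and c_spacer == reverse_complement(p_spacer)
        and spacer_diffs >= 1
    )
    parent_perfect = reverse_complement(p_left) == p_right
    homogenization = not parent_perfect  # child is perfect by precondition
    if inversion and homogenization:
        kind: EventKind = "combined"
    elif inversion:
        kind = "spacer_inversion"
    elif homogenization:
        kind = "arm_homogenization"
    else:
        return None
    return TemplateSwitchEvent(
        gene=gene,
        taxon=taxon,
        ir=ir_in_child,
        kind=kind,
        n_substitutions=arm_diffs + spacer_diffs,
        arm_diffs=arm_diffs,
        spacer_diffs=spacer_diffs,
        parent_region=parent_region,
        child_region=child_region,
        perfect_in_parent=parent_perfect,
    )


def count_parallel_events(
    events: list[TemplateSwitchEvent], tree: PhyloTree | None = None
) -> dict[tuple[str, tuple[int, int], str], dict]:
    """Tally independent terminal-branch occurrences of the same event.

    Events sharing gene, IR footprint and kind are one recurring event;
    the tally counts the distinct strains carrying it.
    """
    tallies: dict[tuple[str, tuple[int, int], str], dict] = {}
    for ev in events:
        key = (ev.gene, ev.ir.footprint, ev.kind)
        entry = tallies.setdefault(key, {"count": 0, "taxa": []})
        if ev.taxon not in entry["taxa"]:
            entry["taxa"].append(ev.taxon)
            entry["count"] += 1
    return tallies
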