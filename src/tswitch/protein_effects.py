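"""Amino-acid consequences of template-switching events.

Translates the codons touched by an event into replacement lists with
Grantham physicochemical distances (high-distance flag above 120), a
codon-span class (one codon / two neighbouring codons / more), and
transition/transversion tallies of the substituted positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .core_seq import SequenceError, grantham_distance, translate

SpanClass = Literal["one_codon", "two_codons", "multi"]

GRANTHAM_HIGH = 120


@dataclass(frozen=True)
class AAReplacement:
    """One codon's amino-acid change (1-based protein position)."""

    position: int
    from_aa: str
    to_aa: str
    from_codon: str
    to_codon: str
    grantham: int | None
    high_distance: bool
    synonymous: bool


@dataclass
class EventConsequences:
    replacements: list[AAReplacement]
    span_class: SpanClass
    synonymous_only: bool
    codons_touched: list[int]  # 0-based codon indices


def aa_consequences(
    parent_cds: str,
    child_cds: str,
    event_columns: Iterable[int],
    frame: int = 0,
) -> EventConsequences:
    """Per-codon consequences of the substitutions at ``event_columns``.

    ``event_columns`` are 0-based nucleotide positions in the given CDS
    pair; ``frame`` anchors the reading frame. Codons upstream of the
    frame anchor or beyond the CDS raise an error. Serine's multi-
    substitution synonymous codons fall out naturally from translating
    whole codons.
    """
    if len(parent_cds) != len(child_cds):
        raise ValueError("CDS pair must have equal length")
    parent_cds = parent_cds.upper()
    child_cds = child_cds.upper()
    cols = sorted(set(event_columns))
    if not cols:
        return EventConsequences([], "one_codon", False, [])
    n_codons = (len(parent_cds) - frame) // 3
    touched: list[int] = []
    for col in cols:
        if col < frame or (col - frame) // 3 >= n_codons:
            raise ValueError(f"event column {col} outside the in-frame CDS")
        ci = (col - frame) // 3
        if ci not in touched:
            touched.append(ci)
    replacements: list[AAReplacement] = []
    any_nuc_change = False
    for ci in touched:
        start = frame + 3 * ci
        pc, cc = parent_cds[start : start + 3], child_cds[start : start + 3]
        if pc == cc:
            continue
        any_nuc_change = True
        pa, ca = translate(pc), translate(cc)
        syn = pa == ca
        if syn or "*" in pa + ca or "X" in pa + ca:
            dist, high = None, False
        else:
            dist = grantham_distance(pa, ca)
            high = dist > GRANTHAM_HIGH
        replacements.append(
            AAReplacement(
                position=ci + 1,
                from_aa=pa,
                to_aa=ca,
                from_codon=pc,
                to_codon=cc,
                grantham=dist,
                high_distance=high,
                synonymous=syn,
            )
        )
    if len(touched) == 1:
        span: SpanClass = "one_codon"
    elif len(touched) == 2 and touched[1] - touched[0] == 1:
        span = "two_codons"
    else:
        span = "multi"
    nonsyn = [r for r in replacements if not r.synonymous]
    return EventConsequences(
        replacements=replacements,
        span_class=span,
        synonymous_only=any_nuc_change and not nonsyn,
        codons_touched=touched,
    )


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ts_tv_tally(
    changes: Iterable[tuple[str, str]],
) -> tuple[int, int, float | None]:
    """(transitions, transversions, ts/tv ratio) over base changes.

    The ratio is ``None`` when undefined (no changes) and ``inf`` when
    there are transitions but no transversions.
    """
    ts = tv = 0
    for a, b in changes:
        a, b = a.upper(), b.upper()
        if a == b:
            continue
        if a not in "ACGT" or b not in "ACGT":
            raise SequenceError(f"cannot classify change {a!r}->{b!r}")
        if (a, b) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if ts == tv == 0:
        ratio: float | None = None
    elif tv == 0:
        ratio = float("inf")
    else:
        ratio = ts / tv
    return ts, tv, ratio


def event_base_changes(parent: str, child: str) -> list[tuple[str, str]]:
    """The (parent, child) base pairs at every differing position."""
    return [(p, c) for p, c in zip(parent.upper(), child.upper()) if p != c]
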