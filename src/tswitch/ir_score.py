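"""IR-less control matching, the IR score, and empirical significance.

The IR score contrasts the odds of MNM overlap on IRs against matched
IR-free control regions::

    score = [(IRs with MNMs + 1) / (IRs without MNMs + 1)]
          / [(controls with MNMs + 1) / (controls without MNMs + 1)]

with a pseudo-count of 1 on every term. Significance is the upper-tail
empirical rank of the real score among the scores of the 100 simulated
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_seq import CodonAlignment
from .ir_finder import InvertedRepeat


@dataclass(frozen=True)
class ControlRegion:
    """An IR-free interval matched to one IR: same strain, length equal to
    the IR's arm length, nearest to the IR footprint (ties broken 5')."""

    seq_id: str
    start: int
    length: int
    distance: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.start + self.length)


def _interval_distance(start: int, length: int, fp: tuple[int, int]) -> int | None:
    if start + length <= fp[0]:
        return fp[0] - (start + length)
    if start >= fp[1]:
        return start - fp[1]
    return None  # overlaps the IR itself


def nearest_control_start(
    length: int,
    footprint: tuple[int, int],
    n_columns: int,
    forbidden: list[tuple[int, int]],
    gap_free: np.ndarray | None = None,
) -> tuple[int, int] | None:
    """(start, distance) of the closest admissible window, or None.

    Admissible: inside ``[0, n_columns)``, intersecting no forbidden
    (IR-footprint) interval, gap-free where a mask is supplied. Ties on
    distance resolve to the smaller start (the 5' side).
    """
    best: tuple[int, int] | None = None
    for start in range(0, n_columns - length + 1):
        d = _interval_distance(start, length, footprint)
        if d is None:
            continue
        end = start + length
        if any(start < f1 and f0 < end for f0, f1 in forbidden):
            continue
        if gap_free is not None and not gap_free[start:end].all():
            continue
        if best is None or d < best[1]:
            best = (start, d)
    return best


def match_controls(
    irs: list[InvertedRepeat],
    alignment: CodonAlignment,
    all_footprints_by_strain: dict[str, list[tuple[int, int]]],
) -> list[tuple[InvertedRepeat, ControlRegion | None]]:
    """One control per IR (so control and IR counts match).

    ``all_footprints_by_strain`` lists every detected IR footprint per
    strain (any bin): controls may not intersect any of them. IRs with
    identical coordinates shared by several strains receive the control
    at the same position in each sharing strain, computed against the
    union of the sharers' forbidden footprints.
    """
    n = alignment.length
    groups: dict[tuple[int, int, int], list[InvertedRepeat]] = {}
    for ir in irs:
        groups.setdefault((ir.left_start, ir.arm_len, ir.spacer_len), []).append(ir)
    out: list[tuple[InvertedRepeat, ControlRegion | None]] = []
    for key in sorted(groups):
        members = groups[key]
        strains = sorted({ir.seq_id for ir in members})
        forbidden = sorted(
            {fp for s in strains for fp in all_footprints_by_strain.get(s, [])}
        )
        gap_free = np.ones(n, dtype=bool)
        for s in strains:
            row = alignment.row(s).residues
            gap_free &= np.frombuffer(row.encode(), dtype="S1") != b"-"
        proto = members[0]
        hit = nearest_control_start(
            proto.arm_len, proto.footprint, n, forbidden, gap_free
        )
        for ir in members:
            if hit is None:
                out.append((ir, None))
            else:
                out.append(
                    (
                        ir,
                        ControlRegion(
                            seq_id=ir.seq_id,
                            start=hit[0],
                            length=ir.arm_len,
                            distance=hit[1],
                        ),
                    )
                )
    return out


def compute_ir_score(
    irs_with_mnm: int,
    irs_without: int,
    controls_with_mnm: int,
    controls_without: int,
) -> float:
    """The pseudo-counted odds ratio ((a+1)/(b+1)) / ((c+1)/(d+1))."""
    counts = (irs_with_mnm, irs_without, controls_with_mnm, controls_without)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    a, b, c, d = counts
    return ((a + 1) / (b + 1)) / ((c + 1) / (d + 1))


def empirical_significance(
    real_score: float, null_scores: list[float] | np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Add-one upper-tail empirical p: (#{null >= real} + 1) / (n + 1).

    Ties count toward the null (conservative). Significant when
    ``p <= alpha``.
    """
    nulls = np.asarray(null_scores, dtype=float)
    if nulls.size == 0:
        raise ValueError("null distribution is empty")
    p = (float(np.sum(nulls >= real_score)) + 1.0) / (nulls.size + 1.0)
    return p, p <= alpha


@dataclass
class IRScoreResult:
    """Per-gene, per-arm-length-bin IR score and its empirical null."""

    gene: str
    arm_len: int
    counts: tuple[int, int, int, int]  # a, b, c, d
    score: float
    null_scores: list[float] = field(default_factory=list)
    empirical_p: float = float("nan")
    significant: bool = False
    n_controls_missing: int = 0

    def finalize(self, alpha: float = 0.05) -> "IRScoreResult":
        self.empirical_p, self.significant = empirical_significance(
            self.score, self.null_scores, alpha=alpha
        )
        return self
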