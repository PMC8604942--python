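"""Detection of perfect inverted repeats (IRs).

A perfect IR is a pair of *arms* in exact reverse-complement orientation
separated by a *spacer*: left arm ``[i, i+k)``, spacer ``[i+k, i+k+L)``,
right arm ``[i+k+L, i+2k+L)`` with ``revcomp(left) == right``. Only
*maximal* IRs are reported: arms extendable neither outward (flanking
bases do not pair, or a sequence boundary is hit) nor inward (the
outermost spacer bases do not pair). ``N`` never pairs with anything.

The search scans anti-diagonals of the base-pairing matrix: every arm
pair ``(i, j)`` of one IR centre satisfies ``i + j = const``, so maximal
IRs are maximal match-runs along anti-diagonals, which vectorizes well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_seq import NucSequence, SequenceError, reverse_complement

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP_CODE = {"A": 3, "C": 2, "G": 1, "T": 0, "N": 5}  # 5 never matches


@dataclass(frozen=True)
class InvertedRepeat:
    """Coordinates of a perfect IR on one (gap-free) sequence.

    All intervals are 0-based half-open; ``left_arm``, ``spacer`` and
    ``right_arm`` abut, so the footprint is ``[left_start, right_end)``.
    """

    seq_id: str
    left_start: int
    arm_len: int
    spacer_len: int

    @property
    def left_arm(self) -> tuple[int, int]:
        return (self.left_start, self.left_start + self.arm_len)

    @property
    def spacer(self) -> tuple[int, int]:
        s = self.left_start + self.arm_len
        return (s, s + self.spacer_len)

    @property
    def right_arm(self) -> tuple[int, int]:
        s = self.left_start + self.arm_len + self.spacer_len
        return (s, s + self.arm_len)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.left_start, self.right_arm[1])

    def slice_arms_spacer(self, seq: str) -> tuple[str, str, str]:
        (l0, l1), (s0, s1), (r0, r1) = self.left_arm, self.spacer, self.right_arm
        return seq[l0:l1], seq[s0:s1], seq[r0:r1]

    def verify(self, seq: str) -> bool:
        left, _, right = self.slice_arms_spacer(seq)
        return "N" not in left and reverse_complement(left) == right


def find_perfect_irs(
    seq: str | NucSequence, min_arm: int = 7, max_spacer: int = 70
) -> list[InvertedRepeat]:
    """All maximal perfect IRs with ``arm_len >= min_arm`` and
    ``spacer_len <= max_spacer`` in a gap-free sequence.

    Results are sorted by ``(left_start, arm_len)``.
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    seq_id = seq.id if isinstance(seq, NucSequence) else ""
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    if "-" in s:
        raise SequenceError("find_perfect_irs requires a gap-free sequence")
    n = len(s)
    if n < 2 * min_arm:
        return []

    x = np.fromiter((_CODE[ch] for ch in s), dtype=np.int8, count=n)
    yc = np.fromiter((_COMP_CODE[ch] for ch in s), dtype=np.int8, count=n)

    # window depth: candidate centres (spacer <= max_spacer) plus room for
    # arm extension; runs hitting the window floor are finished by scalar scan
    arm_pad = 64
    K = max_spacer // 2 + 1 + arm_pad
    diags = np.arange(2 * n - 1)
    i_hi = (diags - 1) // 2  # innermost admissible left index per diagonal
    ks = np.arange(K)
    I = i_hi[:, None] - ks[None, :]
    J = diags[:, None] - I
    valid = (I >= 0) & (J < n)
    Ic = np.clip(I, 0, n - 1)
    Jc = np.clip(J, 0, n - 1)
    M = valid & (x[Ic] == yc[Jc])

    # run[s, k]: consecutive matches at k, k+1, ... (arm growing outward)
    run = np.zeros_like(M, dtype=np.int32)
    run[:, K - 1] = M[:, K - 1]
    for k in range(K - 2, -1, -1):
        run[:, k] = np.where(M[:, k], run[:, k + 1] + 1, 0)

    L0 = np.where(diags % 2 == 1, 0, 1)  # spacer parity per diagonal
    irs: list[InvertedRepeat] = []
    kmax = (max_spacer - L0) // 2
    # candidate centres: innermost pair matches, inward pair does not
    cand = M.copy()
    cand[:, 1:] &= ~M[:, :-1]
    cand &= ks[None, :] <= kmax[:, None]
    cand &= run >= min_arm
    for d, k in zip(*np.nonzero(cand)):
        arm = int(run[d, k])
        i_end = int(i_hi[d] - k)
        if k + arm >= K:  # run touches window floor: finish by direct scan
            i = i_end - arm
            j = d - i
            while i >= 0 and j < n and x[i] == yc[j]:
                arm += 1
                i -= 1
                j += 1
        spacer = int(L0[d] + 2 * k)
        irs.append(
            InvertedRepeat(
                seq_id=seq_id,
                left_start=i_end - arm + 1,
                arm_len=arm,
                spacer_len=spacer,
            )
        )
    irs.sort(key=lambda r: (r.left_start, r.arm_len))
    return irs


def max_arm_ir(irs: list[InvertedRepeat]) -> InvertedRepeat | None:
    """The IR with the longest arm (ties: leftmost)."""
    if not irs:
        return None
    return max(irs, key=lambda r: (r.arm_len, -r.left_start))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _nested(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return (a[0] >= b[0] and a[1] <= b[1]) or (b[0] >= a[0] and b[1] <= a[1])


def bin_and_deduplicate(
    irs: list[InvertedRepeat],
) -> dict[int, list[InvertedRepeat]]:
    """Bin one strain's IRs by arm length and resolve overlaps.

    Each maximal IR goes to the bin of its (maximal) arm length. Within a
    bin, IRs whose footprints partially overlap are all dropped; fully
    nested pairs are both kept.
    """
    bins: dict[int, list[InvertedRepeat]] = {}
    for ir in irs:
        bins.setdefault(ir.arm_len, []).append(ir)
    out: dict[int, list[InvertedRepeat]] = {}
    for arm, group in sorted(bins.items()):
        drop = set()
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                fi, fj = group[i].footprint, group[j].footprint
                if _overlaps(fi, fj) and not _nested(fi, fj):
                    drop.add(i)
                    drop.add(j)
        kept = [ir for k, ir in enumerate(group) if k not in drop]
        if kept:
            out[arm] = kept
    return out


def irs_to_table(irs: list[InvertedRepeat]) -> pd.DataFrame:
    """TSV-ready table: seq_id, arm_len, spacer_len, left_start, right_end."""
    return pd.DataFrame(
        [
            {
                "seq_id": ir.seq_id,
                "arm_len": ir.arm_len,
                "spacer_len": ir.spacer_len,
                "left_start": ir.left_start,
                "right_end": ir.footprint[1],
            }
            for ir in irs
        ],
        columns=["seq_id", "arm_len", "spacer_len", "left_start", "right_end"],
    )
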