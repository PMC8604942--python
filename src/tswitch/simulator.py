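"""Codon-alignment simulation along the tree and the conditional null set.

Each site draws one omega category (shared across the whole tree, the
usual M5 semantics) and codon states are sampled child-ward with the
per-category transition probabilities. No indels are generated, and the
state space is the 61 sense codons, so simulated alignments are gap-free
and stop-free by construction.

The null set mirrors the study's rejection loop: simulate alignments
whose root length is ``length_factor`` times the outgroup length and keep
the first ``n_null`` whose IR count (per arm-length bin, after overlap
resolution) is at least the real alignment's count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_model import CodonModelParams, MixtureModel, PhyloTree
from .core_seq import CODON_INDEX, CodonAlignment, NucSequence, SENSE_CODONS
from .ir_finder import bin_and_deduplicate, find_perfect_irs

_CODON_ARR = np.array(SENSE_CODONS)


class NullSetError(RuntimeError):
    """Raised when the acceptance loop cannot assemble the null set."""


def _decode(codes: np.ndarray, ids: list[str]) -> CodonAlignment:
    return CodonAlignment(
        [
            NucSequence(name, "".join(_CODON_ARR[row]))
            for name, row in zip(ids, codes)
        ]
    )


def simulate_codes(
    tree: PhyloTree,
    model: MixtureModel,
    root_codes: np.ndarray,
    rng: np.random.Generator,
    invariant_sites: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Sample codon codes for every node; returns node index -> codes."""
    n_sites = root_codes.shape[0]
    cats = rng.integers(0, model.n_categories, size=n_sites)
    # per-category cumulative transition rows, built lazily per branch
    states: dict[int, np.ndarray] = {tree.root: root_codes.copy()}
    for v in tree.preorder:
        if tree.parent[v] < 0:
            continue
        parent_states = states[tree.parent[v]]
        child = parent_states.copy()
        t = tree.lengths[v]
        if t > 0:
            for c in range(model.n_categories):
                mask = cats == c
                if invariant_sites is not None:
                    mask = mask & ~invariant_sites
                if not mask.any():
                    continue
                cumP = np.cumsum(model.transition_matrix(t, c), axis=1)
                u = rng.random(mask.sum())
                rows = cumP[parent_states[mask]]
                child[mask] = (rows < u[:, None]).sum(axis=1)
        states[v] = child
    return states


def simulate_alignment(
    tree: PhyloTree,
    params: CodonModelParams,
    root_sequence: str | None = None,
    root_length: int | None = None,
    seed: int | np.random.Generator = 0,
    return_ancestors: bool = False,
    invariant_sites: np.ndarray | None = None,
):
    """Simulate a gap-free codon alignment along the rooted tree.

    Exactly one of ``root_sequence`` (a codon-clean string) or
    ``root_length`` (codons, root drawn from the stationary distribution)
    must be given. With ``return_ancestors`` the sequences of every
    internal node are returned as well.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    model = MixtureModel(params)
    if root_sequence is not None:
        if len(root_sequence) < 3 or len(root_sequence) % 3:
            raise ValueError("root sequence must contain >= 1 whole codon")
        root_codes = np.array(
            [
                CODON_INDEX[root_sequence[3 * i : 3 * i + 3].upper()]
                for i in range(len(root_sequence) // 3)
            ],
            dtype=np.int16,
        )
    elif root_length is not None:
        if root_length < 1:
            raise ValueError("root must be at least 1 codon long")
        root_codes = rng.choice(61, size=root_length, p=model.pi).astype(np.int16)
    else:
        raise ValueError("give either root_sequence or root_length")
    states = simulate_codes(tree, model, root_codes, rng, invariant_sites)
    leaves = [v for v in range(tree.n_nodes) if tree.is_leaf[v]]
    aln = _decode([states[v] for v in leaves], [tree.labels[v] for v in leaves])
    if return_ancestors:
        internals = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
        ancestors = {
            tree.labels[v]: "".join(_CODON_ARR[states[v]]) for v in internals
        }
        return aln, ancestors
    return aln


def count_bin_irs(
    alignment: CodonAlignment,
    arm_len_bin: int,
    min_arm: int = 7,
    max_spacer: int = 70,
    exclude: set[str] | None = None,
) -> int:
    """Total IRs in one arm-length bin, summed over strains, after the
    per-strain overlap/nesting resolution."""
    exclude = exclude or set()
    total = 0
    for row in alignment:
        if row.id in exclude:
            continue
        irs = find_perfect_irs(row.ungapped, min_arm=min_arm, max_spacer=max_spacer)
        total += len(bin_and_deduplicate(irs).get(arm_len_bin, []))
    return total


@dataclass
class NullSet:
    """The accepted null replicates for one gene and one arm-length bin."""

    arm_len_bin: int
    real_ir_count: int
    replicates: list[CodonAlignment]
    ir_counts: list[int]
    seed_ledger: list[dict] = field(default_factory=list)
    n_attempts: int = 0

    @property
    def acceptance_rate(self) -> float:
        return len(self.replicates) / self.n_attempts if self.n_attempts else 0.0


def build_null_set(
    real_alignment: CodonAlignment,
    tree: PhyloTree,
    params: CodonModelParams,
    arm_len_bin: int,
    n_null: int = 100,
    length_factor: float = 4.5,
    max_attempts: int | None = None,
    min_arm: int = 7,
    max_spacer: int = 70,
    seed: int = 0,
    root_sequence: str | None = None,
    outgroup: str | None = None,
) -> NullSet:
    """Rejection-sample ``n_null`` alignments whose bin IR count is >= the
    real alignment's count.

    The root sequence of each replicate is drawn from the stationary
    distribution with length ``length_factor`` times the outgroup's
    (ungapped) length, unless ``root_sequence`` pins it explicitly.
    """
    if not 1 <= n_null:
        raise ValueError("n_null must be >= 1")
    max_attempts = max_attempts or 50 * n_null
    outgroup = outgroup or tree.outgroup
    exclude = {outgroup} if outgroup else set()
    real_count = count_bin_irs(
        real_alignment, arm_len_bin, min_arm, max_spacer, exclude=exclude
    )
    if outgroup is not None:
        ref_len = len(real_alignment.row(outgroup).ungapped)
    else:
        ref_len = real_alignment.length
    root_codons = max(1, int(round(length_factor * ref_len / 3)))
    ss = np.random.SeedSequence(seed)
    kept: list[CodonAlignment] = []
    counts: list[int] = []
    ledger: list[dict] = []
    attempt = 0
    while len(kept) < n_null and attempt < max_attempts:
        child = np.random.default_rng(ss.spawn(1)[0])
        attempt += 1
        aln = simulate_alignment(
            tree,
            params,
            root_sequence=root_sequence,
            root_length=None if root_sequence else root_codons,
            seed=child,
        )
        cnt = count_bin_irs(aln, arm_len_bin, min_arm, max_spacer, exclude=exclude)
        accepted = cnt >= real_count
        ledger.append({"attempt": attempt, "ir_count": cnt, "accepted": accepted})
        if accepted:
            kept.append(aln)
            counts.append(cnt)
    if len(kept) < n_null:
        raise NullSetError(
            f"could not assemble {n_null} null replicates for arm bin "
            f"{arm_len_bin} after {attempt} attempts "
            f"(real IR count {real_count}); the bin cannot be evaluated"
        )
    return NullSet(
        arm_len_bin=arm_len_bin,
        real_ir_count=real_count,
        replicates=kept,
        ir_counts=counts,
        seed_ledger=ledger,
        n_attempts=attempt,
    )
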