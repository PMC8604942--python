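"""Synthetic test universes with planted template-switching events.

Generates a clock-free rooted tree (random-join ingroup plus one
outgroup), gap-free in-frame codon alignments evolved under the M5 codon
model, and optional planted events on terminal branches:

* arm homogenization — the root carries an inverted repeat whose arms
  mismatch over a short contiguous run; on one leaf the mismatched arm is
  overwritten with the reverse complement of the other, yielding a
  perfect IR and a contiguous MNM on that terminal branch;
* spacer inversion — the root carries a perfect IR; on one leaf the
  spacer is replaced by its reverse complement.

The planted IR footprint is held invariant during neutral simulation
(strong local constraint), so the parent node provably retains the
ancestral form and the terminal branch carries exactly the planted
change. Every change is recorded in a ground-truth ledger keyed by gene.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .codon_model import CodonModelParams, PhyloTree
from .core_seq import (
    CodonAlignment,
    NucSequence,
    STOP_CODONS,
    reverse_complement,
    write_fasta,
)
from .ir_finder import InvertedRepeat
from .simulator import simulate_alignment

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PlantingError(ValueError):
    """Raised when a requested event cannot be planted."""


# ---------------------------------------------------------------------------
# event planting primitives


def _diff_runs(a: str, b: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y and start is None:
            start = i
        elif x == y and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(a)))
    return runs


def plant_arm_homogenization(seq: str, ir: InvertedRepeat) -> tuple[str, list[int]]:
    """Overwrite the right arm with the reverse complement of the left,
    turning the imperfect IR at ``ir``'s coordinates into a perfect one.

    The arms must disagree over at least one contiguous run of >= 2
    positions (otherwise the change would not be callable as an MNM).
    Returns the mutated sequence and the changed positions.
    """
    left, _, right = ir.slice_arms_spacer(seq)
    target = reverse_complement(left)
    if right == target:
        raise PlantingError("IR arms are already perfect; nothing to homogenize")
    runs = _diff_runs(right, target)
    if max(e - s for s, e in runs) < 2:
        raise PlantingError(
            "arm mismatches are not contiguous over >= 2 positions"
        )
    r0, r1 = ir.right_arm
    mutated = seq[:r0] + target + seq[r1:]
    changed = [r0 + i for i in range(len(target)) if seq[r0 + i] != target[i]]
    return mutated, changed


def plant_spacer_inversion(seq: str, ir: InvertedRepeat) -> tuple[str, list[int]]:
    """Replace the spacer of a perfect IR by its reverse complement."""
    left, spacer, right = ir.slice_arms_spacer(seq)
    if reverse_complement(left) != right:
        raise PlantingError("IR is not perfect at the given coordinates")
    inverted = reverse_complement(spacer)
    if inverted == spacer:
        raise PlantingError(
            "spacer equals its own reverse complement; inversion unobservable"
        )
    s0, s1 = ir.spacer
    mutated = seq[:s0] + inverted + seq[s1:]
    changed = [s0 + i for i in range(len(spacer)) if spacer[i] != inverted[i]]
    return mutated, changed


# ---------------------------------------------------------------------------
# tree generation


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    outgroup: str = "OUTGROUP",
    mean_branch: float = 0.04,
    min_branch: float = 0.01,
    max_branch: float = 0.12,
    outgroup_branch: float = 0.25,
) -> PhyloTree:
    """Clock-free rooted binary tree: random joins over the ingroup taxa,
    exponential branch lengths (clipped), outgroup attached at the root."""
    if n_taxa < 2:
        raise ValueError("need at least 2 ingroup taxa")

    def blen() -> float:
        return float(np.clip(rng.exponential(mean_branch), min_branch, max_branch))

    nodes = [f"S{i + 1:02d}:{blen():.6f}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        inner = f"({a},{b}):{blen():.6f}"
        nodes.append(inner)
    ingroup = nodes[0].rsplit(":", 1)[0]
    newick = f"({ingroup}:{blen():.6f},{outgroup}:{outgroup_branch:.6f});"
    return PhyloTree.from_newick(newick, outgroup=outgroup)


# ---------------------------------------------------------------------------
# universe generation


@dataclass(frozen=True)
class EventSpec:
    """Planted-event configuration (rates are per gene)."""

    p_arm_homogenization: float = 0.0
    p_spacer_inversion: float = 0.0
    arm_len: int = 10
    spacer_len: int = 4
    mismatch_run: int = 3
    max_branch: float = 0.1  # only leaves with shorter terminal branches
    n_carriers: int = 1

    def __post_init__(self) -> None:
        for p in (self.p_arm_homogenization, self.p_spacer_inversion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("event rates must lie in [0, 1]")


@dataclass
class PlantedEvent:
    gene: str
    kind: str  # arm_homogenization | spacer_inversion
    taxon: str
    left_start: int
    arm_len: int
    spacer_len: int
    pre_region: str  # footprint before the event (= parent state)
    post_region: str  # footprint after the event (leaf state)
    changed_columns: list[int]

    @property
    def ir(self) -> InvertedRepeat:
        return InvertedRepeat(
            seq_id=self.taxon,
            left_start=self.left_start,
            arm_len=self.arm_len,
            spacer_len=self.spacer_len,
        )


@dataclass
class GeneData:
    name: str
    alignment: CodonAlignment
    ancestors: dict[str, str]
    events: list[PlantedEvent] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: everything needed to audit recovery."""

    tree_newick: str
    params: CodonModelParams
    events: list[PlantedEvent] = field(default_factory=list)
    ancestors: dict[str, dict[str, str]] = field(default_factory=dict)

    def events_for(self, gene: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.gene == gene]

    def to_json(self) -> str:
        payload = {
            "tree": self.tree_newick,
            "params": {
                "kappa": self.params.kappa,
                "omega_shape": self.params.omega_shape,
                "omega_rate": self.params.omega_rate,
                "n_categories": self.params.n_categories,
            },
            "events": [asdict(e) for e in self.events],
        }
        return json.dumps(payload, indent=1)


@dataclass
class Universe:
    tree: PhyloTree
    genes: list[GeneData]
    truth: SyntheticTruth
    params: CodonModelParams

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        for g in self.genes:
            write_fasta(g.alignment.taxa, out / f"{g.name}.fasta")
        (out / "truth.json").write_text(self.truth.to_json())


def default_params(n_categories: int = 4) -> CodonModelParams:
    """Yeast-flavoured defaults: kappa ~2.5, strongly purifying omega
    (Gamma mean 0.2), AT-rich F3x4-style codon frequencies."""
    nt = {"A": 0.31, "C": 0.19, "G": 0.20, "T": 0.30}
    from .core_seq import SENSE_CODONS

    freqs = np.array([nt[c[0]] * nt[c[1]] * nt[c[2]] for c in SENSE_CODONS])
    freqs /= freqs.sum()
    return CodonModelParams(
        kappa=2.5,
        omega_shape=0.8,
        omega_rate=4.0,
        n_categories=n_categories,
        codon_freqs=freqs,
    )


def _build_ir_region(
    rng: np.random.Generator, spec: EventSpec, kind: str
) -> tuple[str, str]:
    """(ancestral footprint, derived footprint) for one planted event."""
    bases = "ACGT"
    for _ in range(200):
        left = "".join(rng.choice(list(bases), size=spec.arm_len))
        spacer = "".join(rng.choice(list(bases), size=spec.spacer_len))
        right = reverse_complement(left)
        if kind == "spacer_inversion":
            inv = reverse_complement(spacer)
            runs = _diff_runs(spacer, inv)
            if not runs or max(e - s for s, e in runs) < 2:
                continue
            pre = left + spacer + right
            post = left + inv + right
        else:  # arm_homogenization: break the right arm over a contiguous run
            run = spec.mismatch_run
            if run < 2:
                raise PlantingError("mismatch run must be >= 2 to yield an MNM")
            if run > spec.arm_len:
                raise PlantingError("mismatch run longer than the arm")
            start = int(rng.integers(0, spec.arm_len - run + 1))
            broken = list(right)
            for i in range(start, start + run):
                choices = [b for b in bases if b != right[i]]
                broken[i] = choices[int(rng.integers(0, 3))]
            pre = left + spacer + "".join(broken)
            post = left + spacer + right
        return pre, post
    raise PlantingError("could not construct an IR region for the event")


def _region_stop_free(gene: str, start: int, region: str) -> bool:
    """True when splicing ``region`` into ``gene`` at ``start`` keeps the
    reading frame free of stop codons across the affected codons."""
    s = gene[:start] + region + gene[start + len(region) :]
    c0 = start // 3
    c1 = (start + len(region) + 2) // 3
    for ci in range(c0, min(c1, len(s) // 3)):
        if s[3 * ci : 3 * ci + 3] in STOP_CODONS:
            return False
    return True


def generate_universe(
    n_genes: int,
    n_taxa: int,
    gene_length_codons: int,
    params: CodonModelParams | None = None,
    event_spec: EventSpec | None = None,
    seed: int = 0,
    outgroup: str = "OUTGROUP",
    tree: PhyloTree | None = None,
) -> Universe:
    """Generate genes, tree and ground truth for one synthetic study.

    Events are planted post hoc on terminal branches: the leaf sequence is
    overwritten while its parent keeps the ancestral form. Genes where no
    admissible leaf or region exists log a skipped event in the ledger
    rather than failing.
    """
    rng = np.random.default_rng(seed)
    spec = event_spec or EventSpec()
    params = params or default_params()
    tree = tree or random_tree(n_taxa, rng, outgroup=outgroup)
    truth = SyntheticTruth(tree_newick=tree.to_newick(), params=params)
    genes: list[GeneData] = []
    eligible = [
        t
        for t in tree.leaf_labels
        if t != outgroup and tree.terminal_branch_length(t) <= spec.max_branch
    ]
    L = 3 * gene_length_codons
    for g in range(n_genes):
        name = f"gene{g + 1:04d}"
        u = rng.random()
        if u < spec.p_arm_homogenization and eligible:
            kind = "arm_homogenization"
        elif u < spec.p_arm_homogenization + spec.p_spacer_inversion and eligible:
            kind = "spacer_inversion"
        else:
            kind = None
        if kind is None:
            aln, anc = simulate_alignment(
                tree,
                params,
                root_length=gene_length_codons,
                seed=rng,
                return_ancestors=True,
            )
            genes.append(GeneData(name, aln, anc))
            truth.ancestors[name] = anc
            continue
        # plant the ancestral region into a stop-free root, evolve with the
        # footprint held invariant, then apply the event on chosen leaves
        from .codon_model import MixtureModel

        footprint_len = 2 * spec.arm_len + spec.spacer_len
        pi = MixtureModel(params).pi
        root_codes = rng.choice(61, size=gene_length_codons, p=pi)
        from .core_seq import SENSE_CODONS as _SC

        root_seq = "".join(_SC[c] for c in root_codes)
        placed = None
        for _ in range(200):
            pre, post = _build_ir_region(rng, spec, kind)
            start = int(rng.integers(3, L - footprint_len - 3))
            if _region_stop_free(root_seq, start, pre) and _region_stop_free(
                root_seq, start, post
            ):
                placed = (pre, post, start)
                break
        if placed is None:
            aln0, anc0 = simulate_alignment(
                tree,
                params,
                root_sequence=root_seq,
                seed=rng,
                return_ancestors=True,
            )
            genes.append(GeneData(name, aln0, anc0))
            truth.ancestors[name] = anc0
            continue
        pre, post, start = placed
        root_seq = root_seq[:start] + pre + root_seq[start + footprint_len :]
        inv_sites = np.zeros(gene_length_codons, dtype=bool)
        inv_sites[start // 3 : (start + footprint_len + 2) // 3] = True
        aln, anc = simulate_alignment(
            tree,
            params,
            root_sequence=root_seq,
            seed=rng,
            return_ancestors=True,
            invariant_sites=inv_sites,
        )
        carriers = rng.choice(
            eligible, size=min(spec.n_carriers, len(eligible)), replace=False
        )
        ir = InvertedRepeat(
            seq_id="",
            left_start=start,
            arm_len=spec.arm_len,
            spacer_len=spec.spacer_len,
        )
        rows = {t.id: t.residues for t in aln}
        events: list[PlantedEvent] = []
        for taxon in sorted(carriers):
            ir_t = InvertedRepeat(
                seq_id=taxon,
                left_start=start,
                arm_len=spec.arm_len,
                spacer_len=spec.spacer_len,
            )
            if kind == "arm_homogenization":
                mutated, changed = plant_arm_homogenization(rows[taxon], ir_t)
            else:
                mutated, changed = plant_spacer_inversion(rows[taxon], ir_t)
            rows[taxon] = mutated
            events.append(
                PlantedEvent(
                    gene=name,
                    kind=kind,
                    taxon=taxon,
                    left_start=start,
                    arm_len=spec.arm_len,
                    spacer_len=spec.spacer_len,
                    pre_region=pre,
                    post_region=post,
                    changed_columns=changed,
                )
            )
        aln = CodonAlignment(
            [NucSequence(t.id, rows[t.id]) for t in aln]
        )
        genes.append(GeneData(name, aln, anc, events))
        truth.ancestors[name] = anc
        truth.events.extend(events)
    return Universe(tree=tree, genes=genes, truth=truth, params=params)
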