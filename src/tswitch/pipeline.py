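"""End-to-end orchestration of the template-switching analysis.

Per gene: prefilter -> IR detection and binning -> model fit ->
restricted marginal ancestral reconstruction -> terminal-branch MNM
overlap -> QC -> control matching -> conditional null set -> IR score and
empirical significance -> inversion classification -> protein effects.

Arm-length bins with no QC-passing IR/MNM association are never
simulated: their real score cannot clear the upper-tail threshold, so
they are reported untested (matching the study design, where only genes
with IR-associated MNMs entered the significance stage). Reconstruction
is restricted to the codon columns the counting actually reads (IR
footprints, controls, one flanking base) — site marginals are
independent, so the restriction is exact — and null replicates are
reconstructed in one batched pass.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_model import (
    CodonModelParams,
    MixtureModel,
    PhyloTree,
    SENSE_CODONS,
    encode_alignment,
    fit_parameters,
    reconstruct_codes,
)
from .core_seq import CodonAlignment
from .inversion_caller import TemplateSwitchEvent, classify_event
from .ir_finder import InvertedRepeat, bin_and_deduplicate, find_perfect_irs
from .ir_score import (
    ControlRegion,
    IRScoreResult,
    compute_ir_score,
    nearest_control_start,
)
from .mnm_caller import (
    IRAssociation,
    MNMEvent,
    prefilter_orthoset,
    qc_filter,
    runs_of_true,
    substitution_mask,
)
from .protein_effects import EventConsequences, aa_consequences
from .simulator import NullSetError, build_null_set

logger = logging.getLogger("tswitch")


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults are the study's operating point."""

    min_arm: int = 7
    max_spacer: int = 70
    n_null: int = 100
    alpha: float = 0.05
    score_diff_threshold: float = 15.0
    branch_len_cutoff: float = 0.2
    max_n: int = 20
    min_strains: int = 4
    length_factor: float = 4.5
    grantham_threshold: int = 120
    seed: int = 0
    n_categories: int = 8
    fit_branch_lengths: bool = False
    fit_maxiter: int = 40
    max_attempts: int | None = None
    qc_tail: int = 50

    def __post_init__(self) -> None:
        for name in (
            "min_arm",
            "max_spacer",
            "n_null",
            "alpha",
            "score_diff_threshold",
            "branch_len_cutoff",
            "max_n",
            "min_strains",
            "length_factor",
            "grantham_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Placement:
    """One strain's IR instance mapped onto alignment columns."""

    ir: InvertedRepeat
    strain: str
    fp_interval: tuple[int, int]
    arm_cols: np.ndarray
    spacer_cols: np.ndarray
    fp_cols: np.ndarray
    control: ControlRegion | None = None


def _has_mnm(mask: np.ndarray, cols: np.ndarray) -> bool:
    """True when a >=2-run of substitutions touches ``cols``."""
    if cols.size == 0:
        return False
    n = mask.shape[0]
    m = mask[cols]
    left = np.where(cols - 1 >= 0, mask[np.maximum(cols - 1, 0)], False)
    right = np.where(cols + 1 < n, mask[np.minimum(cols + 1, n - 1)], False)
    return bool(np.any(m & (left | right)))


def layout_bins(
    alignment: CodonAlignment,
    strains: list[str],
    config: RunConfig,
) -> dict[int, list[Placement]]:
    """Detect, bin and column-map IRs per strain, then match controls.

    Controls are matched in alignment-column space, one per IR with the
    IR's arm length, nearest to the footprint, never intersecting any
    detected IR footprint of the sharing strains; identical IRs shared by
    several strains receive identical control positions. IRs whose
    footprint spans a gap get no control (they are QC-rejected anyway).
    """
    n_cols = alignment.length
    per_strain_bins: dict[str, dict[int, list[InvertedRepeat]]] = {}
    forbidden: dict[str, list[tuple[int, int]]] = {}
    colmaps: dict[str, np.ndarray] = {}
    gap_free_rows: dict[str, np.ndarray] = {}
    for strain in strains:
        row = alignment.row(strain)
        ungapped, colmap = row.ungap_with_map()
        colmaps[strain] = colmap
        gap_free_rows[strain] = (
            np.frombuffer(row.residues.encode(), dtype="S1") != b"-"
        )
        irs = find_perfect_irs(
            ungapped, min_arm=config.min_arm, max_spacer=config.max_spacer
        )
        irs = [
            InvertedRepeat(strain, ir.left_start, ir.arm_len, ir.spacer_len)
            for ir in irs
        ]
        per_strain_bins[strain] = bin_and_deduplicate(irs)
        forbidden[strain] = [
            (int(colmap[ir.footprint[0]]), int(colmap[ir.footprint[1] - 1]) + 1)
            for ir in irs
        ]

    bins: dict[int, list[Placement]] = {}
    for strain in strains:
        colmap = colmaps[strain]
        for arm, irs in per_strain_bins[strain].items():
            for ir in irs:
                (l0, l1), (s0, s1), (r0, r1) = ir.left_arm, ir.spacer, ir.right_arm
                arm_cols = np.concatenate([colmap[l0:l1], colmap[r0:r1]])
                spacer_cols = colmap[s0:s1]
                fp_cols = colmap[l0:r1]
                bins.setdefault(arm, []).append(
                    Placement(
                        ir=ir,
                        strain=strain,
                        fp_interval=(int(fp_cols[0]), int(fp_cols[-1]) + 1),
                        arm_cols=arm_cols,
                        spacer_cols=spacer_cols,
                        fp_cols=fp_cols,
                    )
                )

    # control matching, per bin, shared positions for identical IRs
    for arm, placements in bins.items():
        groups: dict[tuple[int, int, int], list[Placement]] = {}
        for p in placements:
            key = (p.fp_interval[0], p.ir.arm_len, p.ir.spacer_len)
            groups.setdefault(key, []).append(p)
        for key in sorted(groups):
            members = groups[key]
            contiguous = all(
                p.fp_cols.size == p.fp_interval[1] - p.fp_interval[0]
                for p in members
            )
            if not contiguous:
                continue  # footprint spans a gap: no control, logged upstream
            sharers = sorted({p.strain for p in members})
            fb = sorted({fp for s in sharers for fp in forbidden[s]})
            gap_free = np.ones(n_cols, dtype=bool)
            for s in sharers:
                gap_free &= gap_free_rows[s]
            hit = nearest_control_start(
                members[0].ir.arm_len,
                members[0].fp_interval,
                n_cols,
                fb,
                gap_free,
            )
            if hit is None:
                continue
            for p in members:
                p.control = ControlRegion(
                    seq_id=p.strain,
                    start=hit[0],
                    length=p.ir.arm_len,
                    distance=hit[1],
                )
    return bins


def needed_codon_columns(
    bins: dict[int, list[Placement]], n_cols: int
) -> np.ndarray:
    """Codon columns the counting reads: footprints, controls, +-1 base."""
    nt: set[int] = set()
    for placements in bins.values():
        for p in placements:
            lo, hi = p.fp_interval
            nt.update(range(max(0, lo - 1), min(n_cols, hi + 1)))
            if p.control is not None:
                c0, c1 = p.control.interval
                nt.update(range(max(0, c0 - 1), min(n_cols, c1 + 1)))
    return np.unique(np.asarray(sorted(nt), dtype=int) // 3)


def terminal_masks_from_states(
    alignment: CodonAlignment,
    tree: PhyloTree,
    strains: list[str],
    states: dict[str, np.ndarray],
    codon_cols: np.ndarray,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Per-strain substitution masks vs the reconstructed parent.

    ``states`` hold codon indices at ``codon_cols`` only; outside those
    columns the parent row is taken equal to the child (no substitution),
    which is exact for every column the counting reads.
    """
    masks: dict[str, np.ndarray] = {}
    ancestors: dict[str, str] = {}
    for strain in strains:
        parent_label = tree.parent_label(strain)
        child = alignment.row(strain).residues
        if parent_label not in ancestors:
            row = list(child)
            st = states[parent_label]
            for k, ci in enumerate(codon_cols):
                codon = "---" if st[k] < 0 else SENSE_CODONS[st[k]]
                row[3 * ci : 3 * ci + 3] = codon
            ancestors[parent_label] = "".join(row)
        else:
            # parent string was built from another child: rebuild per child
            row = list(child)
            st = states[parent_label]
            for k, ci in enumerate(codon_cols):
                codon = "---" if st[k] < 0 else SENSE_CODONS[st[k]]
                row[3 * ci : 3 * ci + 3] = codon
        masks[strain] = substitution_mask(child, "".join(row))
    return masks, ancestors


def _bin_counts(
    placements: list[Placement],
    masks: dict[str, np.ndarray],
    excluded_strains: set[str],
    qc=None,
) -> tuple[tuple[int, int, int, int], list[Placement], int]:
    """(a, b, c, d), the QC-kept arm-MNM placements, and the number of
    instances dropped for missing controls."""
    a = b = c = d = 0
    hits: list[Placement] = []
    missing = 0
    for p in placements:
        if p.strain in excluded_strains:
            continue
        if p.control is None:
            missing += 1
            continue
        mask = masks[p.strain]
        arm_mnm = _has_mnm(mask, p.arm_cols)
        if arm_mnm and qc is not None and not qc(p):
            continue
        if arm_mnm:
            a += 1
            hits.append(p)
        else:
            b += 1
        c0, c1 = p.control.interval
        if _has_mnm(mask, np.arange(c0, c1)):
            c += 1
        else:
            d += 1
    return (a, b, c, d), hits, missing


@dataclass
class GeneReport:
    gene: str
    n_strains: int = 0
    skipped: str | None = None
    params: CodonModelParams | None = None
    bins: list[IRScoreResult] = field(default_factory=list)
    tested_bins: list[int] = field(default_factory=list)
    untestable_bins: list[int] = field(default_factory=list)
    associations: list[IRAssociation] = field(default_factory=list)
    events: list[TemplateSwitchEvent] = field(default_factory=list)
    consequences: list[EventConsequences] = field(default_factory=list)
    rejections: list[dict] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return any(r.significant for r in self.bins)


def _reconstruct_restricted(
    tree: PhyloTree,
    alignment: CodonAlignment,
    model: MixtureModel,
    codon_cols: np.ndarray,
    parent_labels: list[str],
) -> dict[str, np.ndarray]:
    codes, taxa = encode_alignment(alignment, tree.leaf_labels)
    states, _, _ = reconstruct_codes(
        tree, codes[:, codon_cols], taxa, model, nodes=parent_labels
    )
    return states


def analyze_gene(
    gene: str,
    alignment: CodonAlignment,
    tree: PhyloTree,
    config: RunConfig,
    seed: int = 0,
    params: CodonModelParams | None = None,
    significance: bool = True,
) -> GeneReport:
    """Run the full per-gene analysis; see the module docstring.

    ``significance=False`` stops after association/classification (no
    null sets), for recovery-style runs that only need event calls.
    """
    report = GeneReport(gene=gene)
    outgroup = tree.outgroup
    strain_rows = [t for t in alignment if t.id != outgroup]
    kept = prefilter_orthoset(
        strain_rows, max_n=config.max_n, min_strains=config.min_strains
    )
    if not kept:
        report.skipped = "prefilter"
        return report
    keep_ids = {s.id for s in kept} | ({outgroup} if outgroup else set())
    if len(keep_ids) < len(alignment.ids):
        alignment = CodonAlignment([t for t in alignment if t.id in keep_ids])
        tree = tree.prune_to(sorted(keep_ids))
    if alignment.has_internal_stop():
        report.skipped = "immature_stop"
        return report
    strains = sorted(s.id for s in kept)
    report.n_strains = len(strains)

    bins = layout_bins(alignment, strains, config)
    if not bins:
        return report

    if params is None:
        fit = fit_parameters(
            tree,
            alignment,
            optimize_branch_lengths=config.fit_branch_lengths,
            n_categories=config.n_categories,
            maxiter=config.fit_maxiter,
        )
        params, tree = fit.params, fit.tree
    report.params = params
    model = MixtureModel(params)

    parent_labels = sorted({tree.parent_label(s) for s in strains})
    codon_cols = needed_codon_columns(bins, alignment.length)
    states = _reconstruct_restricted(tree, alignment, model, codon_cols, parent_labels)
    masks, ancestors = terminal_masks_from_states(
        alignment, tree, strains, states, codon_cols
    )
    excluded = {
        s
        for s in strains
        if tree.terminal_branch_length(s) > config.branch_len_cutoff
    }
    for s in sorted(excluded):
        report.rejections.append({"strain": s, "reason": "branch_length"})

    def make_qc(aln, anc):
        def qc(p: Placement) -> bool:
            assoc = IRAssociation(ir=p.ir, taxon=p.strain)
            verdict = qc_filter(
                assoc,
                aln,
                tree,
                anc,
                branch_len_cutoff=config.branch_len_cutoff,
                score_diff_threshold=config.score_diff_threshold,
                tail=config.qc_tail,
            )
            if not verdict.keep:
                report.rejections.append(
                    {
                        "strain": p.strain,
                        "ir": p.ir.footprint,
                        "reason": verdict.reason,
                    }
                )
            return verdict.keep

        return qc

    real_qc = make_qc(alignment, ancestors)
    rng_root = np.random.SeedSequence(seed)
    for arm in sorted(bins):
        placements = bins[arm]
        counts, hits, missing = _bin_counts(placements, masks, excluded, qc=real_qc)
        a, b, c, d = counts
        result = IRScoreResult(
            gene=gene,
            arm_len=arm,
            counts=counts,
            score=compute_ir_score(a, b, c, d),
            n_controls_missing=missing,
        )
        if a == 0 or not significance:
            # no QC-passing IR/MNM association: the score cannot clear the
            # upper tail, so the bin is not simulated (untested)
            report.bins.append(result)
            continue
        try:
            null = build_null_set(
                alignment,
                tree,
                params,
                arm,
                n_null=config.n_null,
                length_factor=config.length_factor,
                max_attempts=config.max_attempts,
                min_arm=config.min_arm,
                max_spacer=config.max_spacer,
                seed=int(rng_root.generate_state(1)[0] % (2**31)) + arm,
                outgroup=outgroup,
            )
        except NullSetError as exc:
            logger.warning("gene %s arm %d: %s", gene, arm, exc)
            report.untestable_bins.append(arm)
            report.bins.append(result)
            continue
        result.null_scores = _null_scores(
            null.replicates, tree, model, strains, excluded, config, arm
        )
        result.finalize(alpha=config.alpha)
        report.tested_bins.append(arm)
        report.bins.append(result)

    _classify_events(
        report, gene, alignment, tree, strains, masks, ancestors, excluded, bins,
        config,
    )
    return report


def _null_scores(
    replicates: list[CodonAlignment],
    tree: PhyloTree,
    model: MixtureModel,
    strains: list[str],
    excluded: set[str],
    config: RunConfig,
    arm: int,
    batch_codons: int = 4000,
) -> list[float]:
    """IR scores of the null replicates for one arm bin, with ancestral
    reconstruction batched across replicates."""
    parent_labels = sorted({tree.parent_label(s) for s in strains})
    layouts = []
    for aln in replicates:
        bins = layout_bins(aln, strains, config)
        cols = needed_codon_columns(bins, aln.length)
        layouts.append((aln, bins, cols))
    scores: list[float] = []
    i = 0
    while i < len(layouts):
        j, total = i, 0
        while j < len(layouts) and (
            total == 0 or total + layouts[j][2].size <= batch_codons
        ):
            total += layouts[j][2].size
            j += 1
        batch = layouts[i:j]
        codes_list = []
        taxa = tree.leaf_labels
        for aln, _, cols in batch:
            codes, taxa = encode_alignment(aln, taxa)
            codes_list.append(codes[:, cols])
        cat = np.concatenate(codes_list, axis=1)
        states_cat, _, _ = reconstruct_codes(
            tree, cat, taxa, model, nodes=parent_labels
        )
        off = 0
        for (aln, bins, cols), codes in zip(batch, codes_list):
            k = codes.shape[1]
            states = {lab: st[off : off + k] for lab, st in states_cat.items()}
            off += k
            masks, ancestors = terminal_masks_from_states(
                aln, tree, strains, states, cols
            )
            qc = _silent_qc(aln, tree, ancestors, config)
            counts, _, _ = _bin_counts(bins.get(arm, []), masks, excluded, qc=qc)
            scores.append(compute_ir_score(*counts))
        i = j
    return scores


def _silent_qc(aln, tree, ancestors, config):
    def qc(p: Placement) -> bool:
        assoc = IRAssociation(ir=p.ir, taxon=p.strain)
        return qc_filter(
            assoc,
            aln,
            tree,
            ancestors,
            branch_len_cutoff=config.branch_len_cutoff,
            score_diff_threshold=config.score_diff_threshold,
            tail=config.qc_tail,
        ).keep

    return qc


def _classify_events(
    report: GeneReport,
    gene: str,
    alignment: CodonAlignment,
    tree: PhyloTree,
    strains: list[str],
    masks: dict[str, np.ndarray],
    ancestors: dict[str, str],
    excluded: set[str],
    bins: dict[int, list[Placement]],
    config: RunConfig,
) -> None:
    """Build associations and classify template-switch events per IR."""
    for arm in sorted(bins):
        for p in bins[arm]:
            if p.strain in excluded:
                continue
            mask = masks[p.strain]
            arm_mnm = _has_mnm(mask, p.arm_cols)
            spacer_mnm = _has_mnm(mask, p.spacer_cols)
            if not (arm_mnm or spacer_mnm):
                continue
            child_full = alignment.row(p.strain).residues
            parent_full = ancestors[tree.parent_label(p.strain)]
            assoc = IRAssociation(ir=p.ir, taxon=p.strain)
            fp0, fp1 = p.fp_interval
            sub_cols = np.flatnonzero(mask)
            for s, e in runs_of_true(mask):
                ev = MNMEvent(
                    taxon=p.strain,
                    start=s,
                    end=e,
                    parent_alleles=parent_full[s:e],
                    child_alleles=child_full[s:e],
                )
                if np.isin(np.arange(s, e), p.arm_cols).any():
                    assoc.mnms_on_arms.append(ev)
                if p.spacer_cols.size and np.isin(np.arange(s, e), p.spacer_cols).any():
                    assoc.mnms_on_spacer.append(ev)
            report.associations.append(assoc)
            if p.fp_cols.size != fp1 - fp0:
                continue  # gapped footprint: not classifiable
            parent_region = parent_full[fp0:fp1]
            child_region = child_full[fp0:fp1]
            if "-" in parent_region or "-" in child_region:
                continue
            rel_ir = InvertedRepeat(p.strain, 0, p.ir.arm_len, p.ir.spacer_len)
            event = classify_event(
                parent_region, child_region, rel_ir, gene=gene, taxon=p.strain
            )
            if event is None:
                continue
            ev_cols = [int(c) for c in sub_cols if fp0 <= c < fp1]
            cons = aa_consequences(parent_full, child_full, ev_cols, frame=0)
            event.aa_changes = [
                (r.position, r.from_aa, r.to_aa) for r in cons.replacements
            ]
            report.events.append(event)
            report.consequences.append(cons)


# ---------------------------------------------------------------------------
# directory-level driver


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    reports: list[GeneReport]
    manifest: dict

    @property
    def significant_genes(self) -> list[str]:
        return [r.gene for r in self.reports if r.significant]


def run_pipeline(
    config: RunConfig,
    genes_dir,
    tree_file,
    outgroup: str,
    out_dir=None,
) -> RunResult:
    """Analyze every per-gene FASTA in ``genes_dir`` against the tree.

    Per-gene failures are isolated and logged; nothing is skipped
    silently. With ``out_dir``, writes the score/association/event tables
    (TSV), the per-gene verdicts and a manifest with config, input hashes
    and per-gene seeds.
    """
    genes_dir = Path(genes_dir)
    tree_file = Path(tree_file)
    tree = PhyloTree.from_newick(str(tree_file), outgroup=outgroup)
    fasta_files = sorted(genes_dir.glob("*.fasta")) + sorted(genes_dir.glob("*.fa"))
    reports: list[GeneReport] = []
    manifest: dict = {
        "config": asdict(config),
        "tree": _sha256(tree_file),
        "outgroup": outgroup,
        "genes": {},
    }
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(max(len(fasta_files), 1)) % (2**31)
    if not fasta_files:
        logger.warning("no gene FASTA files found in %s", genes_dir)
    for path, gene_seed in zip(fasta_files, seeds):
        gene = path.stem
        entry = {"sha256": _sha256(path), "seed": int(gene_seed)}
        try:
            alignment = CodonAlignment.from_fasta(path)
            gene_tree = tree
            taxa = set(alignment.ids)
            if taxa != set(tree.leaf_labels):
                gene_tree = tree.prune_to(sorted(taxa & set(tree.leaf_labels)))
                alignment = CodonAlignment(
                    [t for t in alignment if t.id in set(gene_tree.leaf_labels)]
                )
            report = analyze_gene(
                gene, alignment, gene_tree, config, seed=int(gene_seed)
            )
            entry["status"] = report.skipped or "ok"
            entry["significant"] = report.significant
        except Exception as exc:  # noqa: BLE001 - per-gene isolation
            logger.exception("gene %s failed", gene)
            report = GeneReport(gene=gene, skipped=f"error: {exc}")
            entry["status"] = "error"
            entry["error"] = str(exc)
        manifest["genes"][gene] = entry
        reports.append(report)
    result = RunResult(reports=reports, manifest=manifest)
    if out_dir is not None:
        write_report_bundle(result, out_dir)
    return result


def write_report_bundle(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    score_rows, assoc_rows, event_rows = [], [], []
    for r in result.reports:
        for b in r.bins:
            score_rows.append(
                {
                    "gene": r.gene,
                    "arm_len": b.arm_len,
                    "irs_with_mnm": b.counts[0],
                    "irs_without_mnm": b.counts[1],
                    "controls_with_mnm": b.counts[2],
                    "controls_without_mnm": b.counts[3],
                    "score": b.score,
                    "tested": b.arm_len in r.tested_bins,
                    "empirical_p": b.empirical_p,
                    "significant": b.significant,
                }
            )
        for a in r.associations:
            assoc_rows.append(
                {
                    "gene": r.gene,
                    "strain": a.taxon,
                    "arm_len": a.ir.arm_len,
                    "spacer_len": a.ir.spacer_len,
                    "left_start": a.ir.left_start,
                    "n_arm_mnms": len(a.mnms_on_arms),
                    "n_spacer_mnms": len(a.mnms_on_spacer),
                }
            )
        for e, cons in zip(r.events, r.consequences):
            event_rows.append(
                {
                    "gene": e.gene,
                    "strain": e.taxon,
                    "kind": e.kind,
                    "arm_len": e.ir.arm_len,
                    "spacer_len": e.ir.spacer_len,
                    "n_substitutions": e.n_substitutions,
                    "arm_diffs": e.arm_diffs,
                    "spacer_diffs": e.spacer_diffs,
                    "span_class": cons.span_class,
                    "synonymous_only": cons.synonymous_only,
                    "aa_changes": ";".join(
                        f"{f}{pos}{t}" for pos, f, t in e.aa_changes
                    ),
                }
            )
    pd.DataFrame(score_rows).to_csv(out / "ir_scores.tsv", sep="\t", index=False)
    pd.DataFrame(assoc_rows).to_csv(out / "associations.tsv", sep="\t", index=False)
    pd.DataFrame(event_rows).to_csv(out / "events.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
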