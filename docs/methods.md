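# Methods

`tswitch` detects DNA-polymerase template-switching events between the
arms of short inverted repeats (IRs) in coding genes, from per-gene codon
alignments and a rooted species tree. This note documents the models,
the decision rules, the synthetic benchmark and the numerical choices.

## Inverted-repeat detection

A perfect IR is a left arm `[i, i+k)`, a spacer `[i+k, i+k+L)` and a
right arm `[i+k+L, i+2k+L)` with the right arm equal to the exact
reverse complement of the left. Only **maximal** IRs are reported: the
arms can be extended neither outward (the flanking pair does not
complement, or a sequence end intervenes) nor inward (the outermost
spacer bases do not complement; spacers of length 0 or 1 cannot extend
inward). `N` never pairs. Defaults follow the study design: arm length
≥ 7 bp, spacer ≤ 70 bp.

The production finder scans anti-diagonals of the base-pairing matrix
(every arm pair of one IR centre has constant index sum), which
vectorizes over a bounded window; a candidate run that reaches the
window floor (arms beyond ~64 bp) is finished by direct scanning. The
test suite holds this implementation to exact agreement with an
independent brute-force triple enumeration.

Per strain, each maximal IR is binned by its arm length and every bin is
analyzed separately. Within a bin, IRs with partially overlapping
footprints are all discarded; fully nested pairs are both kept.

## Codon model

Substitutions follow a GY94-type codon model: for codons differing at
exactly one nucleotide,

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-nucleotide codon changes, diagonal set so rows sum to 0.
The nonsynonymous/synonymous ratio omega varies across sites with a
Gamma(alpha, beta) distribution (the M5 parameterization), discretized
into `n_categories` equal-probability bins represented by their means
(8 by default; the synthetic studies below use 4, which at their gene
lengths changes fitted likelihoods negligibly). One shared scaling
constant normalizes the category generators so the *mixture* expects one
substitution per codon site per unit branch length; all branch lengths
are in these units, including the 0.2 saturation cutoff.

Codon frequencies default to F3×4 (empirical per-position nucleotide
frequencies, stops excluded, floored at 1e-4 and renormalized).
Likelihoods come from Felsenstein pruning with per-node rescaling;
transition matrices are computed by eigendecomposition of the
symmetrized reversible generator, with `expm` as a fallback. Gaps, `N`
and (defensively) stop codons are missing data: their partial
likelihood is 1 over all 61 sense codons.

`fit_parameters` maximizes the likelihood over (kappa, alpha, beta) —
optionally also branch lengths — by bounded L-BFGS-B in log space
(bounds 0.05–50). Ancestral sequences are **marginal** reconstructions:
per internal node and site, the posterior over the 61 codons given all
leaves, mixed over omega categories with their data-dependent weights;
the reported state is the argmax. Site marginals are independent, so
reconstruction may be restricted to any column subset exactly — the
pipeline exploits this by reconstructing only the columns the counting
reads (IR footprints, controls, one flanking base), and by batching the
restricted columns of all null replicates into single pruning passes.

## MNM calling and association

An MNM is a maximal run of ≥ 2 strictly contiguous substituted columns
between a strain and its reconstructed immediate parent. Gap or `N`
columns never substitute and always break a run; changes on different
branches never join; only terminal branches are scanned. No posterior
threshold is applied to the reconstruction (posteriors are carried for
reporting). An IR is arm-associated when ≥ 1 MNM column of the same
strain falls in either arm, spacer-associated likewise; both labels are
possible.

Quality control, applied to MNM-bearing IRs: (i) terminal branches
longer than 0.2 are saturated and excluded; (ii) IR regions with an
indel between strain and parent are excluded; (iii) the IR region plus a
50-bp downstream tail is re-aligned globally between the strain and its
sister taxon (nearest leaf by patristic distance) twice — as nucleotides
and as indivisible codon triplets, both scored match +1 / mismatch −1 /
gap 0 per base — and the IR is excluded when the two scores differ by
more than 15, the signature of a frameshifted, untrustworthy codon MSA.
An optional per-column alignment-confidence track (e.g. from an external
alignment-confidence tool) is screened at 0.95 when provided.

## Controls, IR score and significance

Each IR receives one control: the nearest window of length equal to the
arm length that intersects no detected IR footprint and no gap, ties
resolved to the 5′ side; identical IRs shared by several strains get the
control at the same position in each. IRs without an admissible control
(or with a gapped footprint) are dropped from scoring with a logged
reason, so control and IR counts always match.

Per gene and arm-length bin, with a = IRs whose arms carry an MNM,
b = IRs without, c/d the same for controls:

    IR score = [(a + 1) / (b + 1)] / [(c + 1) / (d + 1)].

Spacer-only overlaps are *not* counted in `a`; they are handled by the
inversion pathway below. The null distribution is built from simulated
alignments: root sequences drawn from the stationary distribution with
length `length_factor` (default 4.5, configurable in [4, 5]) times the
outgroup's, evolved along the fixed tree under the fitted parameters,
and accepted only if the replicate's bin IR count is at least the real
count, until 100 replicates accumulate (an error names the bin when the
attempt budget — 50 × n_null — is exhausted, the expected outcome for
long arms that simulations cannot produce). Each replicate is scored by
the identical counting path. Significance is the add-one upper-tail
empirical rank, p = (#{null ≥ real} + 1)/(n_null + 1), ties counted
toward the null; a bin is significant at p ≤ 0.05.

Bins in which no QC-passing arm/MNM association exists (a = 0) skip the
simulation stage entirely: with a = 0 the real score is ≤ 1 up to the
missing-control margin while well over half the null replicates score
≥ 1, so p can never reach 0.05. This mirrors the study design — only
genes with IR-associated MNMs entered the significance stage — and is
what keeps the 200-gene calibration run affordable.

## Inversion classification and protein effects

For each MNM-bearing IR, the parent and child footprints are compared:
child spacer equal to the reverse complement of the parent spacer (and
different from it) ⇒ **spacer inversion**; parent arms imperfect as a
pair while the child IR is perfect ⇒ **arm homogenization**; both ⇒
**combined**. Only complete spacer inversions count — partial
reverse-complement matches remain ordinary MNMs. Whether the parent
already carried perfect arms is recorded but not required. Recurring
events are tallied by (gene, footprint, kind) over distinct strains.

Substitutions are translated per codon: replacement lists with Grantham
physicochemical distances (the embedded 1974 table, range 5–215, mean
≈ 100; distances above 120 flagged "high"), a codon-span class
(one codon / two neighbouring codons / more), a synonymous-only label,
and transition/transversion tallies (A↔G, C↔T transitions; ratio
reported as infinite when no transversions occur).

## Synthetic data

The generator emulates the study's inputs at desk scale: a clock-free
rooted binary ingroup (random joins; branch lengths exponential with
mean 0.04, clipped to [0.01, 0.12]) plus one outgroup on a 0.25 branch;
gap-free in-frame codon alignments evolved under M5 with yeast-flavoured
defaults (kappa 2.5, omega ~ Gamma(0.8, 4), AT-rich F3×4 frequencies);
and optional planted events. The studies use 10 ingroup taxa and
100-codon genes (the pipeline itself has no such limits).

Events are planted post hoc on terminal branches: the ancestral IR
(perfect for inversions; one arm broken over a ≥ 2-base contiguous run
for homogenizations) is written into the root, its footprint held
invariant during simulation — strong local constraint — and the leaf
copy is then overwritten (arm replaced by the reverse complement of the
other, or spacer inverted). The parent node therefore provably retains
the ancestral form, and the terminal branch carries exactly the planted
change; every change is recorded in a ground-truth ledger that the
recovery tests audit.

What the generator does **not** emulate: indels and alignment error
(the real pipeline's QC exists for these but is exercised only on
constructed cases), rate variation beyond M5, base-composition
heterogeneity along the gene, and selection on the planted events.
Passing tests therefore demonstrate the machinery's correctness and
calibration under the model, not robustness to misalignment.

## Calibration behaviour

On 200 event-free genes the pipeline flags ~1–3% (the acceptance band is
1–10%). The test is deliberately conservative: null replicates are 4.5×
longer than the real gene and conditioned on carrying at least as many
IRs, so a real single-hit score (driven by small counts and pseudo-
counts) beats null single-hit scores, while the add-one empirical p and
tie handling push the other way. Raw per-bin p values are reported with
no multiple-testing correction across genes (none is applied upstream;
flagged here as a known property of the procedure).

## Reproducibility

Every stochastic step takes a seed; per-gene and per-replicate seeds
derive from the master seed via `SeedSequence` spawning and are logged
(null-set ledgers record per-attempt acceptance). Reruns with the same
seed are byte-identical. The pipeline manifest stores the config, input
hashes and per-gene seeds.

## Known limitations

- MNMs on internal branches are detected nowhere (by design: terminal
  branches only); non-contiguous mutation clusters are not MNMs.
- Pure spacer inversions do not enter the arm IR score; their
  significance is not separately tested (the event catalogue reports
  them, and planted-inversion recovery is exercised directly).
- Imperfect (mismatched-arm) IR detection and direct repeats are out of
  scope.
- The codon/nucleotide score check assumes the sister taxon is a
  reasonable proxy for local alignment quality; when the true sister is
  a clade, the nearest leaf is used.
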