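"""GY94-type codon substitution model with gamma-distributed omega (M5).

The model assigns rate ``q_ij = pi_j * kappa^[transition] * omega^[nonsyn]``
to codon pairs differing at exactly one nucleotide (zero otherwise), with
``omega`` drawn per site from a discretized Gamma(shape, rate) — the mean
of each of ``n_categories`` equal-probability quantile bins. Branch lengths
are expected substitutions per codon site: the per-category generators
share one scaling constant so the *mixture* rate at stationarity is 1.

Provides Felsenstein-pruning log-likelihood over the category mixture,
bounded ML estimation of (kappa, shape, rate) and optionally branch
lengths, and marginal ancestral reconstruction (per-node, per-site
posteriors over the 61 sense codons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .core_seq import (
    CODON_INDEX,
    CODON_TO_AA,
    CodonAlignment,
    SENSE_CODONS,
)

N_CODONS = len(SENSE_CODONS)  # 61

# ---------------------------------------------------------------------------
# static pair classification over the sense-codon space


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masks over 61x61 codon pairs differing at exactly one nucleotide."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    purines = {"A", "G"}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in purines) == (b in purines)
            nonsyn[i, j] = CODON_TO_AA[ci] != CODON_TO_AA[cj]
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _pair_tables()


@dataclass(frozen=True)
class CodonModelParams:
    """M5 parameters: kappa plus Gamma(omega_shape, omega_rate) for omega."""

    kappa: float = 2.0
    omega_shape: float = 1.0
    omega_rate: float = 3.0
    n_categories: int = 8
    codon_freqs: np.ndarray = field(
        default_factory=lambda: np.full(N_CODONS, 1.0 / N_CODONS)
    )

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega_shape <= 0 or self.omega_rate <= 0:
            raise ValueError("kappa, omega_shape and omega_rate must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        freqs = np.asarray(self.codon_freqs, dtype=float)
        if freqs.shape != (N_CODONS,) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("codon_freqs must be 61 values summing to 1")
        object.__setattr__(self, "codon_freqs", freqs)

    @property
    def mean_omega(self) -> float:
        return self.omega_shape / self.omega_rate


def discretize_omega(shape: float, rate: float, n_categories: int) -> np.ndarray:
    """Means of equal-probability Gamma quantile bins."""
    if n_categories == 1:
        return np.array([shape / rate])
    k = np.arange(n_categories + 1) / n_categories
    cuts = gamma_dist.ppf(k, a=shape, scale=1.0 / rate)
    upper = gamma_dist.cdf(cuts, a=shape + 1, scale=1.0 / rate)
    return n_categories * (shape / rate) * np.diff(upper)


def f3x4_frequencies(alignment: CodonAlignment, floor: float = 1e-4) -> np.ndarray:
    """Empirical codon frequencies from per-codon-position nucleotide counts."""
    counts = np.full((3, 4), floor)
    order = "ACGT"
    for row in alignment:
        s = row.residues
        for i in range(0, len(s) - 2, 3):
            for pos in range(3):
                ch = s[i + pos]
                if ch in order:
                    counts[pos, order.index(ch)] += 1
    counts /= counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            counts[0, order.index(c[0])]
            * counts[1, order.index(c[1])]
            * counts[2, order.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    return freqs / freqs.sum()


def build_rate_matrix(
    params: CodonModelParams, omega_value: float, scale: bool = True
) -> np.ndarray:
    """61x61 GY94 generator for one omega value (rows sum to zero).

    With ``scale=True`` the generator is normalized to one expected
    substitution per codon site at stationarity.
    """
    if omega_value < 0:
        raise ValueError("omega must be non-negative")
    pi = params.codon_freqs
    Q = np.where(_SINGLE, pi[None, :], 0.0)
    Q = np.where(_TRANSITION, Q * params.kappa, Q)
    Q = np.where(_NONSYN, Q * omega_value, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = -np.dot(pi, np.diag(Q))
        if rate > 0:
            Q = Q / rate
    return Q


# ---------------------------------------------------------------------------
# tree


class PhyloTree:
    """Rooted tree with indexed arrays for pruning.

    Nodes are integers; ``postorder`` visits children before parents.
    Branch lengths are expected substitutions per codon site. Leaf labels
    must match alignment taxa.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        labels: list[str],
        is_leaf: np.ndarray,
        outgroup: str | None = None,
    ):
        self.parent = parent
        self.lengths = lengths
        self.labels = labels
        self.is_leaf = is_leaf
        self.outgroup = outgroup
        if np.any(lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        n = len(parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            if parent[v] >= 0:
                self.children[parent[v]].append(v)
        self.root = int(np.flatnonzero(parent < 0)[0])
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.preorder = np.array(order)
        self.postorder = self.preorder[::-1].copy()
        self.leaf_index = {labels[v]: v for v in range(n) if is_leaf[v]}
        if outgroup is not None and outgroup not in self.leaf_index:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[v] for v in range(self.n_nodes) if self.is_leaf[v]]

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(),
            np.asarray(lengths, dtype=float),
            list(self.labels),
            self.is_leaf.copy(),
            self.outgroup,
        )

    def terminal_branch_length(self, taxon: str) -> float:
        return float(self.lengths[self.leaf_index[taxon]])

    def parent_label(self, taxon: str) -> str:
        return self.labels[self.parent[self.leaf_index[taxon]]]

    def _depths(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def patristic_distance(self, a: str, b: str) -> float:
        va, vb = self.leaf_index[a], self.leaf_index[b]
        anc_a = {}
        v, dist = va, 0.0
        while v >= 0:
            anc_a[v] = dist
            dist += self.lengths[v]
            v = self.parent[v]
        v, dist = vb, 0.0
        while v not in anc_a:
            dist += self.lengths[v]
            v = self.parent[v]
        return dist + anc_a[v]

    def closest_leaf(self, taxon: str, exclude: set[str] | None = None) -> str | None:
        """The sister taxon proxy: nearest other leaf by patristic distance."""
        exclude = (exclude or set()) | {taxon}
        best, best_d = None, np.inf
        for other in self.leaf_labels:
            if other in exclude:
                continue
            d = self.patristic_distance(taxon, other)
            if d < best_d or (d == best_d and (best is None or other < best)):
                best, best_d = other, d
        return best

    def prune_to(self, taxa: list[str]) -> "PhyloTree":
        """Restrict to a taxon subset (unifurcations suppressed, their
        branch lengths summed)."""
        t = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        t.retain_taxa_with_labels(list(taxa))
        newick = t.as_string(schema="newick", suppress_rooting=True)
        outgroup = self.outgroup if self.outgroup in set(taxa) else None
        return PhyloTree.from_newick(newick, outgroup=outgroup)

    # -- newick I/O (via dendropy) ------------------------------------

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "PhyloTree":
        if "(" not in newick:  # treat as a path
            with open(newick) as fh:
                newick = fh.read()
        t = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nodes = list(t.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        labels: list[str] = []
        is_leaf = np.zeros(n, dtype=bool)
        n_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                is_leaf[i] = True
                labels.append(nd.taxon.label if nd.taxon else f"leaf{i}")
            else:
                lbl = nd.label if nd.label else f"node{n_internal}"
                labels.append(lbl)
                n_internal += 1
        return cls(parent, lengths, labels, is_leaf, outgroup)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if self.is_leaf[v]:
                core = self.labels[v]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
                core += self.labels[v]
            if self.parent[v] >= 0:
                core += f":{self.lengths[v]:.6g}"
            return core

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# likelihood machinery


def encode_alignment(
    alignment: CodonAlignment, taxa: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Codon codes per taxon: (n_taxa, n_sites) int16, -1 = missing.

    Codons containing gaps or ``N`` (and, defensively, stop codons) are
    treated as missing data.
    """
    taxa = taxa or alignment.ids
    n_sites = alignment.length // 3
    codes = np.full((len(taxa), n_sites), -1, dtype=np.int16)
    for r, taxon in enumerate(taxa):
        s = alignment.row(taxon).residues
        for k in range(n_sites):
            codes[r, k] = CODON_INDEX.get(s[3 * k : 3 * k + 3], -1)
    return codes, taxa


class MixtureModel:
    """Per-category generators and transition matrices for one parameter set."""

    def __init__(self, params: CodonModelParams):
        self.params = params
        self.pi = params.codon_freqs
        self.omegas = discretize_omega(
            params.omega_shape, params.omega_rate, params.n_categories
        )
        Qs = [build_rate_matrix(params, w, scale=False) for w in self.omegas]
        rates = [-np.dot(self.pi, np.diag(Q)) for Q in Qs]
        self.scale = float(np.mean(rates))
        self.Qs = [Q / self.scale for Q in Qs]
        sqrt_pi = np.sqrt(self.pi)
        self._eigs = []
        for Q in self.Qs:
            B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
            B = (B + B.T) / 2.0
            try:
                lam, U = np.linalg.eigh(B)
                self._eigs.append((lam, U, sqrt_pi))
            except np.linalg.LinAlgError:  # pragma: no cover
                self._eigs.append(None)

    @property
    def n_categories(self) -> int:
        return len(self.omegas)

    def transition_matrix(self, t: float, category: int) -> np.ndarray:
        """P(t) for one omega category; rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        eig = self._eigs[category]
        if eig is None:  # fallback: scaling-and-squaring
            return expm(self.Qs[category] * t)
        lam, U, s = eig
        M = (U * np.exp(lam * t)) @ U.T
        P = (M / s[:, None]) * s[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def branch_matrices(self, tree: PhyloTree) -> np.ndarray:
        """(n_categories, n_nodes, 61, 61); identity at the root slot."""
        P = np.empty((self.n_categories, tree.n_nodes, N_CODONS, N_CODONS))
        for c in range(self.n_categories):
            for v in range(tree.n_nodes):
                if tree.parent[v] < 0:
                    P[c, v] = np.eye(N_CODONS)
                else:
                    P[c, v] = self.transition_matrix(tree.lengths[v], c)
        return P


def _leaf_partials(codes_row: np.ndarray) -> np.ndarray:
    S = codes_row.shape[0]
    F = np.zeros((S, N_CODONS))
    miss = codes_row < 0
    F[np.arange(S)[~miss], codes_row[~miss]] = 1.0
    F[miss] = 1.0
    return F


def _uppass(tree: PhyloTree, codes: np.ndarray, taxa: list[str], model: MixtureModel,
            P: np.ndarray):
    """Scaled conditional likelihoods; returns (F, M, cum) arrays."""
    K, S = model.n_categories, codes.shape[1]
    n = tree.n_nodes
    F = np.empty((n, K, S, N_CODONS))
    M = np.empty_like(F)
    cum = np.zeros((n, K, S))
    row_of = {t: r for r, t in enumerate(taxa)}
    for v in tree.postorder:
        if tree.is_leaf[v]:
            F[v] = _leaf_partials(codes[row_of[tree.labels[v]]])[None, :, :]
        else:
            Fv = np.ones((K, S, N_CODONS))
            for c in tree.children[v]:
                Fv *= M[c]
                cum[v] += cum[c]
            sc = Fv.max(axis=-1)
            sc[sc == 0] = 1.0
            Fv /= sc[..., None]
            cum[v] += np.log(sc)
            F[v] = Fv
        for k in range(K):
            M[v, k] = F[v, k] @ P[k, v].T
    return F, M, cum


def _site_logliks(tree, F, cum, pi, K):
    root = tree.root
    lik = np.einsum("ksj,j->ks", F[root], pi)
    with np.errstate(divide="ignore"):
        lw = np.log(lik) + cum[root]
    mx = lw.max(axis=0)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    site = safe + np.log(np.mean(np.exp(lw - safe[None, :]), axis=0))
    return site


def pruning_loglik(
    tree: PhyloTree,
    alignment: CodonAlignment,
    params: CodonModelParams,
    model: MixtureModel | None = None,
) -> float:
    """Log-likelihood of the alignment: site likelihoods averaged over the
    equal-weight omega categories, logs summed over sites."""
    model = model or MixtureModel(params)
    codes, taxa = encode_alignment(alignment, tree.leaf_labels)
    P = model.branch_matrices(tree)
    F, _, cum = _uppass(tree, codes, taxa, model, P)
    site = _site_logliks(tree, F, cum, model.pi, model.n_categories)
    if not np.all(np.isfinite(site)):
        warnings.warn("zero-probability site configuration; returning -inf")
        return -np.inf
    return float(site.sum())


@dataclass
class FitResult:
    params: CodonModelParams
    tree: PhyloTree
    loglik: float
    converged: bool


def fit_parameters(
    tree: PhyloTree,
    alignment: CodonAlignment,
    optimize_branch_lengths: bool = False,
    n_categories: int = 8,
    init: CodonModelParams | None = None,
    maxiter: int = 60,
) -> FitResult:
    """Bounded ML estimation of kappa and the omega-gamma parameters
    (optionally branch lengths) under F3x4 codon frequencies."""
    if len(tree.leaf_labels) < 2:
        raise ValueError("need at least 2 taxa")
    freqs = f3x4_frequencies(alignment)
    init = init or CodonModelParams(
        n_categories=n_categories, codon_freqs=freqs
    )
    codes, taxa = encode_alignment(alignment, tree.leaf_labels)
    lengths0 = np.maximum(tree.lengths, 1e-4)
    lengths0[tree.root] = 0.0

    branch_ids = (
        [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
        if optimize_branch_lengths
        else []
    )

    def unpack(x):
        kappa, shape, rate = np.exp(x[:3])
        params = CodonModelParams(
            kappa=kappa,
            omega_shape=shape,
            omega_rate=rate,
            n_categories=n_categories,
            codon_freqs=freqs,
        )
        lengths = lengths0.copy()
        if branch_ids:
            lengths[branch_ids] = np.exp(x[3:])
        return params, tree.with_lengths(lengths)

    def nll(x):
        params, t = unpack(x)
        model = MixtureModel(params)
        P = model.branch_matrices(t)
        F, _, cum = _uppass(t, codes, taxa, model, P)
        site = _site_logliks(t, F, cum, model.pi, model.n_categories)
        val = site.sum()
        return np.inf if not np.isfinite(val) else -float(val)

    x0 = np.log([init.kappa, init.omega_shape, init.omega_rate])
    bounds = [(np.log(0.05), np.log(50.0))] * 3
    if branch_ids:
        x0 = np.concatenate([x0, np.log(lengths0[branch_ids])])
        bounds += [(np.log(1e-6), np.log(5.0))] * len(branch_ids)
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
    )
    best = res.x if res.fun <= nll(x0) else x0
    params, fitted_tree = unpack(best)
    return FitResult(
        params=params,
        tree=fitted_tree,
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


@dataclass
class AncestralReconstruction:
    """Marginal reconstruction: per-internal-node argmax codon sequences
    plus per-site posterior maxima (and optionally full posteriors)."""

    sequences: dict[str, str]
    max_posterior: dict[str, np.ndarray]
    posteriors: dict[str, np.ndarray] | None = None
    columns: np.ndarray | None = None  # codon columns reconstructed

    def parent_sequence_of(self, tree: PhyloTree, taxon: str) -> str:
        return self.sequences[tree.parent_label(taxon)]


def reconstruct_codes(
    tree: PhyloTree,
    codes: np.ndarray,
    taxa: list[str],
    model: MixtureModel,
    nodes: list[str] | None = None,
    include_posteriors: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Marginal reconstruction on raw codon codes.

    Returns ``(states, max_posterior, posteriors)`` keyed by internal-node
    label; states are codon indices with -1 where every leaf is missing.
    Site marginals are independent, so callers may pass any column subset
    (or several concatenated alignments sharing the tree) in one call.
    """
    K = model.n_categories
    P = model.branch_matrices(tree)
    F, M, cum = _uppass(tree, codes, taxa, model, P)
    n, S = tree.n_nodes, codes.shape[1]
    all_missing = (codes < 0).all(axis=0)

    want = set(nodes) if nodes is not None else None
    D = np.empty_like(F)
    cumD = np.zeros((n, K, S))
    states_out: dict[str, np.ndarray] = {}
    max_post: dict[str, np.ndarray] = {}
    posteriors: dict[str, np.ndarray] = {}
    for v in tree.preorder:
        if tree.parent[v] < 0:
            D[v] = model.pi[None, None, :]
        else:
            u = tree.parent[v]
            pre = D[u].copy()
            cD = cumD[u].copy()
            for w in tree.children[u]:
                if w != v:
                    pre *= M[w]
                    cD += cum[w]
            sc = pre.max(axis=-1)
            sc[sc == 0] = 1.0
            pre /= sc[..., None]
            cD += np.log(sc)
            for k in range(K):
                D[v, k] = pre[k] @ P[k, v]
            cumD[v] = cD
        if tree.is_leaf[v] or (want is not None and tree.labels[v] not in want):
            continue
        raw = D[v] * F[v]  # (K, S, 61)
        lw = cumD[v] + cum[v]
        mx = lw.max(axis=0)
        weights = np.exp(lw - mx[None, :])
        post = np.einsum("ks,ksj->sj", weights, raw)
        tot = post.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        post /= tot
        states = post.argmax(axis=1).astype(np.int16)
        states[all_missing] = -1
        label = tree.labels[v]
        states_out[label] = states
        max_post[label] = post.max(axis=1)
        if include_posteriors:
            posteriors[label] = post
    return states_out, max_post, posteriors


def reconstruct_ancestors(
    tree: PhyloTree,
    alignment: CodonAlignment,
    params: CodonModelParams,
    columns: np.ndarray | None = None,
    include_posteriors: bool = False,
    nodes: list[str] | None = None,
) -> AncestralReconstruction:
    """Marginal ancestral reconstruction at every internal node.

    ``columns`` optionally restricts the computation to a subset of codon
    columns (0-based); per-site marginals are independent, so restriction
    is exact. Sites where every leaf is missing are reported as gaps.
    """
    codes, taxa = encode_alignment(alignment, tree.leaf_labels)
    if columns is not None:
        columns = np.asarray(columns, dtype=int)
        codes = codes[:, columns]
    model = MixtureModel(params)
    states, max_post, posteriors = reconstruct_codes(
        tree, codes, taxa, model, nodes=nodes, include_posteriors=include_posteriors
    )
    sequences = {
        label: "".join(
            "---" if s < 0 else SENSE_CODONS[s] for s in st
        )
        for label, st in states.items()
    }
    return AncestralReconstruction(
        sequences=sequences,
        max_posterior=max_post,
        posteriors=posteriors or None if include_posteriors else None,
        columns=columns,
    )
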