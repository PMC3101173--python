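"""Codon substitution-model machinery.

Implements the Goldman–Yang style ω-parameterized codon process used by
all site and branch models: instantaneous rates between sense codons are
zero for multi-nucleotide changes and otherwise proportional to the
target codon frequency, times κ for transitions and ω for nonsynonymous
changes.  Likelihoods are computed by Felsenstein pruning with per-taxon
missing data, IUPAC-ambiguous tip states as partial likelihood vectors,
site-pattern compression, and per-node scaling against underflow.

Branch lengths are expected substitutions per codon: site-class mixtures
share a single normalization c = Σ_k p_k μ_k (μ_k the mean rate of class
k at stationarity), while branch models normalize each branch's
generator by its own ω's mean rate, so a branch length keeps the same
meaning whatever ω the branch carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import STANDARD_CODE, CodonCode
from .io import CodonAlignment, Phylogeny, GAP_CODON


class EngineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model specification


@dataclass
class CodonModelSpec:
    """Parameters of a codon model: κ, codon frequencies, a site-class
    mixture {(p_k, ω_k)} (optionally generated from a discretized beta
    plus an extra ω_s class), and an optional branch-label → ω map."""

    kappa: float = 2.0
    codon_freqs: np.ndarray | None = None  # default: uniform over 61
    site_classes: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 1.0)])
    beta_params: tuple[float, float, int] | None = None  # (p, q, K)
    omega_s: tuple[float, float] | None = None  # (ω_s, p_s)
    branch_omega_map: dict[int, float] | None = None
    genetic_code: int = 1

    def __post_init__(self):
        if self.kappa <= 0:
            raise EngineError("kappa must be positive")
        if self.codon_freqs is not None:
            f = np.asarray(self.codon_freqs, dtype=float)
            if f.ndim != 1 or np.any(f < 0) or abs(f.sum() - 1) > 1e-8:
                raise EngineError("codon_freqs must be a simplex vector")
            self.codon_freqs = f
        for p, w in self.site_classes:
            if not (0 <= p <= 1) or w < 0:
                raise EngineError(f"invalid site class (p={p}, omega={w})")
        if self.beta_params is None:
            total = sum(p for p, _ in self.site_classes)
            if abs(total - 1) > 1e-6:
                raise EngineError(f"class proportions sum to {total}, not 1")

    def resolved_classes(self) -> list[tuple[float, float]]:
        """Discrete (proportion, ω) classes, expanding any beta block."""
        if self.beta_params is None:
            return list(self.site_classes)
        from .sitemodels import discretize_beta
        p, q, K = self.beta_params
        p_s = self.omega_s[1] if self.omega_s else 0.0
        classes = [(w_k * (1 - p_s), om)
                   for w_k, om in discretize_beta(p, q, K)]
        if self.omega_s:
            classes.append((p_s, self.omega_s[0]))
        return classes


# ---------------------------------------------------------------------------
# Rate matrices


@dataclass
class RateMatrix:
    """Instantaneous-rate generator over the sense codons.

    ``generator`` has unit mean rate at stationarity when built with
    ``normalize=True``; ``scale`` records the raw mean rate μ that was
    divided out (expected substitutions per codon per unit time of the
    unnormalized process).
    """

    generator: np.ndarray
    freqs: np.ndarray
    scale: float


def uniform_codon_freqs(code: CodonCode = STANDARD_CODE) -> np.ndarray:
    return np.full(code.n_states, 1.0 / code.n_states)


def f3x4_frequencies(aln: CodonAlignment,
                     code: CodonCode | None = None) -> np.ndarray:
    """F3x4 codon frequencies: product of per-codon-position nucleotide
    frequencies observed in the data, renormalized over sense codons.
    Ambiguous codons are skipped; a small floor keeps frequencies
    positive when a base is unobserved at some position."""
    code = code or STANDARD_CODE
    counts = np.zeros((3, 4))
    lookup = {b: i for i, b in enumerate("ACGT")}
    for i, row in enumerate(aln.codons):
        for s, codon in enumerate(row):
            if aln.mask[i, s] or codon == GAP_CODON:
                continue
            if any(b not in lookup for b in codon):
                continue
            for pos, b in enumerate(codon):
                counts[pos, lookup[b]] += 1
    pos_freqs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freqs[0, lookup[c[0]]]
        * pos_freqs[1, lookup[c[1]]]
        * pos_freqs[2, lookup[c[2]]]
        for c in code.codons
    ])
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


def _raw_generator(freqs: np.ndarray, kappa: float, omega: float,
                   code: CodonCode) -> np.ndarray:
    single = code.n_diffs == 1
    q = np.where(single, freqs[None, :], 0.0)
    q = np.where(single & code.is_transition, q * kappa, q)
    q = np.where(single & ~code.is_synonymous, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def mean_rate(freqs: np.ndarray, kappa: float, omega: float,
              code: CodonCode = STANDARD_CODE) -> float:
    """Expected substitutions per codon per unit time, μ(κ, ω)."""
    fn, fs = neutral_fluxes(freqs, kappa, code)
    return omega * fn + fs


def neutral_fluxes(freqs: np.ndarray, kappa: float,
                   code: CodonCode = STANDARD_CODE) -> tuple[float, float]:
    """(nonsynonymous, synonymous) flux at ω = 1: the mutational
    opportunity split that defines N and S site counts."""
    q = _raw_generator(freqs, kappa, 1.0, code)
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    flux = freqs[:, None] * off
    fn = flux[~code.is_synonymous & (code.n_diffs == 1)].sum()
    fs = flux[code.is_synonymous & (code.n_diffs == 1)].sum()
    return fn, fs


def nonsyn_syn_site_counts(freqs: np.ndarray, kappa: float,
                           code: CodonCode = STANDARD_CODE
                           ) -> tuple[float, float]:
    """Per-codon counts of nonsynonymous and synonymous sites (N, S),
    N + S = 3, proportional to the neutral fluxes."""
    fn, fs = neutral_fluxes(freqs, kappa, code)
    return 3 * fn / (fn + fs), 3 * fs / (fn + fs)


def build_generator(freqs: np.ndarray, kappa: float, omega: float,
                    code: CodonCode = STANDARD_CODE,
                    normalize: bool = True) -> RateMatrix:
    if omega < 0:
        raise EngineError("omega must be nonnegative")
    if kappa <= 0:
        raise EngineError("kappa must be positive")
    freqs = np.asarray(freqs, dtype=float)
    q = _raw_generator(freqs, kappa, omega, code)
    mu = float(-(freqs * np.diag(q)).sum())
    if normalize:
        q = q / mu
    return RateMatrix(generator=q, freqs=freqs, scale=mu)


class _Decomposition:
    """Eigen-decomposition of a reversible generator, giving cheap
    transition matrices for any set of branch lengths."""

    def __init__(self, q: np.ndarray, freqs: np.ndarray):
        sqrt_pi = np.sqrt(freqs)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        lam, vec = np.linalg.eigh((sym + sym.T) / 2)
        self.lam = lam
        self.left = vec / sqrt_pi[:, None]
        self.right = vec.T * sqrt_pi[None, :]

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """(len(ts), 61, 61) stochastic matrices P(t) = exp(Qt)."""
        e = np.exp(np.outer(ts, self.lam))
        p = np.einsum("ik,bk,kj->bij", self.left, e, self.right,
                      optimize=True)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """P(t) for a single branch length t ≥ 0."""
    if t < 0:
        raise EngineError("branch length must be nonnegative")
    return _Decomposition(rm.generator, rm.freqs).transition_matrices(
        np.array([t]))[0]


# ---------------------------------------------------------------------------
# Tree compilation and site patterns


class TreeIndex:
    """Postorder-array view of a Phylogeny for fast pruning."""

    def __init__(self, phylogeny: Phylogeny, taxa: list[str]):
        taxon_pos = {name: i for i, name in enumerate(taxa)}
        nodes = list(phylogeny.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_of = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.lengths = np.zeros(self.n_nodes)
        self.labels = np.zeros(self.n_nodes, dtype=int)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.tip_taxon = np.full(self.n_nodes, -1, dtype=int)
        self.postorder = list(range(self.n_nodes))
        missing = []
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = self.node_of[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = node.edge.length or 0.0
                self.labels[i] = getattr(node, "omega_label", 0)
            if node.is_leaf():
                name = node.taxon.label
                if name not in taxon_pos:
                    missing.append(name)
                else:
                    self.tip_taxon[i] = taxon_pos[name]
        if missing:
            raise EngineError(
                f"tree tips absent from alignment: {sorted(missing)}")
        self.root = self.n_nodes - 1
        self.is_tip = self.tip_taxon >= 0
        self.branch_nodes = [i for i in range(self.n_nodes)
                             if self.parent[i] >= 0]


class PatternData:
    """Alignment compressed to unique site patterns, with tip partial
    likelihood vectors (ones for missing data, indicators over
    compatible sense codons for ambiguous states)."""

    def __init__(self, aln: CodonAlignment, code: CodonCode | None = None):
        self.code = code or CodonCode(aln.genetic_code)
        keys = []
        for s in range(aln.n_sites):
            keys.append("|".join(
                GAP_CODON if aln.mask[i, s] else aln.codons[i][s]
                for i in range(aln.n_taxa)))
        uniq, inverse, counts = np.unique(
            keys, return_inverse=True, return_counts=True)
        self.site_to_pattern = inverse
        self.weights = counts.astype(float)
        self.n_patterns = len(uniq)
        n = self.code.n_states
        self.tip_partials = np.zeros((aln.n_taxa, self.n_patterns, n))
        rep_sites = np.zeros(self.n_patterns, dtype=int)
        rep_sites[inverse] = np.arange(aln.n_sites)
        for i in range(aln.n_taxa):
            for p in range(self.n_patterns):
                s = rep_sites[p]
                if aln.mask[i, s]:
                    self.tip_partials[i, p, :] = 1.0
                    continue
                codon = aln.codons[i][s]
                states = self.code.expand_ambiguous(codon)
                if not states:
                    raise EngineError(
                        f"{aln.taxa[i]}: unmasked stop codon {codon} at "
                        f"site {s + 1}; mask it (premature-stop rule) "
                        "or remove the sequence"
                    )
                self.tip_partials[i, p, states] = 1.0

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern array (last axis patterns) back to sites."""
        return per_pattern[..., self.site_to_pattern]


def _prune(tidx: TreeIndex, tip_partials: np.ndarray,
           p_edges: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Class-batched pruning.

    p_edges: (C, n_nodes, n, n) transition matrix for the edge above each
    node (unused rows for the root).  Returns (C, n_patterns) log-likelihoods.
    """
    n_classes, _, n_pat = (p_edges.shape[0], 0, tip_partials.shape[1])
    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node in tidx.postorder:
        if tidx.is_tip[node]:
            partial[node] = np.broadcast_to(
                tip_partials[tidx.tip_taxon[node]],
                (n_classes, n_pat, tip_partials.shape[2]))
            logscale[node] = np.zeros((n_classes, n_pat))
            continue
        acc = None
        scale = np.zeros((n_classes, n_pat))
        for child in tidx.children[node]:
            lifted = np.matmul(
                partial[child], p_edges[:, child].transpose(0, 2, 1))
            acc = lifted if acc is None else acc * lifted
            scale += logscale[child]
            del partial[child], logscale[child]
        m = np.maximum(acc.max(axis=2, keepdims=True), 1e-300)
        acc /= m
        scale += np.log(m[..., 0])
        partial[node] = acc
        logscale[node] = scale
    root = tidx.root
    like = np.maximum(partial[root] @ freqs, 1e-300)
    return np.log(like) + logscale[root]


class LikelihoodEvaluator:
    """Binds one (alignment, tree) pair; evaluates site-class and
    branch-model log-likelihoods for arbitrary parameters.

    ``site_class_logliks`` uses *raw* (unnormalized) generators with all
    branch lengths multiplied by ``t_mult``; dividing ``t_mult`` by the
    mixture mean rate c = Σ p_k μ_k yields the normalized model in which
    branch lengths are expected substitutions per codon.
    """

    def __init__(self, aln: CodonAlignment, tree: Phylogeny,
                 freqs: np.ndarray | None = None,
                 freq_model: str = "f3x4",
                 pmatrix_method: str = "eigen"):
        """``pmatrix_method='eigen'`` (default) reconstructs transition
        matrices from a cached spectral decomposition — fast inside
        optimization, absolutely accurate to ~1e-14 but with reduced
        relative accuracy on very small probabilities.  ``'expm'`` uses
        scaling-and-squaring per branch, preserving small entries, for
        direct high-precision evaluation."""
        if pmatrix_method not in ("eigen", "expm"):
            raise EngineError(
                f"unknown pmatrix method {pmatrix_method!r}")
        self.pmatrix_method = pmatrix_method
        self.aln = aln
        self.tree = tree
        self.code = CodonCode(aln.genetic_code) if aln.genetic_code != 1 \
            else STANDARD_CODE
        self.patterns = PatternData(aln, self.code)
        self.tidx = TreeIndex(tree, aln.taxa)
        if freqs is not None:
            self.freqs = np.asarray(freqs, dtype=float)
        elif freq_model == "f3x4":
            self.freqs = f3x4_frequencies(aln, self.code)
        elif freq_model == "uniform":
            self.freqs = uniform_codon_freqs(self.code)
        else:
            raise EngineError(f"unknown codon frequency model {freq_model!r}")
        self._decomp_cache: dict[tuple[float, float], _Decomposition] = {}

    @property
    def n_sites(self) -> int:
        return self.aln.n_sites

    def _decomposition(self, kappa: float, omega: float) -> _Decomposition:
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._decomp_cache:
            if len(self._decomp_cache) > 256:
                self._decomp_cache.clear()
            rm = build_generator(self.freqs, kappa, omega, self.code,
                                 normalize=False)
            self._decomp_cache[key] = _Decomposition(rm.generator, self.freqs)
        return self._decomp_cache[key]

    def _pmatrices(self, kappa: float, omega: float,
                   ts: np.ndarray) -> np.ndarray:
        if self.pmatrix_method == "eigen":
            return self._decomposition(kappa, omega).transition_matrices(ts)
        from scipy.linalg import expm

        q = _raw_generator(self.freqs, kappa, omega, self.code)
        uniq, inverse = np.unique(np.round(ts, 15), return_inverse=True)
        mats = np.stack([expm(q * t) for t in uniq])
        return mats[inverse]

    def site_class_logliks(self, kappa: float, omegas,
                           t_mult: float = 1.0) -> np.ndarray:
        """(n_classes, n_patterns) per-class log-likelihoods under raw
        generators with branch lengths × t_mult."""
        omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
        ts = self.tidx.lengths * t_mult
        n = self.code.n_states
        p_edges = np.empty((len(omegas), self.tidx.n_nodes, n, n))
        for c, om in enumerate(omegas):
            p_edges[c] = self._pmatrices(kappa, om, ts)
        return _prune(self.tidx, self.patterns.tip_partials, p_edges,
                      self.freqs)

    def branch_logliks(self, kappa: float, omega_by_label: dict[int, float],
                       t_mult: float = 1.0) -> np.ndarray:
        """(n_patterns,) log-likelihood with per-branch ω by label.

        Each branch's generator is normalized by its own mean rate so
        branch lengths stay in expected-substitutions-per-codon units.
        """
        ts = self.tidx.lengths * t_mult
        n = self.code.n_states
        p_edges = np.empty((1, self.tidx.n_nodes, n, n))
        for label in set(self.tidx.labels[self.tidx.branch_nodes]):
            if label not in omega_by_label:
                raise EngineError(f"no omega for branch label {label}")
        for label, om in omega_by_label.items():
            sel = np.flatnonzero(self.tidx.labels == label)
            sel = sel[sel != self.tidx.root]
            if len(sel) == 0:
                continue
            mu = mean_rate(self.freqs, kappa, om, self.code)
            p_edges[0, sel] = self._pmatrices(kappa, om, ts[sel] / mu)
        return _prune(self.tidx, self.patterns.tip_partials, p_edges,
                      self.freqs)[0]

    def mixture_loglik(self, class_logliks: np.ndarray,
                       weights) -> tuple[float, np.ndarray]:
        """Total and per-pattern lnL of a weighted class mixture."""
        weights = np.asarray(weights, dtype=float)
        logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)),
                        -np.inf)
        stacked = class_logliks + logw[:, None]
        m = stacked.max(axis=0)
        per_pattern = m + np.log(np.exp(stacked - m).sum(axis=0))
        return float(per_pattern @ self.patterns.weights), per_pattern


def alignment_log_likelihood(aln: CodonAlignment, tree: Phylogeny,
                             spec: CodonModelSpec,
                             freqs: np.ndarray | None = None):
    """Total, per-site, and per-site-per-class log-likelihoods of an
    alignment under a codon model with branch lengths in expected
    substitutions per codon."""
    ev = LikelihoodEvaluator(
        aln, tree,
        freqs=spec.codon_freqs if freqs is None else freqs,
        pmatrix_method="expm")
    if spec.branch_omega_map is not None:
        per_pattern = ev.branch_logliks(spec.kappa, spec.branch_omega_map)
        per_site = ev.patterns.expand(per_pattern)
        total = float(per_pattern @ ev.patterns.weights)
        return total, per_site, per_site[None, :]
    classes = spec.resolved_classes()
    probs = np.array([p for p, _ in classes])
    omegas = np.array([w for _, w in classes])
    mus = np.array([mean_rate(ev.freqs, spec.kappa, w, ev.code)
                    for w in omegas])
    c = float(probs @ mus)
    logliks = ev.site_class_logliks(spec.kappa, omegas, t_mult=1.0 / c)
    total, per_pattern = ev.mixture_loglik(logliks, probs)
    return total, ev.patterns.expand(per_pattern), ev.patterns.expand(logliks)


def expected_branch_substitutions(freqs: np.ndarray, kappa: float,
                                  omega: float, branch_length: float,
                                  n_sites: int | None = None,
                                  code: CodonCode = STANDARD_CODE) -> dict:
    """Expected nonsynonymous/synonymous substitution counts on a branch
    whose length is in expected substitutions per codon.

    Returns per-codon and (if ``n_sites`` given) per-gene counts plus
    the dN/dS decomposition under the mutational-opportunity site counts.
    """
    if branch_length < 0:
        raise EngineError("branch length must be nonnegative")
    fn, fs = neutral_fluxes(freqs, kappa, code)
    mu = omega * fn + fs
    en = branch_length * omega * fn / mu
    es = branch_length * fs / mu
    n_count, s_count = nonsyn_syn_site_counts(freqs, kappa, code)
    out = {
        "nonsyn_per_codon": en,
        "syn_per_codon": es,
        "dN": en / n_count if n_count > 0 else np.nan,
        "dS": es / s_count if s_count > 0 else np.nan,
        "N_sites": n_count,
        "S_sites": s_count,
    }
    if n_sites is not None:
        out["nonsyn_per_gene"] = en * n_sites
        out["syn_per_gene"] = es * n_sites
    return out
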