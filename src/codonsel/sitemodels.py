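"""Site-class ω-mixture models (M0, M1a, M2a, M7, M8, M8a).

Model definitions
-----------------
* M0    one ω for all sites.
* M1a   nearly neutral: classes (ω0 < 1, ω1 = 1).
* M2a   positive selection: M1a plus a class ω2 ≥ 1.
* M7    beta: ω ~ Beta(p, q) discretized into K equal-weight classes.
* M8    beta & ω: proportion p0 follows the beta, p1 = 1 − p0 sits at
        ωs ≥ 1.
* M8a   M8 with the extra class pinned at ωs = 1.

Fitting maximizes the likelihood over κ, the class ω values and a global
branch-length scale with bounded quasi-Newton from a small set of
deterministic starting points; mixture proportions are profiled out by
EM at every objective evaluation (the profile is exact because the
log-likelihood is concave in the weights).  Per-site posterior
probabilities of the ω > 1 class are available by naive empirical Bayes
(NEB) or Bayes empirical Bayes (BEB) over a discrete parameter grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt
from scipy import stats as _stats

from .engine import (
    EngineError,
    LikelihoodEvaluator,
    mean_rate,
)
from .io import CodonAlignment, Phylogeny

SITE_MODELS = ("M0", "M1a", "M2a", "M7", "M8", "M8a")

BETA_CATEGORIES = 10

_BOUNDS = {
    "kappa": (0.2, 99.0),
    "omega0": (1e-4, 0.9999),
    "omega_pos": (1.0, 99.0),
    "omega_free": (1e-4, 99.0),
    "beta_shape": (0.005, 99.0),
    "scale": (1e-3, 99.0),
}

# Deterministic starting values for the positive-selection class ω; the
# near-boundary start keeps nested-model likelihood orderings honest.
_POSITIVE_STARTS = (1.05, 2.0, 5.0)


def discretize_beta(p: float, q: float, K: int = BETA_CATEGORIES,
                    rule: str = "mean") -> list[tuple[float, float]]:
    """K equal-weight (proportion, ω) classes from Beta(p, q).

    ``rule='mean'`` uses the conditional mean of each equal-probability
    bin; ``rule='median'`` uses the bin midpoint quantile.
    """
    if p <= 0 or q <= 0:
        raise EngineError("beta shapes must be positive")
    if K < 2:
        raise EngineError("need at least 2 beta categories")
    edges = _stats.beta.ppf(np.linspace(0, 1, K + 1), p, q)
    if rule == "median":
        omegas = _stats.beta.ppf((np.arange(K) + 0.5) / K, p, q)
    elif rule == "mean":
        # E[X | bin] = (p/(p+q)) * ΔI(x; p+1, q) / ΔI(x; p, q); the
        # denominator is 1/K by construction of the bins.
        upper = _stats.beta.cdf(edges, p + 1, q)
        omegas = (p / (p + q)) * np.diff(upper) * K
    else:
        raise EngineError(f"unknown discretization rule {rule!r}")
    omegas = np.clip(omegas, 1e-8, 1 - 1e-8)
    return [(1.0 / K, float(w)) for w in omegas]


def _profile_weights(class_logliks: np.ndarray, pattern_weights: np.ndarray,
                     groups: list[list[int]],
                     max_iter: int = 300, tol: float = 1e-10
                     ) -> tuple[np.ndarray, float]:
    """Maximize the mixture lnL over group weights by EM.

    Classes inside a group share their group's probability equally
    (e.g. the K beta categories of M8).  Returns (full per-class
    weights, lnL)."""
    g_log = np.stack([
        _logmeanexp(class_logliks[idx]) for idx in groups
    ])
    n_groups = len(groups)
    w = np.full(n_groups, 1.0 / n_groups)
    total = pattern_weights.sum()
    lnl_prev = -np.inf
    for _ in range(max_iter):
        a = g_log + np.log(np.maximum(w, 1e-300))[:, None]
        m = a.max(axis=0)
        r = np.exp(a - m)
        denom = r.sum(axis=0)
        lnl = float((m + np.log(denom)) @ pattern_weights)
        w = ((r / denom) @ pattern_weights) / total
        if lnl - lnl_prev < tol:
            break
        lnl_prev = lnl
    full = np.zeros(class_logliks.shape[0])
    for gi, idx in enumerate(groups):
        full[idx] = w[gi] / len(idx)
    return full, lnl


def _logmeanexp(rows: np.ndarray) -> np.ndarray:
    if rows.shape[0] == 1:
        return rows[0]
    m = rows.max(axis=0)
    return m + np.log(np.exp(rows - m).mean(axis=0))


@dataclass
class FitResult:
    """Maximum-likelihood fit of one codon model."""

    model_name: str
    lnL: float
    mle: dict
    n_params: int
    converged: bool
    class_proportions: np.ndarray
    class_omegas: np.ndarray
    tree_scale: float
    per_site_posteriors: np.ndarray | None = None
    _ctx: dict = field(default_factory=dict, repr=False)

    @property
    def avg_omega(self) -> float:
        """Mixture-weighted mean ω across site classes."""
        return float(self.class_proportions @ self.class_omegas)

    @property
    def positive_class(self) -> int | None:
        pos = np.flatnonzero(self.class_omegas > 1.0)
        return int(pos[-1]) if len(pos) else None

    @property
    def positive_proportion(self) -> float:
        k = self.positive_class
        return float(self.class_proportions[k]) if k is not None else 0.0

    @property
    def positive_omega(self) -> float | None:
        k = self.positive_class
        return float(self.class_omegas[k]) if k is not None else None


class _SiteModel:
    """Maps an outer parameter vector to (class ω values, groups)."""

    def __init__(self, name: str):
        if name not in SITE_MODELS:
            raise EngineError(f"unknown site model {name!r}; "
                              f"choose from {SITE_MODELS}")
        self.name = name

    def layout(self):
        b = _BOUNDS
        if self.name == "M0":
            return (["kappa", "omega", "scale"],
                    [b["kappa"], b["omega_free"], b["scale"]])
        if self.name == "M1a":
            return (["kappa", "omega0", "scale"],
                    [b["kappa"], b["omega0"], b["scale"]])
        if self.name == "M2a":
            return (["kappa", "omega0", "omega2", "scale"],
                    [b["kappa"], b["omega0"], b["omega_pos"], b["scale"]])
        if self.name == "M7":
            return (["kappa", "beta_p", "beta_q", "scale"],
                    [b["kappa"], b["beta_shape"], b["beta_shape"],
                     b["scale"]])
        if self.name == "M8":
            return (["kappa", "beta_p", "beta_q", "omega_s", "scale"],
                    [b["kappa"], b["beta_shape"], b["beta_shape"],
                     b["omega_pos"], b["scale"]])
        # M8a
        return (["kappa", "beta_p", "beta_q", "scale"],
                [b["kappa"], b["beta_shape"], b["beta_shape"], b["scale"]])

    def classes(self, params: dict) -> tuple[np.ndarray, list[list[int]]]:
        """Class ω values and EM weight groups for one parameter point."""
        if self.name == "M0":
            return np.array([params["omega"]]), [[0]]
        if self.name == "M1a":
            return np.array([params["omega0"], 1.0]), [[0], [1]]
        if self.name == "M2a":
            return (np.array([params["omega0"], 1.0, params["omega2"]]),
                    [[0], [1], [2]])
        beta = discretize_beta(params["beta_p"], params["beta_q"])
        omegas = [w for _, w in beta]
        if self.name == "M7":
            return np.array(omegas), [list(range(len(omegas)))]
        extra = params["omega_s"] if self.name == "M8" else 1.0
        return (np.array(omegas + [extra]),
                [list(range(len(omegas))), [len(omegas)]])

    def starts(self) -> list[dict]:
        base = {"kappa": 2.0, "scale": 1.0}
        if self.name == "M0":
            return [dict(base, omega=w) for w in (0.1, 0.5, 2.0)]
        if self.name == "M1a":
            return [dict(base, omega0=w) for w in (0.05, 0.3)]
        if self.name == "M2a":
            return [dict(base, omega0=0.1, omega2=w)
                    for w in _POSITIVE_STARTS]
        if self.name == "M7":
            return [dict(base, beta_p=p, beta_q=q)
                    for p, q in ((0.3, 1.0), (1.0, 1.0))]
        if self.name == "M8":
            return [dict(base, beta_p=0.3, beta_q=1.0, omega_s=w)
                    for w in _POSITIVE_STARTS]
        return [dict(base, beta_p=p, beta_q=q)
                for p, q in ((0.3, 1.0), (1.0, 1.0))]

    def n_free_params(self) -> int:
        # outer parameters + free mixture proportions
        return {
            "M0": 3, "M1a": 4, "M2a": 6, "M7": 4, "M8": 6, "M8a": 5,
        }[self.name]


def fit_site_model(aln: CodonAlignment, tree: Phylogeny, model_name: str,
                   freq_model: str = "f3x4",
                   evaluator: LikelihoodEvaluator | None = None,
                   maxiter: int = 200,
                   extra_starts: list[dict] | None = None) -> FitResult:
    """Fit one site-class model by maximum likelihood.

    Branch lengths are taken from the tree up to a fitted global scale
    factor (reported, after normalization, in expected substitutions per
    codon).  ``extra_starts`` adds starting points beyond the model's
    deterministic defaults — e.g. the nested null's optimum, which
    guarantees the nesting inequality lnL(alt) ≥ lnL(null) in LRTs.
    Non-convergence is flagged on the result, not raised.
    """
    model = _SiteModel(model_name)
    ev = evaluator or LikelihoodEvaluator(aln, tree, freq_model=freq_model)
    names, bounds = model.layout()
    patw = ev.patterns.weights

    state = {}

    def neg_lnl(x: np.ndarray) -> float:
        params = dict(zip(names, x))
        omegas, groups = model.classes(params)
        logliks = ev.site_class_logliks(params["kappa"], omegas,
                                        t_mult=params["scale"])
        weights, lnl = _profile_weights(logliks, patw, groups)
        state.update(params=params, omegas=omegas, weights=weights,
                     logliks=logliks, lnl=lnl)
        return -lnl

    starts = model.starts() + [
        {**model.starts()[0], **s} for s in (extra_starts or [])]
    best = None
    for start in starts:
        x0 = np.array([
            np.clip(start[n], bounds[i][0], bounds[i][1])
            for i, n in enumerate(names)])
        res = _opt.minimize(neg_lnl, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    neg_lnl(best.x)  # repopulate state at the optimum

    params = state["params"]
    omegas = state["omegas"]
    weights = state["weights"]
    mus = np.array([mean_rate(ev.freqs, params["kappa"], w, ev.code)
                    for w in omegas])
    c = float(weights @ mus)
    mle = dict(params)
    mle["proportions"] = weights.tolist()
    mle["tree_scale"] = params["scale"] * c
    return FitResult(
        model_name=model_name,
        lnL=state["lnl"],
        mle=mle,
        n_params=model.n_free_params(),
        converged=bool(best.success),
        class_proportions=weights,
        class_omegas=omegas,
        tree_scale=params["scale"] * c,
        _ctx={"evaluator": ev, "state": dict(state), "model": model},
    )


# ---------------------------------------------------------------------------
# Posterior probabilities of positive selection


def site_posteriors(fit: FitResult, method: str = "BEB") -> np.ndarray:
    """Per-site posterior probability of the ω > 1 class.

    NEB evaluates the posterior at the MLEs; BEB averages over a uniform
    discrete grid on the mixture parameters (10 points per dimension).
    """
    if fit.positive_class is None:
        raise EngineError(
            f"{fit.model_name} has no ω > 1 class; posterior positive-"
            "selection probabilities need M2a or M8")
    if method.upper() == "NEB":
        return _neb(fit)
    if method.upper() == "BEB":
        if fit.model_name == "M2a":
            return _beb_m2a(fit)
        if fit.model_name == "M8":
            return _beb_m8(fit)
        raise EngineError("BEB implemented for M2a and M8 fits")
    raise EngineError(f"unknown posterior method {method!r}")


def _neb(fit: FitResult) -> np.ndarray:
    state = fit._ctx["state"]
    ev = fit._ctx["evaluator"]
    logliks = state["logliks"]
    w = np.asarray(state["weights"], dtype=float)
    logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    a = logliks + logw[:, None]
    m = a.max(axis=0)
    post = np.exp(a - m) / np.exp(a - m).sum(axis=0)
    return ev.patterns.expand(post[fit.positive_class])


def _grid_midpoints(lo: float, hi: float, n: int = 10) -> np.ndarray:
    return lo + (hi - lo) * (np.arange(n) + 0.5) / n


def _beb_m2a(fit: FitResult, n_grid: int = 10) -> np.ndarray:
    """BEB for M2a: uniform grid prior over (p0, p1) on the probability
    triangle, ω0 ~ U(0,1), ω2 ~ U(1,11), branch lengths and κ fixed at
    their MLEs."""
    ev = fit._ctx["evaluator"]
    state = fit._ctx["state"]
    kappa = state["params"]["kappa"]
    scale = state["params"]["scale"]
    patw = ev.patterns.weights

    omega0_grid = _grid_midpoints(0.0, 1.0, n_grid)
    omega2_grid = _grid_midpoints(1.0, 11.0, n_grid)
    l0 = ev.site_class_logliks(kappa, omega0_grid, t_mult=scale)
    l1 = ev.site_class_logliks(kappa, [1.0], t_mult=scale)[0]
    l2 = ev.site_class_logliks(kappa, omega2_grid, t_mult=scale)

    # (p0, p1) combinations with p0 + p1 ≤ 1, uniform prior on the grid.
    mids = _grid_midpoints(0.0, 1.0, n_grid)
    combos = [(p0, p1) for p0 in mids for p1 in mids if p0 + p1 <= 1.0]
    p_arr = np.array(combos)  # (n_w, 2)
    p2_arr = 1.0 - p_arr.sum(axis=1)

    n_pat = len(patw)
    post_num = np.zeros(n_pat)
    log_marg_terms = []
    post_terms = []
    for a in range(n_grid):
        for b in range(n_grid):
            stack = np.stack([l0[a], l1, l2[b]])  # (3, n_pat)
            m = stack.max(axis=0)
            e = np.exp(stack - m)  # (3, n_pat)
            mix = (p_arr[:, 0][:, None] * e[0]
                   + p_arr[:, 1][:, None] * e[1]
                   + p2_arr[:, None] * e[2])  # (n_w, n_pat)
            log_f = (np.log(np.maximum(mix, 1e-300)) + m) @ patw  # (n_w,)
            log_marg_terms.append(log_f)
            post_terms.append(p2_arr[:, None] * e[2] / np.maximum(mix, 1e-300))
    log_marg = np.concatenate(log_marg_terms)
    grid_post = np.exp(log_marg - log_marg.max())
    grid_post /= grid_post.sum()
    pieces = np.concatenate(post_terms, axis=0)
    site_post = grid_post @ pieces
    return ev.patterns.expand(np.clip(site_post, 0.0, 1.0))


def _beb_m8(fit: FitResult, n_grid: int = 10) -> np.ndarray:
    """BEB for M8 over (p0, ωs): p0 ~ U(0,1), ωs ~ U(1,11) on 10-point
    grids, with the beta shape parameters, κ and branch lengths fixed at
    their MLEs (a reduced grid relative to the full construction; the
    beta shapes are typically well determined by the data)."""
    ev = fit._ctx["evaluator"]
    state = fit._ctx["state"]
    params = state["params"]
    patw = ev.patterns.weights

    beta = discretize_beta(params["beta_p"], params["beta_q"])
    beta_omegas = np.array([w for _, w in beta])
    lbeta = ev.site_class_logliks(params["kappa"], beta_omegas,
                                  t_mult=params["scale"])
    lbeta_group = _logmeanexp(lbeta)  # (n_pat,)
    omega_s_grid = _grid_midpoints(1.0, 11.0, n_grid)
    ls = ev.site_class_logliks(params["kappa"], omega_s_grid,
                               t_mult=params["scale"])
    p0_grid = _grid_midpoints(0.0, 1.0, n_grid)

    log_marg = np.zeros((n_grid, n_grid))
    post = np.zeros((n_grid, n_grid, len(patw)))
    for b in range(n_grid):
        stack = np.stack([lbeta_group, ls[b]])
        m = stack.max(axis=0)
        e = np.exp(stack - m)
        for a, p0 in enumerate(p0_grid):
            mix = p0 * e[0] + (1 - p0) * e[1]
            log_marg[a, b] = (np.log(np.maximum(mix, 1e-300)) + m) @ patw
            post[a, b] = (1 - p0) * e[1] / np.maximum(mix, 1e-300)
    grid_post = np.exp(log_marg - log_marg.max())
    grid_post /= grid_post.sum()
    site_post = np.einsum("ab,abp->p", grid_post, post)
    return ev.patterns.expand(np.clip(site_post, 0.0, 1.0))


def positively_selected_sites(posteriors: np.ndarray,
                              threshold: float = 0.95) -> list[int]:
    """1-based alignment sites with posterior ≥ threshold, ascending."""
    if not (0 < threshold <= 1):
        raise EngineError("threshold must be in (0, 1]")
    return [int(i) + 1 for i in np.flatnonzero(
        np.asarray(posteriors) >= threshold)]
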