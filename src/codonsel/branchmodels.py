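"""Branch-wise ω models: one-ratio (M0), two-ratio with stem / whole-
clade / terminal foreground selections, free-ratio, and per-species
root-to-tip ω, dN and dS.

Foreground branches carry integer ω-class labels (0 = background); each
label class gets its own ω while κ, codon frequencies and the global
branch-length scale are shared.  Root-to-tip statistics for a tip fit a
two-ratio model whose foreground is every branch on the path from a
designated ancestor down to that tip — the selection summary used for
the trait regressions — with path dN and dS accumulated branch by
branch along the fitted path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as _opt

from .engine import (
    EngineError,
    LikelihoodEvaluator,
    expected_branch_substitutions,
)
from .io import Phylogeny, CodonAlignment
from .sitemodels import FitResult, _BOUNDS


class SelectionError(ValueError):
    pass


@dataclass
class BranchSelection:
    """A foreground choice for a two-ratio model.

    mode 'stem' labels only the branch subtending the target clade's
    last common ancestor; 'clade' labels the stem plus every branch
    inside the clade; 'terminal' labels the branch above a single tip.
    """

    target: str | list[str]
    mode: str = "stem"
    label: int = 1

    def tip_set(self) -> list[str]:
        return [self.target] if isinstance(self.target, str) \
            else list(self.target)


def mark_branches(tree: Phylogeny, selection: BranchSelection) -> Phylogeny:
    """Return a relabeled copy with foreground branches set to
    ``selection.label`` and everything else to 0."""
    marked = tree.clone()
    for node in marked.tree:
        node.omega_label = 0
    tips = selection.tip_set()
    if selection.mode == "terminal":
        if len(tips) != 1:
            raise SelectionError("terminal mode takes a single tip")
        node = marked.mrca(tips)
        if not node.is_leaf():
            raise SelectionError(f"{tips[0]} is not a tip")
        node.omega_label = selection.label
        return marked
    mrca = marked.mrca(tips)
    clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if clade_tips != set(tips):
        raise SelectionError(
            "target is not monophyletic; clade additionally contains "
            f"{sorted(clade_tips - set(tips))}")
    if mrca.parent_node is None:
        raise SelectionError("cannot label the root branch")
    mrca.omega_label = selection.label
    if selection.mode == "clade":
        for node in mrca.preorder_iter():
            node.omega_label = selection.label
    elif selection.mode != "stem":
        raise SelectionError(f"unknown selection mode {selection.mode!r}")
    return marked


def label_all_branches(tree: Phylogeny) -> Phylogeny:
    """Give every branch its own label (free-ratio model input)."""
    marked = tree.clone()
    k = 0
    for node in marked.tree.postorder_node_iter():
        if node.parent_node is not None:
            node.omega_label = k
            k += 1
        else:
            node.omega_label = 0
    return marked


def mark_path(tree: Phylogeny, ancestor_tips: list[str], tip: str,
              label: int = 1) -> Phylogeny:
    """Label every branch on the path from the MRCA of ``ancestor_tips``
    down to ``tip`` (root-to-tip foreground)."""
    marked = tree.clone()
    for node in marked.tree:
        node.omega_label = 0
    ancestor = marked.mrca(ancestor_tips)
    target = marked.mrca([tip])
    node = target
    path = []
    while node is not None and node is not ancestor:
        path.append(node)
        node = node.parent_node
    if node is not ancestor:
        raise EngineError(
            f"{ancestor_tips} MRCA is not an ancestor of {tip}")
    for n in path:
        n.omega_label = label
    return marked


def fit_branch_model(aln: CodonAlignment, tree: Phylogeny,
                     freq_model: str = "f3x4",
                     evaluator: LikelihoodEvaluator | None = None,
                     maxiter: int = 500) -> FitResult:
    """ML fit of a labeled branch model (one ω per label class).

    With all labels 0 this is M0; with all branches distinctly labeled
    it is the free-ratio model.  κ and a global branch-length scale are
    shared across classes.
    """
    ev = evaluator or LikelihoodEvaluator(aln, tree, freq_model=freq_model)
    labels = sorted(set(ev.tidx.labels[ev.tidx.branch_nodes]))
    if not labels:
        raise SelectionError("tree has no branches")
    patw = ev.patterns.weights

    def unpack(x):
        kappa, scale = x[0], x[1]
        omega = dict(zip(labels, x[2:]))
        return kappa, scale, omega

    def neg_lnl(x):
        kappa, scale, omega = unpack(x)
        per_pattern = ev.branch_logliks(kappa, omega, t_mult=scale)
        return -float(per_pattern @ patw)

    bounds = [_BOUNDS["kappa"], _BOUNDS["scale"]] + \
        [_BOUNDS["omega_free"]] * len(labels)
    # Multi-start pays off for low-dimensional fits; free-ratio fits are
    # high-dimensional and smooth enough for a single neutral-ish start.
    omega_starts = (0.2, 1.0) if len(labels) <= 4 else (0.5,)
    best = None
    for omega_start in omega_starts:
        x0 = np.array([2.0, 1.0] + [omega_start] * len(labels))
        res = _opt.minimize(neg_lnl, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    kappa, scale, omega = unpack(best.x)
    mle = {"kappa": kappa, "scale": scale,
           "omega_by_label": {int(k): float(v) for k, v in omega.items()}}
    return FitResult(
        model_name="branch" if len(labels) > 1 else "M0",
        lnL=-best.fun,
        mle=mle,
        n_params=2 + len(labels),
        converged=bool(best.success),
        class_proportions=np.array([1.0]),
        class_omegas=np.array([omega[labels[0]]]),
        tree_scale=scale,
        _ctx={"evaluator": ev, "labels": labels, "omega": omega,
              "kappa": kappa, "scale": scale},
    )


def branch_substitution_counts(fit: FitResult) -> list[dict]:
    """Per-branch expected nonsynonymous/synonymous substitution counts
    under a fitted branch model (per codon and per gene)."""
    if "omega" not in fit._ctx:
        raise EngineError("substitution counts need a branch-model fit")
    ev = fit._ctx["evaluator"]
    omega = fit._ctx["omega"]
    kappa, scale = fit._ctx["kappa"], fit._ctx["scale"]
    rows = []
    for node in ev.tidx.branch_nodes:
        label = int(ev.tidx.labels[node])
        t = ev.tidx.lengths[node] * scale
        counts = expected_branch_substitutions(
            ev.freqs, kappa, omega[label], t, n_sites=ev.n_sites,
            code=ev.code)
        counts.update(branch=node, label=label, omega=omega[label],
                      length=t)
        rows.append(counts)
    return rows


@dataclass
class RootToTipStats:
    """Selection summary along one ancestor→tip path."""

    species: str
    omega: float | None
    dN: float
    dS: float
    lnL: float
    background_omega: float
    undefined: bool = False


def root_to_tip_stats(aln: CodonAlignment, tree: Phylogeny,
                      ancestor_tips: list[str], tip: str,
                      freq_model: str = "f3x4") -> RootToTipStats:
    """Two-ratio fit with the ancestor→tip path as foreground.

    Path dN and dS are the per-site rates summed over path branches;
    ω is the fitted foreground ratio (undefined and flagged when the
    path has no synonymous opportunity, e.g. zero length).
    """
    marked = mark_path(tree, ancestor_tips, tip)
    fit = fit_branch_model(aln, marked, freq_model=freq_model)
    ev = fit._ctx["evaluator"]
    omega = fit._ctx["omega"]
    rows = branch_substitution_counts(fit)
    dn = sum(r["dN"] for r in rows if r["label"] == 1)
    ds = sum(r["dS"] for r in rows if r["label"] == 1)
    path_len = sum(r["length"] for r in rows if r["label"] == 1)
    undefined = ds <= 0 or path_len <= 0
    return RootToTipStats(
        species=tip,
        omega=None if undefined else float(omega[1]),
        dN=float(dn),
        dS=float(ds),
        lnL=fit.lnL,
        background_omega=float(omega[0]),
        undefined=undefined,
    )


def root_to_tip_table(aln: CodonAlignment, tree: Phylogeny,
                      ancestor_tips: list[str], tips: list[str],
                      freq_model: str = "f3x4"):
    """Root-to-tip stats for many tips as a pandas DataFrame."""
    import pandas as pd

    rows = [root_to_tip_stats(aln, tree, ancestor_tips, t, freq_model)
            for t in tips]
    return pd.DataFrame([r.__dict__ for r in rows])
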