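"""End-to-end analysis batteries.

Three reports mirror the standard layout of a selection study on a gene:

* site-model battery — nearly-neutral vs positive-selection site models
  (M1a/M2a, M8/M8a) fitted per clade subset and per input tree, with
  LRTs and BEB-called sites;
* branch-model battery — a list of two-ratio foreground selections plus
  the free-ratio model, each tested against M0 with Bonferroni control
  across the battery;
* association battery — PGLS of root-to-tip ω (and its dN/dS
  decomposition) on brain/body phenotypes.

Failed fits mark their rows rather than aborting a battery; every run
can emit a manifest (config hash, seed, version) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .branchmodels import (
    BranchSelection,
    fit_branch_model,
    label_all_branches,
    mark_branches,
    root_to_tip_table,
)
from .comparative import association_battery
from .comparison import bonferroni_threshold, likelihood_ratio_test
from .engine import LikelihoodEvaluator
from .io import CodonAlignment, Phylogeny
from .sitemodels import fit_site_model, positively_selected_sites, \
    site_posteriors

#: below this many tips, site-model tests are reported but flagged as
#: underpowered (robust M2a/M8 tests want more sequences).
MIN_RECOMMENDED_TIPS = 6


@dataclass
class AnalysisConfig:
    alignment: CodonAlignment
    species_tree: Phylogeny
    gene_tree: Phylogeny | None = None
    time_tree: Phylogeny | None = None
    phenotypes: pd.DataFrame | None = None
    clades: dict[str, list[str]] = field(default_factory=dict)
    branch_selections: list[BranchSelection] = field(default_factory=list)
    site_models: tuple[str, ...] = ("M1a", "M2a", "M8", "M8a")
    beb_threshold: float = 0.95
    alpha: float = 0.05
    seed: int = 0

    def trees(self) -> dict[str, Phylogeny]:
        out = {"species_tree": self.species_tree}
        if self.gene_tree is not None:
            out["gene_tree"] = self.gene_tree
        return out


def manifest(config: AnalysisConfig) -> dict:
    """Reproducibility record: config digest, seed, software version."""
    payload = {
        "clades": {k: sorted(v) for k, v in sorted(config.clades.items())},
        "site_models": list(config.site_models),
        "selections": [
            (s.mode, sorted(s.tip_set())) for s in config.branch_selections],
        "alpha": config.alpha,
        "beb_threshold": config.beb_threshold,
        "taxa": list(config.alignment.taxa),
        "n_sites": config.alignment.n_sites,
        "trees": {k: t.to_newick() for k, t in config.trees().items()},
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    return {"config_sha256": digest, "seed": config.seed,
            "version": __version__}


_LRT_PAIRS = (("M1a", "M2a", 2, False), ("M8a", "M8", 1, True))


def run_site_model_battery(config: AnalysisConfig
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Fit the site models per clade subset and tree; returns the report
    table and a list of warnings (small clades, failed fits)."""
    rows, warnings_list = [], []
    clades = config.clades or {"all": list(config.alignment.taxa)}
    for tree_name, tree in config.trees().items():
        for clade_name, tips in clades.items():
            tips = [t for t in tips if t in config.alignment.taxa]
            if len(tips) < MIN_RECOMMENDED_TIPS:
                warnings_list.append(
                    f"{clade_name}: only {len(tips)} tips — well below "
                    "the recommended number for robust site-model tests")
            sub_aln = config.alignment.subset(tips)
            sub_tree = tree.extract(tips)
            ev = LikelihoodEvaluator(sub_aln, sub_tree)
            fits = {}
            # warm-start each alternative from its nested null's optimum
            # so battery LRT statistics cannot go negative; nulls are
            # fitted first regardless of the configured order
            null_of = {"M2a": ("M1a", {"omega2": 1.0}),
                       "M8": ("M8a", {"omega_s": 1.0})}
            fit_order = sorted(
                config.site_models,
                key=lambda m: m in null_of)
            for model in fit_order:
                extra = []
                if model in null_of and null_of[model][0] in fits:
                    null_fit, patch = fits[null_of[model][0]], \
                        null_of[model][1]
                    params = {k: v for k, v in null_fit.mle.items()
                              if isinstance(v, (int, float))}
                    extra = [{**params, **patch}]
                try:
                    fits[model] = fit_site_model(
                        sub_aln, sub_tree, model, evaluator=ev,
                        extra_starts=extra)
                except Exception as exc:  # battery must not abort
                    warnings_list.append(
                        f"{clade_name}/{tree_name}/{model} failed: {exc}")
            for model in config.site_models:
                if model not in fits:
                    continue
                fit = fits[model]
                sites = []
                if fit.positive_class is not None and \
                        model in ("M2a", "M8"):
                    beb = site_posteriors(fit, "BEB")
                    sites = positively_selected_sites(
                        beb, config.beb_threshold)
                rows.append({
                    "tree": tree_name, "clade": clade_name, "row": "fit",
                    "model": model, "neg_lnL": -fit.lnL,
                    "avg_omega": fit.avg_omega,
                    "prop_positive": fit.positive_proportion,
                    "omega_positive": fit.positive_omega,
                    "converged": fit.converged,
                    "beb_sites": ",".join(map(str, sites)),
                })
            for null, alt, df, halve in _LRT_PAIRS:
                if null in fits and alt in fits:
                    lrt = likelihood_ratio_test(
                        -fits[null].lnL, -fits[alt].lnL, df=df, halve=halve,
                        alpha_corrected=config.alpha)
                    rows.append({
                        "tree": tree_name, "clade": clade_name,
                        "row": "lrt", "model": f"{null} v {alt}",
                        "statistic": lrt.statistic, "df": df, "p": lrt.p,
                        "halved": halve,
                        "significant": lrt.significant_after_correction,
                    })
    return pd.DataFrame(rows), warnings_list


def run_branch_model_battery(config: AnalysisConfig
                             ) -> tuple[pd.DataFrame, list[str]]:
    """Two-ratio selections plus free-ratio, each LRT-tested against M0
    with Bonferroni correction across the whole battery."""
    rows, warnings_list = [], []
    m_tests = len(config.branch_selections) + 1  # + free-ratio
    level = bonferroni_threshold(config.alpha, m_tests)
    for tree_name, tree in config.trees().items():
        ev = LikelihoodEvaluator(config.alignment, tree)
        m0 = fit_branch_model(config.alignment, tree, evaluator=ev)
        rows.append({"tree": tree_name, "model": "M0",
                     "neg_lnL": -m0.lnL,
                     "omega_foreground": m0.mle["omega_by_label"][0],
                     "p": np.nan, "significant": np.nan})
        for sel in config.branch_selections:
            name = "+".join(sel.tip_set()) if len(sel.tip_set()) < 3 \
                else f"{sel.tip_set()[0]}..({len(sel.tip_set())} tips)"
            try:
                marked = mark_branches(tree, sel)
                fit = fit_branch_model(config.alignment, marked)
                lrt = likelihood_ratio_test(-m0.lnL, -fit.lnL, df=1,
                                            alpha_corrected=level)
            except Exception as exc:
                warnings_list.append(
                    f"{tree_name}/{sel.mode}:{name} failed: {exc}")
                rows.append({"tree": tree_name,
                             "model": f"{sel.mode}:{name}",
                             "failed": True})
                continue
            rows.append({
                "tree": tree_name, "model": f"{sel.mode}:{name}",
                "neg_lnL": -fit.lnL,
                "omega_foreground": fit.mle["omega_by_label"][sel.label],
                "omega_background": fit.mle["omega_by_label"][0],
                "statistic": lrt.statistic, "p": lrt.p,
                "significant": lrt.significant_after_correction,
            })
        free = fit_branch_model(config.alignment,
                                label_all_branches(tree))
        df_free = tree.n_branches() - 1
        lrt = likelihood_ratio_test(-m0.lnL, -free.lnL, df=df_free,
                                    alpha_corrected=level)
        rows.append({
            "tree": tree_name, "model": "free-ratio",
            "neg_lnL": -free.lnL, "statistic": lrt.statistic,
            "df": df_free, "p": lrt.p,
            "significant": lrt.significant_after_correction,
        })
    report = pd.DataFrame(rows)
    report.attrs["bonferroni_level"] = level
    report.attrs["n_tests"] = m_tests
    return report, warnings_list


def run_association_analysis(config: AnalysisConfig,
                             regression_clade: str = "Cetacea",
                             subset_clade: str | None = "Odontoceti"
                             ) -> pd.DataFrame:
    """Root-to-tip ω extraction followed by the PGLS battery.

    ``regression_clade`` names the clade whose LCA anchors the
    root-to-tip paths (its phenotyped members enter the regressions);
    ``subset_clade`` adds a restricted scope (e.g. toothed whales only).
    """
    if config.time_tree is None or config.phenotypes is None:
        raise ValueError("association analysis needs a time tree and "
                         "phenotype table")
    clade_tips = config.clades.get(regression_clade)
    if clade_tips is None:
        raise ValueError(f"clade {regression_clade!r} not configured")
    phen = config.phenotypes
    missing = [s for s in clade_tips
               if s not in set(phen["species"])]
    tips = [t for t in clade_tips if t not in missing]
    rtt = root_to_tip_table(config.alignment, config.species_tree,
                            clade_tips, tips)
    scopes: dict[str, list[str] | None] = {"all": None}
    if subset_clade and subset_clade in config.clades:
        scopes[subset_clade] = config.clades[subset_clade]
    report = association_battery(rtt, phen, config.time_tree, scopes)
    report.attrs["dropped_species"] = missing
    return report
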