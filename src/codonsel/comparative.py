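"""Phenotype engineering and phylogenetically controlled regression.

The encephalization quotient follows the standard mammalian allometry
EQ = brain / (0.12 · body^0.67) with masses in grams.  Regressions are
generalized least squares with a Brownian-motion covariance — residual
covariance between two species proportional to the length of their
shared root path on a time-calibrated tree (Pagel's λ fixed at 1).
Log transforms are base 10 and are applied by the callers that build
regression inputs, not by ``pgls_fit`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats

from .io import Phylogeny

EQ_COEFFICIENT = 0.12
EQ_EXPONENT = 0.67


def encephalization_quotient(brain_mass, body_mass):
    """EQ = brain / (0.12 · body^0.67), masses in grams."""
    brain = np.asarray(brain_mass, dtype=float)
    body = np.asarray(body_mass, dtype=float)
    if np.any(brain <= 0) or np.any(body <= 0):
        raise ValueError("masses must be positive")
    return brain / (EQ_COEFFICIENT * body ** EQ_EXPONENT)


def body_mass_for_eq(brain_mass, eq):
    """Invert the EQ allometry: body mass giving the stated EQ."""
    brain = np.asarray(brain_mass, dtype=float)
    return (brain / (EQ_COEFFICIENT * np.asarray(eq, dtype=float))) \
        ** (1.0 / EQ_EXPONENT)


def bm_covariance(tree: Phylogeny, species: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = depth of the MRCA of i, j."""
    missing = set(species) - set(tree.tip_names())
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    depths = tree.depths()
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(species)
    cov = np.zeros((n, n))
    for i, a in enumerate(species):
        cov[i, i] = depths[a]
        for j in range(i + 1, n):
            b = species[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            cov[i, j] = cov[j, i] = 0.5 * (depths[a] + depths[b] - d)
    return cov


@dataclass
class RegressionResult:
    predictors: list[str]
    coefficients: dict[str, float]
    t_statistics: dict[str, float]
    one_tailed_p: dict[str, float]
    directions: dict[str, str]
    R_squared: float
    n: int
    df_resid: int
    intercept: float
    covariance_source: str


def _one_tailed(t: float, df: int, direction: str) -> float:
    if direction == "positive":
        return float(_stats.t.sf(t, df))
    if direction == "negative":
        return float(_stats.t.cdf(t, df))
    if direction == "two-sided":
        return float(2 * _stats.t.sf(abs(t), df))
    raise ValueError(f"unknown test direction {direction!r}")


def pgls_fit(response: pd.Series, predictors: pd.DataFrame,
             tree: Phylogeny, direction="positive") -> RegressionResult:
    """GLS regression with BM covariance from ``tree``.

    ``response`` and ``predictors`` are aligned on their species index
    (already transformed as desired).  ``direction`` may be a single
    string for all predictors or a dict per predictor column.
    """
    species = list(response.index)
    X = predictors.loc[species]
    if X.isna().any().any() or response.isna().any():
        raise ValueError("missing values in regression inputs")
    n, k = len(species), X.shape[1]
    if n < k + 2:
        raise ValueError(f"{n} species cannot support {k} predictors")
    cov = bm_covariance(tree, species)
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    if isinstance(direction, str):
        direction = {c: direction for c in X.columns}
    y = response.to_numpy(dtype=float)
    df = n - X.shape[1] - 1
    if np.ptp(y) == 0.0:
        # degenerate: a constant response carries no information; all
        # slopes are exactly 0 and every one-tailed test sits at t = 0
        return RegressionResult(
            predictors=list(X.columns),
            coefficients={c: 0.0 for c in X.columns},
            t_statistics={c: 0.0 for c in X.columns},
            one_tailed_p={c: _one_tailed(0.0, df, direction[c])
                          for c in X.columns},
            directions=dict(direction),
            R_squared=0.0, n=n, df_resid=df,
            intercept=float(y[0]), covariance_source=tree.name,
        )
    model = sm.GLS(y, design, sigma=cov).fit()
    t_stats = dict(zip(X.columns, model.tvalues[1:]))
    df = int(model.df_resid)
    r2 = float(model.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0
    return RegressionResult(
        predictors=list(X.columns),
        coefficients=dict(zip(X.columns, model.params[1:])),
        t_statistics={c: float(t) for c, t in t_stats.items()},
        one_tailed_p={c: _one_tailed(t, df, direction[c])
                      for c, t in t_stats.items()},
        directions=dict(direction),
        R_squared=float(np.clip(r2, 0.0, 1.0)),
        n=n,
        df_resid=df,
        intercept=float(model.params[0]),
        covariance_source=tree.name,
    )


def brain_size_residuals(brain: pd.Series, body: pd.Series,
                         tree: Phylogeny) -> pd.Series:
    """Residual relative brain size: residuals of a PGLS of log10 brain
    mass on log10 body mass."""
    y = np.log10(brain)
    x = pd.DataFrame({"log_body": np.log10(body)}, index=body.index)
    fit = pgls_fit(y, x, tree, direction="two-sided")
    pred = fit.intercept + fit.coefficients["log_body"] * x["log_body"]
    return y - pred


PANEL_A_TRAITS = ("brain_mass", "EQ", "body_mass", "max_body_mass")


def association_battery(root_to_tip: pd.DataFrame, phenotypes: pd.DataFrame,
                        tree: Phylogeny,
                        scopes: dict[str, list[str] | None] | None = None
                        ) -> pd.DataFrame:
    """ω-vs-phenotype regression battery.

    Panel A: log10 root-to-tip ω against each log10 trait, one-tailed
    positive, across each scope (e.g. all cetaceans / odontocetes only).
    Panel B: each of log10 body and brain mass against log10 dN and
    log10 dS jointly, testing dN one-tailed positive and dS one-tailed
    negative (across the first scope).
    """
    rtt = root_to_tip.set_index("species") \
        if "species" in root_to_tip.columns else root_to_tip
    phen = phenotypes.set_index("species") \
        if "species" in phenotypes.columns else phenotypes
    scopes = scopes or {"all": None}
    rows = []
    for scope_name, scope_tips in scopes.items():
        species = [s for s in rtt.index if scope_tips is None
                   or s in set(scope_tips)]
        species = [s for s in species
                   if s in phen.index and not rtt.loc[s, "undefined"]]
        if len(species) < 4:
            raise ValueError(
                f"scope {scope_name!r} has {len(species)} usable species; "
                "at least 4 are required")
        log_omega = np.log10(rtt.loc[species, "omega"].astype(float))
        for trait in PANEL_A_TRAITS:
            x = pd.DataFrame(
                {f"log_{trait}": np.log10(phen.loc[species, trait])},
                index=species)
            fit = pgls_fit(log_omega, x, tree, direction="positive")
            rows.append({
                "panel": "A", "scope": scope_name,
                "analysis": f"omega vs {trait}",
                "n": fit.n, "R2": fit.R_squared,
                "t": fit.t_statistics[f"log_{trait}"],
                "p_one_tailed": fit.one_tailed_p[f"log_{trait}"],
                "direction": "positive",
            })
    # Panel B on the first scope
    first = next(iter(scopes.values()))
    species = [s for s in rtt.index if first is None or s in set(first)]
    species = [s for s in species
               if s in phen.index and not rtt.loc[s, "undefined"]]
    preds = pd.DataFrame({
        "log_dN": np.log10(rtt.loc[species, "dN"].astype(float)),
        "log_dS": np.log10(rtt.loc[species, "dS"].astype(float)),
    }, index=species)
    for trait in ("body_mass", "brain_mass"):
        y = pd.Series(np.log10(phen.loc[species, trait]), index=species,
                      dtype=float)
        fit = pgls_fit(y, preds, tree,
                       direction={"log_dN": "positive",
                                  "log_dS": "negative"})
        rows.append({
            "panel": "B", "scope": next(iter(scopes)),
            "analysis": f"{trait} vs dN & dS",
            "n": fit.n, "R2": fit.R_squared,
            "t": fit.t_statistics["log_dN"],
            "p_one_tailed": fit.one_tailed_p["log_dN"],
            "direction": "positive",
            "t_dS": fit.t_statistics["log_dS"],
            "p_dS_one_tailed": fit.one_tailed_p["log_dS"],
            "direction_dS": "negative",
        })
    return pd.DataFrame(rows)
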