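"""Likelihood-ratio tests and familywise error control.

Conventions: the statistic is 2·(−lnL_null − (−lnL_alt)); significance
comes from a χ² upper tail with the caller's degrees of freedom.  When
the null pins a parameter at the boundary of the alternative's space
(M8a's ωs = 1 inside M8), the p-value is halved — the null distribution
is a 50:50 mixture of χ²₀ and χ²₁.  Branch-model batteries use a
Bonferroni-corrected per-test level α/m with ≤ comparison semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _stats


class InconsistentFitError(ValueError):
    """The alternative fit is worse than the null beyond optimizer noise."""


#: |negative statistic| below this is clamped to zero (optimizer noise);
#: anything larger indicates a failed fit and raises.
NEGATIVE_TOLERANCE = 1e-3


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    halved: bool = False
    significant_after_correction: bool | None = None
    clamped: bool = False


def likelihood_ratio_test(null_neg_lnL: float, alt_neg_lnL: float, df: int,
                          halve: bool = False,
                          alpha_corrected: float | None = None) -> LRTResult:
    """LRT from the two models' *negative* log-likelihoods.

    ``alpha_corrected``, when given, sets the significant-after-
    correction flag with p ≤ α semantics.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    statistic = 2.0 * (float(null_neg_lnL) - float(alt_neg_lnL))
    clamped = False
    if statistic < 0:
        if statistic < -NEGATIVE_TOLERANCE:
            raise InconsistentFitError(
                f"-2ΔlnL = {statistic:.6f} < 0: the alternative fit is "
                "worse than the null; refit with more starting points")
        statistic, clamped = 0.0, True
    p = float(_stats.chi2.sf(statistic, df))
    if halve:
        p *= 0.5
    significant = None if alpha_corrected is None else (p <= alpha_corrected)
    return LRTResult(statistic=statistic, df=df, p=p, halved=halve,
                     significant_after_correction=significant,
                     clamped=clamped)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level α/m for a battery of m tests (compare with ≤)."""
    if m < 1:
        raise ValueError("test count must be at least 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
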