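"""Multiple-testing corrections across responses.

Adjusted p-values are delegated to :func:`statsmodels.stats.multitest.multipletests`
(Bonferroni FWER control and Benjamini-Hochberg step-up FDR control); this
module adds the conventions the stage-wise frameworks need on top: per-response
adjustment factors c^(r) (so that the response-specific significance level
alpha / c^(r) can be carried into model selection), and NaN handling for
degenerate responses, which carry no test and are excluded from the count of
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


@dataclass
class AdjustedP:
    """Raw and adjusted p-values with per-response adjustment factors.

    ``c`` is the multiplicative adjustment applied to each raw p-value:
    constant R under Bonferroni, and the operational ratio adjusted/raw under
    Benjamini-Hochberg (1 where the raw p is exactly 0). Degenerate entries
    (raw p NaN) receive adjusted p = 1, c = NaN, and do not count towards the
    number of tests R.
    """

    raw: np.ndarray
    adjusted: np.ndarray
    c: np.ndarray
    significant: np.ndarray
    method: str
    alpha: float
    n_tests: int


def adjust(pvals, method: str = "bh", alpha: float = 0.05) -> AdjustedP:
    raw = np.asarray(pvals, dtype=float)
    if raw.ndim != 1:
        raise ValueError("p-values must be a 1-d array")
    ok = ~np.isnan(raw)
    if np.any((raw[ok] < 0) | (raw[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _METHODS:
        raise ValueError(f"unknown correction {method!r}; choose from {sorted(_METHODS)}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    adjusted = np.ones_like(raw)
    c = np.full_like(raw, np.nan)
    R = int(ok.sum())
    if R > 0:
        _, adj, _, _ = multipletests(raw[ok], alpha=alpha, method=_METHODS[method])
        adjusted[ok] = adj
        if method == "bonferroni":
            c[ok] = R
        else:
            sub_raw = raw[ok]
            sub_c = np.ones(R)
            nz = sub_raw > 0
            sub_c[nz] = adj[nz] / sub_raw[nz]
            c[ok] = sub_c
    significant = np.zeros_like(raw, dtype=bool)
    significant[ok] = adjusted[ok] <= alpha
    return AdjustedP(raw=raw, adjusted=adjusted, c=c, significant=significant,
                     method=method, alpha=alpha, n_tests=R)


def adjust_bonferroni(pvals, alpha: float = 0.05) -> AdjustedP:
    """Bonferroni FWER control: adjusted p = min(1, R p), c^(r) = R."""
    return adjust(pvals, method="bonferroni", alpha=alpha)


def adjust_bh(pvals, alpha: float = 0.05) -> AdjustedP:
    """Benjamini-Hochberg step-up FDR control."""
    return adjust(pvals, method="bh", alpha=alpha)


def per_test_level(alpha: float, R: int, mode: str = "sidak") -> float:
    """Per-test significance level controlling the FWER over R tests.

    'sidak' gives the exact level 1 - (1 - alpha)^(1/R) for independent
    tests; 'bonferroni' the upper-bound approximation alpha / R.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if R < 1:
        raise ValueError("R must be >= 1")
    if mode == "sidak":
        return 1.0 - (1.0 - alpha) ** (1.0 / R)
    if mode == "bonferroni":
        return alpha / R
    raise ValueError(f"unknown mode {mode!r}")


def response_alpha(alpha: float, c: float) -> float:
    """Response-specific significance level alpha / c^(r) for model selection."""
    if not np.all(np.asarray(c) >= 1):
        raise ValueError("adjustment factors must be >= 1")
    return alpha / c
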