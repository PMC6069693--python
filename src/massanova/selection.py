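"""Predictive-model selection per response via F-tests under marginality.

The saturated model provides the term-wise F tests; the predictive model is
the set of significant terms completed under marginality (a retained
interaction forces its main effects in). Two selection strategies are
provided: a single pass against the saturated residual (default), and a
backward sequential scheme that pools dropped high-order terms into the
residual before testing lower-order terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import (
    Decomposition,
    Design,
    ModelSpec,
    Term,
    decompose,
    f_test,
    marginality_closure,
    predict_cells,
    treatment_terms,
)

__all__ = [
    "SelectionConfig",
    "marginality_closure",
    "candidate_models",
    "select_model",
    "fit_predictive",
]


@dataclass(frozen=True)
class SelectionConfig:
    """How terms are tested during model selection.

    method : 'single-pass' tests every term against the saturated residual in
        one pass; 'sequential-pooling' tests interactions first, pooling the
        SS and df of dropped terms into the residual before testing
        lower-order terms.
    allow_nonhierarchical : when True, the significant-term set is returned
        as-is instead of its marginality closure.
    """

    method: str = "single-pass"
    allow_nonhierarchical: bool = False

    def __post_init__(self):
        if self.method not in ("single-pass", "sequential-pooling"):
            raise ValueError(f"unknown selection method {self.method!r}")


def candidate_models(design: Design, allow_nonhierarchical: bool = False) -> list[ModelSpec]:
    """All possible predictive models for a design.

    Hierarchical mode returns only marginality-closed term subsets (5 models
    for two crossed factors, 19 for three); non-hierarchical mode returns all
    2^T subsets of treatment terms.
    """
    terms = treatment_terms(design)
    models = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            spec = ModelSpec(frozenset(combo))
            if allow_nonhierarchical or spec.is_closed():
                models.append(spec)
    return models


def _single_pass_include(dec: Decomposition, levels: np.ndarray) -> np.ndarray:
    """Vectorised single-pass selection over all responses of a decomposition.

    Returns a boolean (R, n_terms) inclusion matrix after marginality closure:
    a term is included iff it, or any superset interaction, is significant at
    the (response-specific) level.
    """
    terms = dec.terms
    ss = dec.ss_matrix()
    dfv = dec.df_vector()
    _, p = f_test(ss, dfv[None, :], dec.ss_res[:, None], dec.df_res)
    sig = p <= levels[:, None]
    # degenerate responses (zero total SS) select nothing
    sig &= (dec.ss_total > 0)[:, None]
    include = np.zeros_like(sig)
    for j, t in enumerate(terms):
        supersets = [k for k, u in enumerate(terms) if set(t) <= set(u)]
        include[:, j] = sig[:, supersets].any(axis=1)
    return include, sig


def _sequential_include(dec: Decomposition, level: float, r: int) -> frozenset[Term]:
    """Backward sequential-pooling selection for response column r."""
    terms = list(dec.terms)
    ss = {t: float(dec.ss[t][r]) for t in terms}
    df = {t: dec.df[t] for t in terms}
    res_ss = float(dec.ss_res[r])
    res_df = dec.df_res
    retained: set[Term] = set(terms)
    for order in sorted({len(t) for t in terms}, reverse=True):
        protected = set()
        for t in retained:
            if len(t) > order:
                protected.update(s for s in retained if len(s) == order and set(s) < set(t))
        dropped_now = []
        for t in [t for t in terms if len(t) == order and t in retained]:
            if t in protected:
                continue
            _, p = f_test(ss[t], df[t], res_ss, res_df)
            if float(p) > level:
                dropped_now.append(t)
        for t in dropped_now:
            retained.discard(t)
            res_ss += ss[t]
            res_df += df[t]
    return frozenset(retained)


def select_model(
    y,
    design: Design,
    level: float,
    config: SelectionConfig | None = None,
) -> ModelSpec:
    """Select the predictive model for one response at a significance level.

    Ties at p == level count as significant. The result is marginality-closed
    unless ``config.allow_nonhierarchical``.
    """
    if not 0 < level < 1:
        raise ValueError("significance level must be in (0, 1)")
    config = config or SelectionConfig()
    dec = decompose(np.asarray(y, dtype=float), design)
    if config.method == "sequential-pooling":
        terms = _sequential_include(dec, level, 0)
        if config.allow_nonhierarchical:
            return ModelSpec(terms)
        return ModelSpec(marginality_closure(terms))
    include, sig = _single_pass_include(dec, np.array([level]))
    cols = sig[0] if config.allow_nonhierarchical else include[0]
    return ModelSpec(frozenset(t for t, keep in zip(dec.terms, cols) if keep))


def fit_predictive(y, design: Design, model: ModelSpec):
    """Fit a predictive model: predictions plus the pooled residual.

    The SS and df of dropped treatment terms are pooled into the residual
    (the inflated-residual semantics of the overall test of a reduced model).
    Returns (prediction table, pooled residual MS, pooled residual df).
    """
    dec = decompose(np.asarray(y, dtype=float), design)
    retained_df = int(sum(dec.df[t] for t in model.terms))
    dropped_ss = float(sum(dec.ss[t][0] for t in dec.terms if t not in model.terms))
    res_ss = float(dec.ss_res[0]) + dropped_ss
    res_df = design.N - 1 - design.block_df - retained_df
    preds = predict_cells(y, design, model)
    return preds, res_ss / res_df, res_df
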