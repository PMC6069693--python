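"""Stage-wise analysis pipelines over a full response matrix.

Each framework orders the three steps RANK (order responses by an overall
one-way test), FILTER (multiplicity-correct and discard non-significant
responses) and MODEL (select a predictive model per response by term-wise
F-tests under marginality) differently:

* RFM — rank and filter on the one-way test of the *saturated* model, then
  select a model for the survivors at the response-specific level alpha/c^(r).
* MRF — select a model for every response at the unadjusted level, then rank
  and filter on the one-way test of the *predictive* model (dropped-term SS
  pooled into the residual).
* RMF — rank on the saturated one-way test, select for every response at
  alpha/c^(r), then filter on the predictive-model one-way test at the same
  response-specific level.
* MSF — per-explanatory-term multiplicity corrections across responses (or one
  global correction over all R x p tests); this can violate marginality and
  such responses are flagged.

All pipelines are vectorised over responses via a single orthogonal
decomposition of the response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import multiplicity
from .design import (
    Decomposition,
    Design,
    ModelSpec,
    Term,
    decompose,
    f_test,
    marginality_closure,
    term_label,
)
from .selection import SelectionConfig, _sequential_include, _single_pass_include

FILTERED_LABEL = "filtered"


@dataclass
class FrameworkResult:
    """Per-response outcome of a stage-wise framework run.

    ``table`` is indexed by response id with columns ``p_raw`` (overall
    one-way p), ``p_adj``, ``c`` (adjustment factor), ``rank`` (1 = most
    significant, ties share the minimum rank), ``passed`` (survived the
    filter) and ``model`` (predictive-model label; empty for responses that
    were filtered before model selection). ``term_p``/``term_p_adj`` hold the
    saturated per-term p-values (raw / multiplied by c^(r)), and ``relevance``
    the per-term sqrt(MS_T) biological-relevance measure.
    """

    framework: str
    correction: str
    alpha: float
    design: Design
    table: pd.DataFrame
    models: dict[object, ModelSpec | None]
    term_p: pd.DataFrame
    term_p_adj: pd.DataFrame
    relevance: pd.DataFrame
    sig_terms: pd.DataFrame  # raw significant-term pattern used in selection

    @property
    def response_ids(self) -> pd.Index:
        return self.table.index

    @property
    def survivors(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def _as_matrix(Y) -> tuple[np.ndarray, pd.Index]:
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), Y.columns
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, pd.RangeIndex(arr.shape[1])


def _saturated_oneway(dec: Decomposition) -> np.ndarray:
    """p-value of the one-way test of the saturated model, per response.

    Degenerate (zero total SS) responses get NaN: they carry no test.
    """
    ss1 = dec.ss_matrix().sum(axis=1)
    df1 = int(dec.df_vector().sum())
    _, p = f_test(ss1, df1, dec.ss_res, dec.df_res)
    p = np.asarray(p, dtype=float)
    p[dec.ss_total <= 0] = np.nan
    return p


def _predictive_oneway(
    dec: Decomposition,
    include: np.ndarray,
    lack_of_fit: bool = False,
    convention: str = "standard",
) -> np.ndarray:
    """One-way p of each response's predictive model (pooled residual).

    ``include`` is a boolean (R, n_terms) matrix. Null models get p = 1;
    degenerate responses get NaN. Under the "as-printed" df convention, a
    purely additive model on factors with t_1..t_m levels is counted on
    (sum t_f - 1, N - sum t_f) degrees of freedom; models containing an
    interaction (where that counting is undefined) keep the standard one.
    """
    if convention not in ("standard", "as-printed"):
        raise ValueError(f"unknown df convention {convention!r}")
    ss = dec.ss_matrix()
    dfv = dec.df_vector()
    N = dec.design.N
    retained_ss = (ss * include).sum(axis=1)
    df1 = include @ dfv
    dropped_ss = ss.sum(axis=1) - retained_ss
    if lack_of_fit:
        den_ss = np.broadcast_to(dec.ss_res, retained_ss.shape).copy()
        df2 = np.full_like(df1, float(dec.df_res))
    else:
        den_ss = dec.ss_res + dropped_ss
        df2 = N - 1 - dec.block_df - df1
        if convention == "as-printed":
            is_main = np.array([len(t) == 1 for t in dec.terms])
            levels = np.array(
                [dec.design.n_levels(t[0]) if len(t) == 1 else 0 for t in dec.terms],
                dtype=float,
            )
            additive = ~(include & ~is_main).any(axis=1) & (include.sum(axis=1) >= 2)
            tsum = include @ levels
            df1 = np.where(additive, tsum - 1, df1)
            df2 = np.where(additive, N - tsum - dec.block_df, df2)
    p = np.ones_like(retained_ss)
    tested = df1 > 0
    _, p_t = f_test(retained_ss[tested], df1[tested], den_ss[tested], df2[tested])
    p[tested] = p_t
    p[dec.ss_total <= 0] = np.nan
    return p


def _select_matrix(
    dec: Decomposition, levels: np.ndarray, config: SelectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-response term inclusion (after closure) and raw significance marks."""
    if config.method == "single-pass":
        return _single_pass_include(dec, levels)
    R = dec.n_responses
    T = len(dec.terms)
    include = np.zeros((R, T), dtype=bool)
    sig = np.zeros((R, T), dtype=bool)
    for r in range(R):
        if dec.ss_total[r] <= 0:
            continue
        kept = _sequential_include(dec, float(levels[r]), r)
        closed = marginality_closure(kept)
        for j, t in enumerate(dec.terms):
            sig[r, j] = t in kept
            include[r, j] = t in closed
    return include, sig


def _rank(p_adj: np.ndarray, p_raw: np.ndarray) -> np.ndarray:
    """Ranks ascending by (adjusted p, raw p); ties share the minimum rank."""
    a = np.where(np.isnan(p_adj), np.inf, p_adj)
    b = np.where(np.isnan(p_raw), np.inf, p_raw)
    _, codes = np.unique(np.column_stack([a, b]), axis=0, return_inverse=True)
    return rankdata(codes, method="min").astype(int)


def _term_frames(dec: Decomposition, ids: pd.Index, c: np.ndarray):
    ss = dec.ss_matrix()
    dfv = dec.df_vector()
    _, p = f_test(ss, dfv[None, :], dec.ss_res[:, None], dec.df_res)
    cols = [term_label(t) for t in dec.terms]
    term_p = pd.DataFrame(p, index=ids, columns=cols)
    with np.errstate(invalid="ignore"):
        adj = np.minimum(1.0, p * c[:, None])
    term_p_adj = pd.DataFrame(adj, index=ids, columns=cols)
    relevance = pd.DataFrame(np.sqrt(ss / dfv[None, :]), index=ids, columns=cols)
    return term_p, term_p_adj, relevance


def _assemble(
    framework: str,
    correction: str,
    alpha: float,
    dec: Decomposition,
    ids: pd.Index,
    p_raw: np.ndarray,
    adj: multiplicity.AdjustedP,
    passed: np.ndarray,
    include: np.ndarray,
    sig: np.ndarray,
    model_assessed: np.ndarray,
) -> FrameworkResult:
    models: dict[object, ModelSpec | None] = {}
    labels = []
    for r, rid in enumerate(ids):
        if model_assessed[r]:
            spec = ModelSpec(frozenset(t for t, keep in zip(dec.terms, include[r]) if keep))
            models[rid] = spec
            labels.append(spec.label())
        else:
            models[rid] = None
            labels.append(FILTERED_LABEL)
    table = pd.DataFrame(
        {
            "p_raw": p_raw,
            "p_adj": adj.adjusted,
            "c": adj.c,
            "rank": _rank(adj.adjusted, p_raw),
            "passed": passed,
            "model": labels,
        },
        index=ids,
    )
    term_p, term_p_adj, relevance = _term_frames(dec, ids, adj.c)
    sig_terms = pd.DataFrame(sig, index=ids, columns=[term_label(t) for t in dec.terms])
    return FrameworkResult(
        framework=framework,
        correction=correction,
        alpha=alpha,
        design=dec.design,
        table=table,
        models=models,
        term_p=term_p,
        term_p_adj=term_p_adj,
        relevance=relevance,
        sig_terms=sig_terms,
    )


def run_rfm(
    Y,
    design: Design,
    correction: str = "bh",
    alpha: float = 0.05,
    selection: SelectionConfig | None = None,
) -> FrameworkResult:
    """Rank, Filter, Model.

    The overall one-way test of the saturated model is multiplicity-corrected
    across responses; non-significant responses are filtered out (no model is
    assigned); the survivors get a predictive model selected at the
    response-specific level alpha / c^(r).
    """
    selection = selection or SelectionConfig()
    mat, ids = _as_matrix(Y)
    dec = decompose(mat, design)
    p_raw = _saturated_oneway(dec)
    adj = multiplicity.adjust(p_raw, method=correction, alpha=alpha)
    passed = adj.significant
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(passed, alpha / adj.c, np.nan)
    include = np.zeros((dec.n_responses, len(dec.terms)), dtype=bool)
    sig = np.zeros_like(include)
    if passed.any():
        sub = Decomposition(
            design=dec.design, terms=dec.terms, df=dec.df,
            ss={t: dec.ss[t][passed] for t in dec.terms},
            block_ss=dec.block_ss[passed] if dec.block_ss is not None else None,
            block_df=dec.block_df, ss_res=dec.ss_res[passed], df_res=dec.df_res,
            ss_total=dec.ss_total[passed], grand=dec.grand[passed],
        )
        inc_s, sig_s = _select_matrix(sub, levels[passed], selection)
        include[passed] = inc_s
        sig[passed] = sig_s
    return _assemble("rfm", correction, alpha, dec, ids, p_raw, adj, passed, include, sig,
                     model_assessed=passed)


def run_mrf(
    Y,
    design: Design,
    correction: str = "bh",
    alpha: float = 0.05,
    selection: SelectionConfig | None = None,
    oneway: str = "pooled",
    convention: str = "standard",
) -> FrameworkResult:
    """Model, Rank, Filter.

    A predictive model is selected for every response at the unadjusted level
    alpha; the one-way test of that predictive model (dropped-term SS pooled
    into the residual, or kept as a lack-of-fit term when
    ``oneway='lack-of-fit'``) is multiplicity-corrected and used to filter.
    Responses whose selected model is null receive p = 1.
    """
    if oneway not in ("pooled", "lack-of-fit"):
        raise ValueError("oneway must be 'pooled' or 'lack-of-fit'")
    selection = selection or SelectionConfig()
    mat, ids = _as_matrix(Y)
    dec = decompose(mat, design)
    include, sig = _select_matrix(dec, np.full(dec.n_responses, alpha), selection)
    p_raw = _predictive_oneway(dec, include, lack_of_fit=(oneway == "lack-of-fit"),
                               convention=convention)
    adj = multiplicity.adjust(p_raw, method=correction, alpha=alpha)
    passed = adj.significant
    model_assessed = dec.ss_total > 0
    return _assemble("mrf", correction, alpha, dec, ids, p_raw, adj, passed, include, sig,
                     model_assessed=model_assessed)


def run_rmf(
    Y,
    design: Design,
    correction: str = "bh",
    alpha: float = 0.05,
    selection: SelectionConfig | None = None,
    convention: str = "standard",
) -> FrameworkResult:
    """Rank, Model, Filter.

    Ranking and the adjustment factors c^(r) come from the saturated one-way
    test (as in RFM); a predictive model is then selected for every response
    at alpha / c^(r), and the filter is applied to the predictive-model
    one-way test at the same response-specific level.
    """
    selection = selection or SelectionConfig()
    mat, ids = _as_matrix(Y)
    dec = decompose(mat, design)
    p_sat = _saturated_oneway(dec)
    adj_sat = multiplicity.adjust(p_sat, method=correction, alpha=alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = alpha / adj_sat.c
    levels = np.where(np.isnan(levels), 0.0, levels)
    include, sig = _select_matrix(dec, levels, selection)
    p_pred = _predictive_oneway(dec, include, convention=convention)
    with np.errstate(invalid="ignore"):
        passed = p_pred <= levels
    passed &= ~np.isnan(p_pred)
    adj = multiplicity.AdjustedP(
        raw=p_pred,
        adjusted=np.where(np.isnan(p_pred), 1.0, np.minimum(1.0, p_pred * adj_sat.c)),
        c=adj_sat.c,
        significant=passed,
        method=correction,
        alpha=alpha,
        n_tests=adj_sat.n_tests,
    )
    model_assessed = dec.ss_total > 0
    return _assemble("rmf", correction, alpha, dec, ids, p_pred, adj, passed, include, sig,
                     model_assessed=model_assessed)


@dataclass
class MsfResult:
    """Per-term multiplicity correction across responses (Model, Subset, Filter).

    ``p_adj`` and ``significant`` are response x term frames; in 'per-term'
    mode each term's R p-values are corrected separately, in 'global' mode a
    single correction spans all R x p tests. ``marginality_violations`` flags
    responses whose significant-term set is not marginality-closed.
    """

    mode: str
    correction: str
    alpha: float
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame
    marginality_violations: pd.Series


def run_msf(
    Y,
    design: Design,
    correction: str = "bh",
    alpha: float = 0.05,
    mode: str = "per-term",
    selection: SelectionConfig | None = None,
) -> MsfResult:
    """Per-explanatory-term (or global R x p) multiplicity correction.

    When a ``selection`` config is given, a model selection step at the
    unadjusted level alpha is applied first and only the terms of each
    response's predictive model are tested (others are excluded from the
    correction).
    """
    if mode not in ("per-term", "global"):
        raise ValueError("mode must be 'per-term' or 'global'")
    mat, ids = _as_matrix(Y)
    dec = decompose(mat, design)
    ss = dec.ss_matrix()
    dfv = dec.df_vector()
    _, p = f_test(ss, dfv[None, :], dec.ss_res[:, None], dec.df_res)
    p = np.asarray(p, dtype=float)
    p[dec.ss_total <= 0, :] = np.nan
    if selection is not None:
        include, _ = _select_matrix(dec, np.full(dec.n_responses, alpha), selection)
        p = np.where(include, p, np.nan)
    cols = [term_label(t) for t in dec.terms]
    adj = np.ones_like(p)
    sig = np.zeros_like(p, dtype=bool)
    if mode == "per-term":
        for j in range(p.shape[1]):
            a = multiplicity.adjust(p[:, j], method=correction, alpha=alpha)
            adj[:, j] = a.adjusted
            sig[:, j] = a.significant
    else:
        a = multiplicity.adjust(p.ravel(), method=correction, alpha=alpha)
        adj = a.adjusted.reshape(p.shape)
        sig = a.significant.reshape(p.shape)
    violations = np.zeros(len(ids), dtype=bool)
    for j, t in enumerate(dec.terms):
        if len(t) == 1:
            continue
        for k, s in enumerate(dec.terms):
            if set(s) < set(t):
                violations |= sig[:, j] & ~sig[:, k]
    return MsfResult(
        mode=mode,
        correction=correction,
        alpha=alpha,
        p_raw=pd.DataFrame(p, index=ids, columns=cols),
        p_adj=pd.DataFrame(adj, index=ids, columns=cols),
        significant=pd.DataFrame(sig, index=ids, columns=cols),
        marginality_violations=pd.Series(violations, index=ids),
    )


def group_by_model(result: FrameworkResult, by: str = "model") -> pd.DataFrame:
    """Partition responses by predictive model (or significant-term pattern).

    Returns one row per group with its size and member responses. Filtered
    responses form their own 'filtered' group.
    """
    if by == "model":
        labels = result.table["model"]
    elif by == "pattern":
        cols = result.sig_terms.columns
        def pat(row):
            terms = [c for c in cols if row[c]]
            return "+".join(terms) if terms else "null"
        labels = pd.Series(
            [pat(result.sig_terms.loc[i]) if result.models[i] is not None else FILTERED_LABEL
             for i in result.table.index],
            index=result.table.index,
        )
    else:
        raise ValueError("by must be 'model' or 'pattern'")
    groups = labels.groupby(labels).groups
    rows = [
        {"group": g, "n": len(members), "responses": ";".join(map(str, members))}
        for g, members in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["group", "n", "responses"])


def rank_responses(result: FrameworkResult) -> pd.Index:
    """Response ids ordered by adjusted then raw overall p (stable for ties)."""
    t = result.table
    order = np.lexsort((
        np.arange(len(t)),
        np.where(np.isnan(t["p_raw"].to_numpy()), np.inf, t["p_raw"].to_numpy()),
        np.where(np.isnan(t["p_adj"].to_numpy()), np.inf, t["p_adj"].to_numpy()),
    ))
    return t.index[order]
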