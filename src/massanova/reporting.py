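"""Biological-relevance measures and plot-ready volcano/heatmap tables.

Statistical significance alone rarely identifies the interesting responses in
an 'omics screen; these helpers couple the frameworks' adjusted p-values with
relevance measures on the natural scale: predicted fold changes to a baseline
condition, the maximal fold increase/decrease under any condition, and the
generalised per-term relevance sqrt(MS_T) for factors with more than two
levels.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import AnovaTable
from .frameworks import FrameworkResult


def _condition_label(row: pd.Series, factors: Sequence[str]) -> str:
    return ",".join(f"{f}={row[f]}" for f in factors)


def fold_change_table(
    predictions: pd.DataFrame,
    baseline: Mapping[str, str],
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-condition fold changes of predicted means against a baseline cell.

    Predictions are on the log scale with the stated base (default log2, the
    usual abundance scale); the fold change for a condition is
    base**(prediction - baseline prediction).
    """
    factors = [c for c in predictions.columns if c != "prediction"]
    mask = np.ones(len(predictions), dtype=bool)
    for f, lvl in baseline.items():
        if f not in factors:
            raise ValueError(f"baseline names unknown factor {f!r}")
        mask &= predictions[f].astype(str) == str(lvl)
    if mask.sum() != 1:
        raise ValueError(f"baseline {dict(baseline)} does not identify exactly one treatment condition")
    base_pred = float(predictions.loc[mask, "prediction"].iloc[0])
    out = predictions.copy()
    out["fold_change"] = np.power(log_base, out["prediction"] - base_pred)
    out["condition"] = out.apply(lambda r: _condition_label(r, factors), axis=1)
    out["is_baseline"] = mask
    return out


def max_fold_change(fold_changes: pd.DataFrame) -> tuple[float, float]:
    """Maximal fold increase and decrease over non-baseline conditions.

    The decrease is reported as a factor >= its reciprocal scale (a fold
    change of 0.25 is a 4-fold decrease). Returns (max increase, max
    decrease).
    """
    others = fold_changes.loc[~fold_changes["is_baseline"], "fold_change"]
    if others.empty:
        raise ValueError("no non-baseline conditions")
    fc = others.to_numpy(dtype=float)
    return float(fc.max()), float((1.0 / fc).max())


def term_relevance(table: AnovaTable, c: float = 1.0) -> pd.DataFrame:
    """Per-term relevance sqrt(MS_T) with multiplicity-adjusted term p-values.

    Each treatment mean square is tested against MS_T / MS_res = 1 (the
    term's F test); the p-value is multiplied by the response's one-way
    adjustment factor c^(r) and capped at 1. sqrt(MS_T) generalises the fold
    change axis of a volcano plot to multi-level factors.
    """
    if c < 1:
        raise ValueError("adjustment factor c must be >= 1")
    sub = table.table.loc[list(table.treatment_labels)]
    rel = np.sqrt(sub["mean_sq"].to_numpy(dtype=float))
    p_raw = sub["p"].to_numpy(dtype=float)
    p_adj = np.minimum(1.0, p_raw * c)
    return pd.DataFrame(
        {"sqrt_ms": rel, "p_raw": p_raw, "p_adj": p_adj},
        index=list(table.treatment_labels),
    )


def _neglog10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return -np.log10(p)


def volcano_tables(
    result: FrameworkResult,
    fold_changes: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    fc_threshold: float = 4.0,
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables coupling significance with relevance.

    Returns a dict with:

    - ``per_term``: generalised volcano, one row per surviving response x
      treatment term, with sqrt(MS_T) and -log10 adjusted term p.
    - ``heatmap``: responses x terms -log10 adjusted term p, with a boolean
      significance mask at ``p_threshold``; filtered responses are present but
      fully masked.
    - ``per_condition`` and ``overall`` (when ``fold_changes`` is given: a
      frame indexed by response with one column per condition): classical
      volcanoes against per-condition and maximal fold change.
    """
    survivors = result.survivors
    tables: dict[str, pd.DataFrame] = {}

    long = result.term_p_adj.loc[survivors].stack().rename("p_adj").reset_index()
    long.columns = ["response", "term", "p_adj"]
    rel_long = result.relevance.loc[survivors].stack().rename("sqrt_ms").reset_index()
    long["sqrt_ms"] = rel_long["sqrt_ms"]
    long["neg_log10_p"] = _neglog10(long["p_adj"].to_numpy(dtype=float))
    long["significant"] = long["p_adj"] <= p_threshold
    long["relevant"] = long["sqrt_ms"] ** 2 > fc_threshold
    tables["per_term"] = long

    heat = pd.DataFrame(
        _neglog10(result.term_p_adj.to_numpy(dtype=float)),
        index=result.term_p_adj.index,
        columns=result.term_p_adj.columns,
    )
    mask = result.term_p_adj <= p_threshold
    mask.loc[~result.table["passed"]] = False
    tables["heatmap"] = heat
    tables["heatmap_mask"] = mask

    if fold_changes is not None:
        fc = fold_changes.loc[fold_changes.index.intersection(survivors)]
        neg = _neglog10(result.table.loc[fc.index, "p_adj"].to_numpy(dtype=float))
        per_cond = fc.stack().rename("fold_change").reset_index()
        per_cond.columns = ["response", "condition", "fold_change"]
        per_cond["neg_log10_p"] = per_cond["response"].map(
            pd.Series(neg, index=fc.index)
        )
        per_cond["log_fc"] = np.log2(per_cond["fold_change"].to_numpy(dtype=float))
        tables["per_condition"] = per_cond

        arr = fc.to_numpy(dtype=float)
        overall = pd.DataFrame(
            {
                "max_fold_increase": arr.max(axis=1),
                "max_fold_decrease": (1.0 / arr).max(axis=1),
                "neg_log10_p": neg,
            },
            index=fc.index,
        )
        overall["important"] = (
            (result.table.loc[fc.index, "p_adj"] <= p_threshold)
            & (
                (overall["max_fold_increase"] >= fc_threshold)
                | (overall["max_fold_decrease"] >= fc_threshold)
            )
        )
        tables["overall"] = overall
    return tables
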