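"""File interfaces: response matrices, design tables, contrasts, results.

Responses are columns and samples rows (first column = sample id), matching
common 'omics export layouts; ``transpose=True`` accepts the opposite
orientation. Values are assumed to be log-scale abundances; linear-scale data
can be logged at load time.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import ContrastSet, Design
from .frameworks import FrameworkResult, group_by_model


def read_response_matrix(
    path: str | Path,
    sep: str | None = None,
    transpose: bool = False,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Load a samples x responses matrix from delimited text.

    Non-numeric or missing values cause the whole response (column) to be
    dropped with a warning. ``log_base=0`` means the file holds linear-scale
    abundances, which are log2-transformed before analysis.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.columns[numeric.isna().any(axis=0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} response(s) with missing or non-numeric values: "
            f"{list(bad[:10])}{'...' if len(bad) > 10 else ''}"
        )
        numeric = numeric.drop(columns=bad)
    if numeric.shape[1] == 0:
        raise ValueError("no numeric response columns remain after validation")
    if log_base == 0:
        if (numeric <= 0).any().any():
            raise ValueError("linear-scale data must be positive to be log-transformed")
        numeric = np.log2(numeric)
    return numeric


def read_design_table(
    path: str | Path,
    factors: Sequence[str] | None = None,
    block: str | None = None,
    sep: str | None = None,
) -> tuple[Design, pd.Index]:
    """Load a design table (first column = sample id) into a :class:`Design`.

    Returns the design and the sample order its observations follow; align the
    response matrix with :func:`align_responses`. Imbalance is rejected with a
    per-cell count report.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in design table: "
                         f"{df.index[df.index.duplicated()].unique().tolist()}")
    if factors is None:
        factors = [c for c in df.columns if c != block]
    missing = [f for f in factors if f not in df.columns]
    if missing:
        raise ValueError(f"design table lacks factor column(s) {missing}")
    levels = {}
    codes = {}
    for f in factors:
        vals = df[f].astype(str)
        lv = tuple(sorted(vals.unique()))
        levels[f] = lv
        lookup = {v: i for i, v in enumerate(lv)}
        codes[f] = vals.map(lookup).to_numpy(dtype=np.int64)
    blk = None
    if block is not None:
        if block not in df.columns:
            raise ValueError(f"design table lacks block column {block!r}")
        bvals = df[block].astype(str)
        blv = tuple(sorted(bvals.unique()))
        blookup = {v: i for i, v in enumerate(blv)}
        blk = (block, blv, bvals.map(blookup).to_numpy(dtype=np.int64))
    design = Design.from_codes(list(factors), levels, codes, block=blk)
    return design, df.index


def align_responses(Y: pd.DataFrame, samples: pd.Index) -> pd.DataFrame:
    """Reorder the response matrix rows to the design's sample order."""
    missing = [s for s in samples if s not in Y.index]
    if missing:
        raise ValueError(f"response matrix lacks samples {missing[:10]}"
                         f"{'...' if len(missing) > 10 else ''}")
    extra = [s for s in Y.index if s not in set(samples)]
    if extra:
        warnings.warn(f"ignoring {len(extra)} sample(s) absent from the design table")
    return Y.loc[samples]


def read_contrasts(path: str | Path, design: Design, sep: str | None = None) -> dict[str, ContrastSet]:
    """Load contrasts from a long table with columns factor, component, level, coefficient."""
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"factor", "component", "level", "coefficient"}
    if not required <= set(df.columns):
        raise ValueError(f"contrast file must have columns {sorted(required)}")
    out: dict[str, ContrastSet] = {}
    for factor, sub in df.groupby("factor"):
        if factor not in design.factor_names:
            raise ValueError(f"contrast file names unknown factor {factor!r}")
        lv = design.levels[factor]
        comps: dict[str, np.ndarray] = {}
        for comp, rows in sub.groupby("component"):
            vec = np.zeros(len(lv))
            for _, row in rows.iterrows():
                lbl = str(row["level"])
                if lbl not in lv:
                    raise ValueError(f"contrast {comp!r}: level {lbl!r} not in factor {factor!r} ({lv})")
                vec[lv.index(lbl)] = float(row["coefficient"])
            comps[str(comp)] = vec
        out[str(factor)] = ContrastSet.build(str(factor), comps)
    return out


def write_results(
    result: FrameworkResult,
    out_dir: str | Path,
    relevance_overall: pd.DataFrame | None = None,
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write per-response, per-term and model-group tables plus run metadata.

    p-values are written at full double precision so that a rerun with the
    same configuration is byte-identical (apart from the metadata timestamp,
    which is deliberately omitted).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    overall = result.table.copy()
    if relevance_overall is not None:
        overall = overall.join(relevance_overall, how="left")
    paths["overall"] = out / f"{result.framework}_overall.csv"
    overall.to_csv(paths["overall"], index_label="response")

    long = result.term_p.stack().rename("p_raw").reset_index()
    long.columns = ["response", "term", "p_raw"]
    long["p_adj"] = result.term_p_adj.stack().to_numpy()
    long["sqrt_ms"] = result.relevance.stack().to_numpy()
    paths["terms"] = out / f"{result.framework}_terms.csv"
    long.to_csv(paths["terms"], index=False)

    paths["groups"] = out / f"{result.framework}_groups.csv"
    group_by_model(result).to_csv(paths["groups"], index=False)

    from . import __version__

    meta = {
        "framework": result.framework,
        "correction": result.correction,
        "alpha": float(result.alpha),
        "n_responses": int(len(result.table)),
        "factors": {f: list(result.design.levels[f]) for f in result.design.factor_names},
        "replication": int(result.design.replication),
        "block": result.design.block_name,
        "software_version": __version__,
    }
    if config:
        meta["config"] = dict(config)
    paths["metadata"] = out / f"{result.framework}_metadata.yaml"
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths
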