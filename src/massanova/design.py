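"""Balanced factorial designs and orthogonal ANOVA decompositions.

This module is the computational core: it represents balanced (optionally
blocked) factorial treatment structures with up to three factors, decomposes a
response vector (or a whole samples x responses matrix) into orthogonal
per-term sums of squares, and provides the one-way "collapses" of a factorial
model used by the stage-wise analysis frameworks.

All arithmetic exploits the balance and orthogonality of the design: the sum
of squares for a term is computed from marginal means (the effect of a term is
its marginal mean minus all lower-order effects), which for balanced designs
coincides with least-squares projection onto the term's contrast space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# A treatment term is the tuple of factor names it involves, in design order.
Term = tuple[str, ...]

#: sentinel term for the blocking factor (never part of a treatment model)
BLOCK: Term = ("__block__",)

RESIDUAL_LABEL = "Residual"
BLOCK_LABEL = "Block"

_ZERO_TOL = 1e-12


def term_label(term: Term) -> str:
    """Human-readable label for a term, e.g. ``('A','B') -> 'A:B'``."""
    if term == BLOCK:
        return BLOCK_LABEL
    return ":".join(term)


def term_from_label(label: str) -> Term:
    if label == BLOCK_LABEL:
        return BLOCK
    return tuple(label.split(":"))


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Design:
    """A balanced factorial treatment structure, optionally blocked.

    Attributes
    ----------
    factor_names : ordered treatment factor names (1-3 factors).
    levels : mapping factor name -> ordered tuple of level labels.
    codes : mapping factor name -> integer level index per observation.
    replication : observations per treatment cell.
    N : total number of observations.
    block_name, block_levels, block_codes : optional blocking factor.
    """

    factor_names: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]
    codes: dict[str, np.ndarray]
    replication: int
    N: int
    block_name: str | None = None
    block_levels: tuple[str, ...] | None = None
    block_codes: np.ndarray | None = None

    # -- basic geometry ----------------------------------------------------
    def n_levels(self, factor: str) -> int:
        return len(self.levels[factor])

    @property
    def n_cells(self) -> int:
        return int(np.prod([self.n_levels(f) for f in self.factor_names]))

    @property
    def n_blocks(self) -> int:
        return len(self.block_levels) if self.block_levels is not None else 0

    @property
    def block_df(self) -> int:
        return self.n_blocks - 1 if self.block_name else 0

    @property
    def residual_df(self) -> int:
        """Residual df of the saturated model (blocks included)."""
        return self.N - self.n_cells - self.block_df

    def term_df(self, term: Term) -> int:
        if term == BLOCK:
            return self.block_df
        return int(np.prod([self.n_levels(f) - 1 for f in term]))

    def term_codes(self, term: Term) -> tuple[np.ndarray, int]:
        """Combined integer cell index for a term, and its cell count."""
        if term == BLOCK:
            return self.block_codes, self.n_blocks
        code = np.zeros(self.N, dtype=np.int64)
        ncell = 1
        for f in term:
            code = code * self.n_levels(f) + self.codes[f]
            ncell *= self.n_levels(f)
        return code, ncell

    def cell_codes(self) -> tuple[np.ndarray, int]:
        return self.term_codes(tuple(self.factor_names))

    def cell_frame(self) -> pd.DataFrame:
        """All treatment combinations (level labels), in product order."""
        combos = list(itertools.product(*[self.levels[f] for f in self.factor_names]))
        return pd.DataFrame(combos, columns=list(self.factor_names))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_codes(
        cls,
        factor_names: Sequence[str],
        levels: Mapping[str, Sequence[str]],
        codes: Mapping[str, np.ndarray],
        block: tuple[str, Sequence[str], np.ndarray] | None = None,
    ) -> "Design":
        factor_names = tuple(factor_names)
        if not 1 <= len(factor_names) <= 3:
            raise ValueError("designs with 1 to 3 treatment factors are supported")
        levels = {f: tuple(levels[f]) for f in factor_names}
        codes = {f: np.asarray(codes[f], dtype=np.int64) for f in factor_names}
        N = len(next(iter(codes.values())))
        for f in factor_names:
            if len(levels[f]) < 2:
                raise ValueError(f"factor {f!r} must have at least 2 levels")
            if len(codes[f]) != N:
                raise ValueError("factor code vectors differ in length")
        block_name = block_levels = block_codes = None
        if block is not None:
            block_name, blevels, bcodes = block
            block_levels = tuple(blevels)
            block_codes = np.asarray(bcodes, dtype=np.int64)
            if len(block_levels) < 2:
                raise ValueError("a block factor must have at least 2 levels")
            if len(block_codes) != N:
                raise ValueError("block code vector length mismatch")
        design = cls(
            factor_names=factor_names,
            levels=levels,
            codes=codes,
            replication=0,  # patched below after balance check
            N=N,
            block_name=block_name,
            block_levels=block_levels,
            block_codes=block_codes,
        )
        rep = design._check_balance()
        object.__setattr__(design, "replication", rep)
        if design.residual_df <= 0:
            raise ValueError(
                "the saturated model leaves zero residual degrees of freedom; "
                "at least 2 replicates (or 2 blocks) per treatment cell are required"
            )
        return design

    def _check_balance(self) -> int:
        """Verify equal replication in every cell; return the replication."""
        code, ncell = self.cell_codes()
        counts = np.bincount(code, minlength=ncell)
        if counts.min() != counts.max() or counts.min() == 0:
            bad = self._describe_cells(counts)
            raise ValueError(f"design is not balanced; observations per cell:\n{bad}")
        if self.block_name:
            bcode = self.block_codes * ncell + code
            bcounts = np.bincount(bcode, minlength=ncell * self.n_blocks)
            if bcounts.min() != bcounts.max() or bcounts.min() == 0:
                raise ValueError(
                    "blocked design is not balanced: every block must contain "
                    "every treatment cell equally often"
                )
        return int(counts[0])

    def _describe_cells(self, counts: np.ndarray) -> str:
        frame = self.cell_frame()
        frame["count"] = counts
        short = frame[frame["count"] != counts.max()]
        return short.to_string(index=False)


def build_design(
    factor_spec: Sequence[tuple[str, int | Sequence[str]]] | Mapping[str, int | Sequence[str]],
    replication: int,
    block_spec: str | None = None,
) -> Design:
    """Construct a balanced factorial :class:`Design` in standard layout.

    Parameters
    ----------
    factor_spec : ordered (name, levels) pairs; levels may be a count or a
        sequence of labels. Up to three treatment factors.
    replication : observations per treatment cell. When ``block_spec`` names a
        blocking factor, the design is a randomized complete block design with
        one replicate per block (so the number of blocks equals the
        replication).
    """
    if isinstance(factor_spec, Mapping):
        factor_spec = list(factor_spec.items())
    names = [name for name, _ in factor_spec]
    levels: dict[str, tuple[str, ...]] = {}
    for name, lv in factor_spec:
        if isinstance(lv, int):
            levels[name] = tuple(str(i + 1) for i in range(lv))
        else:
            levels[name] = tuple(str(x) for x in lv)
    if replication < 2:
        raise ValueError("replication must be at least 2")
    counts = [len(levels[f]) for f in names]
    ncell = int(np.prod(counts))
    # cell-major layout, replicate index fastest
    grid = np.array(list(itertools.product(*[range(t) for t in counts])), dtype=np.int64)
    grid = np.repeat(grid, replication, axis=0)
    codes = {f: grid[:, i].copy() for i, f in enumerate(names)}
    block = None
    if block_spec:
        bcodes = np.tile(np.arange(replication, dtype=np.int64), ncell)
        blabels = tuple(str(i + 1) for i in range(replication))
        block = (block_spec, blabels, bcodes)
    return Design.from_codes(names, levels, codes, block=block)


def enumerate_terms(design: Design, include_block: bool = True) -> list[Term]:
    """All model terms in canonical order: block, mains, 2-way, 3-way."""
    terms: list[Term] = []
    if include_block and design.block_name:
        terms.append(BLOCK)
    for order in range(1, len(design.factor_names) + 1):
        for combo in itertools.combinations(design.factor_names, order):
            terms.append(combo)
    return terms


def treatment_terms(design: Design) -> list[Term]:
    return enumerate_terms(design, include_block=False)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


def _proper_subsets(term: Term) -> list[Term]:
    out: list[Term] = []
    for r in range(1, len(term)):
        out.extend(itertools.combinations(term, r))
    return out


def marginality_closure(terms: Iterable[Term]) -> frozenset[Term]:
    """Smallest superset closed under marginality.

    Every lower-order term contained in an included interaction is added, so
    that (for example) a model retaining A:B also contains both A and B.
    """
    closed: set[Term] = set()
    for t in terms:
        closed.add(tuple(t))
        closed.update(_proper_subsets(tuple(t)))
    return frozenset(closed)


@dataclass(frozen=True)
class ModelSpec:
    """A predictive model: a set of treatment terms (blocks are implicit).

    The blocking factor, when present in the design, is always part of the
    fitted model — blocks are design structure, not hypotheses.
    """

    terms: frozenset[Term] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "terms", frozenset(tuple(t) for t in self.terms))

    @property
    def is_null(self) -> bool:
        return not self.terms

    def is_closed(self) -> bool:
        return self.terms == marginality_closure(self.terms)

    def closure(self) -> "ModelSpec":
        return ModelSpec(marginality_closure(self.terms))

    def is_saturated(self, design: Design) -> bool:
        return self.terms == frozenset(treatment_terms(design))

    def label(self) -> str:
        if not self.terms:
            return "null"
        ordered = sorted(self.terms, key=lambda t: (len(t), t))
        return "+".join(term_label(t) for t in ordered)

    @classmethod
    def saturated(cls, design: Design) -> "ModelSpec":
        return cls(frozenset(treatment_terms(design)))

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        if label in ("null", ""):
            return cls()
        return cls(frozenset(term_from_label(x) for x in label.split("+")))


def _validate_model(design: Design, model: ModelSpec, require_closed: bool = True) -> None:
    valid = set(treatment_terms(design))
    extra = set(model.terms) - valid
    if extra:
        raise ValueError(f"model contains terms not in the design: {sorted(extra)}")
    if require_closed and not model.is_closed():
        raise ValueError(
            "model violates marginality: every lower-order term contained in an "
            "included interaction must itself be included"
        )


# ---------------------------------------------------------------------------
# Orthogonal decomposition
# ---------------------------------------------------------------------------


@dataclass
class Decomposition:
    """Per-term sums of squares for one or many responses on one design.

    ``ss[term]`` is an array of length R (number of responses). Residual SS is
    total corrected SS minus all term (and block) SS, which for balanced
    orthogonal designs equals the least-squares residual.
    """

    design: Design
    terms: tuple[Term, ...]
    df: dict[Term, int]
    ss: dict[Term, np.ndarray]
    block_ss: np.ndarray | None
    block_df: int
    ss_res: np.ndarray
    df_res: int
    ss_total: np.ndarray
    grand: np.ndarray
    effects: dict[Term, np.ndarray] | None = None

    @property
    def n_responses(self) -> int:
        return len(self.grand)

    def ss_matrix(self) -> np.ndarray:
        """Treatment SS stacked as an (R, n_terms) array (term order = self.terms)."""
        return np.column_stack([self.ss[t] for t in self.terms])

    def df_vector(self) -> np.ndarray:
        return np.array([self.df[t] for t in self.terms], dtype=float)


def _group_mean_obs(code: np.ndarray, ncell: int, Y: np.ndarray) -> np.ndarray:
    sums = np.zeros((ncell, Y.shape[1]))
    np.add.at(sums, code, Y)
    counts = np.bincount(code, minlength=ncell).astype(float)
    means = sums / counts[:, None]
    return means[code]


def decompose(Y: np.ndarray | pd.DataFrame, design: Design, keep_effects: bool = False) -> Decomposition:
    """Orthogonal ANOVA decomposition of each column of ``Y``.

    Term effects are built recursively from marginal means: the effect of a
    term is its marginal mean minus the grand mean and all lower-order effects
    contained in it; the term SS is the sum of squared effects over
    observations. Balance makes the decomposition exact and order-free.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.N:
        raise ValueError(f"response length {Y.shape[0]} != design size {design.N}")
    if not np.isfinite(Y).all():
        raise ValueError("responses must be finite (drop or impute before analysis)")

    grand = Y.mean(axis=0)
    eff: dict[Term, np.ndarray] = {(): np.broadcast_to(grand, Y.shape)}
    ss: dict[Term, np.ndarray] = {}

    block_ss = None
    if design.block_name:
        code, ncell = design.term_codes(BLOCK)
        e = _group_mean_obs(code, ncell, Y) - eff[()]
        block_ss = (e * e).sum(axis=0)
        # block effects are orthogonal to every treatment term in a balanced
        # RCB, so they never enter the treatment recursion

    terms = tuple(treatment_terms(design))
    df = {t: design.term_df(t) for t in terms}
    for term in terms:  # ordered by increasing interaction order
        code, ncell = design.term_codes(term)
        e = _group_mean_obs(code, ncell, Y) - eff[()]
        for sub in _proper_subsets(term):
            e = e - eff[sub]
        ss[term] = (e * e).sum(axis=0)
        eff[term] = e

    centred = Y - grand
    ss_total = (centred * centred).sum(axis=0)
    explained = sum(ss.values())
    if block_ss is not None:
        explained = explained + block_ss
    ss_res = np.maximum(ss_total - explained, 0.0)
    df_res = design.residual_df

    return Decomposition(
        design=design,
        terms=terms,
        df=df,
        ss=ss,
        block_ss=block_ss,
        block_df=design.block_df,
        ss_res=ss_res,
        df_res=df_res,
        ss_total=ss_total,
        grand=grand,
        effects={t: eff[t].copy() for t in terms} if keep_effects else None,
    )


# ---------------------------------------------------------------------------
# F tests
# ---------------------------------------------------------------------------


def f_tail(F, df1, df2):
    """Upper-tail probability of the F distribution (vectorised)."""
    F = np.asarray(F, dtype=float)
    df1 = np.asarray(df1, dtype=float)
    df2 = np.asarray(df2, dtype=float)
    if np.any(df1 < 1) or np.any(df2 < 1):
        raise ValueError("degrees of freedom must be >= 1")
    if np.any(F < 0):
        raise ValueError("a variance ratio cannot be negative")
    p = stats.f.sf(F, df1, df2)
    return float(p) if p.ndim == 0 else p


def f_test(ss, df, ss_den, df_den):
    """F statistic and p for term SS against a denominator SS (vectorised).

    Degenerate convention for mass analysis: a zero-variance comparison
    (both numerator and denominator SS are zero) yields F = NaN and p = 1; a
    non-zero numerator over a zero denominator yields F = inf and p = 0.
    """
    ss = np.asarray(ss, dtype=float)
    ss_den = np.asarray(ss_den, dtype=float)
    ms = ss / df
    ms_den = ss_den / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms / ms_den
    p = np.where(
        ms_den > _ZERO_TOL,
        stats.f.sf(np.where(ms_den > _ZERO_TOL, F, 0.0), df, df_den),
        np.where(ms > _ZERO_TOL, 0.0, 1.0),
    )
    F = np.where((ms_den <= _ZERO_TOL) & (ms <= _ZERO_TOL), np.nan, F)
    return F, p


# ---------------------------------------------------------------------------
# ANOVA tables
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """A classical ANOVA table: one row per term plus a residual row.

    ``table`` is indexed by row label with columns df, sum_sq, mean_sq, F, p.
    Treatment rows carry F = MS_term / MS_res and p from the upper F tail.
    """

    table: pd.DataFrame
    treatment_labels: tuple[str, ...]
    N: int

    @property
    def df_res(self) -> int:
        return int(self.table.loc[RESIDUAL_LABEL, "df"])

    @property
    def ss_res(self) -> float:
        return float(self.table.loc[RESIDUAL_LABEL, "sum_sq"])

    @property
    def ms_res(self) -> float:
        return float(self.table.loc[RESIDUAL_LABEL, "mean_sq"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()

    @classmethod
    def from_components(
        cls,
        rows: Mapping[str, tuple[int, float]],
        residual: tuple[int, float],
        block: tuple[int, float] | None = None,
        N: int | None = None,
    ) -> "AnovaTable":
        """Assemble a table from (df, SS) components, e.g. published values."""
        df_res, ss_res = residual
        records = []
        if block is not None:
            records.append((BLOCK_LABEL, block[0], block[1]))
        records.extend((label, d, s) for label, (d, s) in rows.items())
        labels = [r[0] for r in records]
        dfs = np.array([r[1] for r in records], dtype=float)
        sss = np.array([r[2] for r in records], dtype=float)
        F, p = f_test(sss, dfs, ss_res, df_res)
        frame = pd.DataFrame(
            {"df": dfs.astype(int), "sum_sq": sss, "mean_sq": sss / dfs, "F": F, "p": p},
            index=labels,
        )
        if block is not None:
            frame.loc[BLOCK_LABEL, ["F", "p"]] = np.nan
        ms_res = ss_res / df_res if df_res > 0 else np.nan
        frame.loc[RESIDUAL_LABEL] = [df_res, ss_res, ms_res, np.nan, np.nan]
        frame["df"] = frame["df"].astype(int)
        if N is None:
            N = int(dfs.sum()) + df_res + 1
        treatment = tuple(label for label in labels if label != BLOCK_LABEL)
        return cls(table=frame, treatment_labels=treatment, N=N)


def fit_anova(y: np.ndarray | pd.Series, design: Design) -> AnovaTable:
    """Structured ANOVA of a single response on a balanced design."""
    dec = decompose(np.asarray(y, dtype=float), design)
    rows = {term_label(t): (dec.df[t], float(dec.ss[t][0])) for t in dec.terms}
    block = (dec.block_df, float(dec.block_ss[0])) if dec.block_ss is not None else None
    return AnovaTable.from_components(rows, residual=(dec.df_res, float(dec.ss_res[0])), block=block, N=design.N)


# ---------------------------------------------------------------------------
# One-way collapses
# ---------------------------------------------------------------------------


@dataclass
class OnewayTest:
    """An overall (one-way) F test of a treatment model.

    ``convention`` records how the degrees of freedom of a reduced model were
    counted; ``lack_of_fit`` optionally carries a separate lack-of-fit row as
    (df, SS, F, p).
    """

    F: float
    df1: int
    df2: int
    p: float
    model: ModelSpec | None = None
    convention: str = "standard"
    lack_of_fit: tuple[int, float, float, float] | None = None


def _oneway_from_parts(
    design: Design,
    retained_ss: float,
    retained_df: int,
    dropped_ss: float,
    ss_res: float,
    model: ModelSpec,
    convention: str,
) -> OnewayTest:
    if retained_df == 0:
        return OnewayTest(F=np.nan, df1=0, df2=design.N - 1 - design.block_df, p=1.0, model=model, convention=convention)
    if convention == "standard":
        df1 = retained_df
        df2 = design.N - 1 - design.block_df - df1
    elif convention == "as-printed":
        if any(len(t) > 1 for t in model.terms) and not model.is_saturated(design):
            raise ValueError("the as-printed df convention is defined for additive (or saturated) models only")
        if model.is_saturated(design):
            df1 = retained_df
            df2 = design.N - 1 - design.block_df - df1
        else:
            tsum = sum(design.n_levels(f) for (f,) in model.terms)
            df1 = tsum - 1
            df2 = design.N - tsum - design.block_df
    else:
        raise ValueError(f"unknown df convention {convention!r}")
    den_ss = ss_res + dropped_ss
    F, p = f_test(retained_ss, df1, den_ss, df2)
    return OnewayTest(F=float(F), df1=int(df1), df2=int(df2), p=float(p), model=model, convention=convention)


def collapse_oneway(
    y: np.ndarray | pd.Series,
    design: Design,
    model: ModelSpec,
    convention: str = "standard",
) -> OnewayTest:
    """Overall one-way F test of a (marginality-closed) treatment model.

    For the saturated model this is the classical one-way ANOVA over all
    treatment combinations. For a reduced model, the SS of the dropped terms
    are pooled into the denominator along with their degrees of freedom
    ("standard" convention: df1 is the sum of retained-term dfs). The
    "as-printed" convention counts an additive model on factors with t_1..t_m
    levels as (sum t_f - 1, N - sum t_f) degrees of freedom.
    """
    _validate_model(design, model)
    dec = decompose(np.asarray(y, dtype=float), design)
    retained_ss = float(sum(dec.ss[t][0] for t in model.terms))
    retained_df = int(sum(dec.df[t] for t in model.terms))
    total_treat = float(sum(dec.ss[t][0] for t in dec.terms))
    dropped_ss = total_treat - retained_ss
    return _oneway_from_parts(design, retained_ss, retained_df, dropped_ss, float(dec.ss_res[0]), model, convention)


def pool_from_table(table: AnovaTable) -> OnewayTest:
    """Pool the treatment rows of an ANOVA table into one overall F test."""
    if RESIDUAL_LABEL not in table.table.index:
        raise ValueError("ANOVA table has no residual row")
    if not table.treatment_labels:
        raise ValueError("ANOVA table has no treatment rows to pool")
    sub = table.table.loc[list(table.treatment_labels)]
    df1 = int(sub["df"].sum())
    ss1 = float(sub["sum_sq"].sum())
    F, p = f_test(ss1, df1, table.ss_res, table.df_res)
    return OnewayTest(F=float(F), df1=df1, df2=table.df_res, p=float(p))


def lack_of_fit_test(y: np.ndarray | pd.Series, design: Design, model: ModelSpec) -> OnewayTest:
    """One-way test of a reduced model that preserves the designed residual.

    The pooled treatment SS is partitioned into the model's one-way component
    and a lack-of-fit remainder; both are tested against the saturated-model
    residual mean square, so the residual degrees of freedom remain those the
    experiment was designed for.
    """
    _validate_model(design, model)
    if model.is_saturated(design):
        raise ValueError("model is saturated: there is no lack-of-fit term (use collapse_oneway)")
    dec = decompose(np.asarray(y, dtype=float), design)
    retained_ss = float(sum(dec.ss[t][0] for t in model.terms))
    retained_df = int(sum(dec.df[t] for t in model.terms))
    total_treat = float(sum(dec.ss[t][0] for t in dec.terms))
    total_df = int(sum(dec.df.values()))
    lof_ss = total_treat - retained_ss
    lof_df = total_df - retained_df
    ss_res = float(dec.ss_res[0])
    lof_F, lof_p = f_test(lof_ss, lof_df, ss_res, dec.df_res)
    if retained_df == 0:
        return OnewayTest(
            F=np.nan, df1=0, df2=dec.df_res, p=1.0, model=model, convention="lack-of-fit",
            lack_of_fit=(lof_df, lof_ss, float(lof_F), float(lof_p)),
        )
    F, p = f_test(retained_ss, retained_df, ss_res, dec.df_res)
    return OnewayTest(
        F=float(F), df1=retained_df, df2=dec.df_res, p=float(p), model=model,
        convention="lack-of-fit", lack_of_fit=(lof_df, lof_ss, float(lof_F), float(lof_p)),
    )


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSet:
    """Named orthogonal contrast components on the levels of one factor.

    Each component is a (d, t) coefficient matrix over the factor's t levels:
    d single-degree-of-freedom contrast vectors. All rows, across components,
    must sum to zero and be mutually orthogonal; rows are normalised to unit
    length internally so that integer patterns such as (-1, 0, 1) are accepted.
    """

    factor: str
    components: tuple[tuple[str, np.ndarray], ...]

    @classmethod
    def build(cls, factor: str, components: Mapping[str, Sequence[Sequence[float]] | Sequence[float]]) -> "ContrastSet":
        normed: list[tuple[str, np.ndarray]] = []
        for name, coef in components.items():
            mat = np.atleast_2d(np.asarray(coef, dtype=float))
            if np.any(np.abs(mat.sum(axis=1)) > 1e-8 * max(1.0, np.abs(mat).max())):
                raise ValueError(f"contrast {name!r} on factor {factor!r}: coefficients must sum to 0")
            norms = np.linalg.norm(mat, axis=1)
            if np.any(norms == 0):
                raise ValueError(f"contrast {name!r} on factor {factor!r} has a zero row")
            normed.append((str(name), mat / norms[:, None]))
        allrows = np.vstack([m for _, m in normed])
        gram = allrows @ allrows.T
        if not np.allclose(gram, np.eye(len(allrows)), atol=1e-8):
            raise ValueError(f"contrast components on factor {factor!r} are not mutually orthogonal")
        t = allrows.shape[1]
        if len(allrows) > t - 1:
            raise ValueError(f"factor {factor!r}: contrast dfs exceed {t - 1}")
        return cls(factor=factor, components=tuple(normed))

    @property
    def total_df(self) -> int:
        return int(sum(m.shape[0] for _, m in self.components))


def contrast_anova(
    y: np.ndarray | pd.Series,
    design: Design,
    contrasts: Mapping[str, ContrastSet],
) -> AnovaTable:
    """Structured ANOVA with main-effect terms split into contrast components.

    For each factor with a supplied :class:`ContrastSet`, the factor's SS is
    decomposed into one row per component (each tested against the saturated
    residual mean square); a 'deviations' remainder row is added when the
    components do not exhaust the factor's degrees of freedom. Other terms are
    reported as usual.
    """
    dec = decompose(np.asarray(y, dtype=float), design)
    n_marg = {f: design.N / design.n_levels(f) for f in design.factor_names}
    y0 = np.asarray(y, dtype=float)

    rows: dict[str, tuple[int, float]] = {}
    for term in dec.terms:
        label = term_label(term)
        if len(term) == 1 and term[0] in contrasts:
            f = term[0]
            cs = contrasts[f]
            if cs.factor != f:
                raise ValueError(f"contrast set for factor {cs.factor!r} supplied under key {f!r}")
            code = design.codes[f]
            t = design.n_levels(f)
            sums = np.bincount(code, weights=y0, minlength=t)
            m = sums / (design.N / t)
            used = 0.0
            for name, mat in cs.components:
                comp_ss = float(sum(n_marg[f] * (row @ m) ** 2 for row in mat))
                rows[f"{f}:{name}"] = (mat.shape[0], comp_ss)
                used += comp_ss
            rem_df = (t - 1) - cs.total_df
            if rem_df > 0:
                rows[f"{f}:deviations"] = (rem_df, max(float(dec.ss[term][0]) - used, 0.0))
        else:
            rows[label] = (dec.df[term], float(dec.ss[term][0]))
    block = (dec.block_df, float(dec.block_ss[0])) if dec.block_ss is not None else None
    return AnovaTable.from_components(rows, residual=(dec.df_res, float(dec.ss_res[0])), block=block, N=design.N)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


def predict_cells(y: np.ndarray | pd.Series, design: Design, model: ModelSpec) -> pd.DataFrame:
    """Least-squares predicted means per treatment combination (log scale).

    Returns the design's cell frame with a ``prediction`` column. The
    saturated model reproduces observed cell means; the null model predicts
    the grand mean everywhere; block effects are averaged out.
    """
    _validate_model(design, model)
    dec = decompose(np.asarray(y, dtype=float), design, keep_effects=True)
    fitted = np.full(design.N, dec.grand[0])
    for t in model.terms:
        fitted = fitted + dec.effects[t][:, 0]
    code, ncell = design.cell_codes()
    sums = np.bincount(code, weights=fitted, minlength=ncell)
    counts = np.bincount(code, minlength=ncell)
    frame = design.cell_frame()
    frame["prediction"] = sums / counts
    return frame
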