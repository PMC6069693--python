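"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from massanova import build_design
from massanova.design import Design, Term, treatment_terms, BLOCK


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)

@pytest.fixture
def design_4x3():
    """The lipidomics layout: 4 genotypes x 3 salt levels, 4 replicates."""
    return build_design(
        [("Genotype", ["Col", "Sha", "Ta", "Eut"]), ("Salt", ["0", "100", "200"])],
        replication=4,
    )

@pytest.fixture
def design_4x3_rep3():
    return build_design([("Genotype", 4), ("Salt", 3)], replication=3)

@pytest.fixture
def design_2x2():
    return build_design([("A", 2), ("B", 2)], replication=3)

@pytest.fixture
def design_3f():
    return build_design([("A", 2), ("B", 3), ("C", 2)], replication=2)

@pytest.fixture
def design_blocked():
    return build_design([("A", 3), ("B", 2)], replication=3, block_spec="block")


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the package's decomposition code paths)
# ---------------------------------------------------------------------------


def dummy_columns(design: Design, term: Term) -> np.ndarray:
    """0/1 indicator columns for every level combination of a term."""
    if term == BLOCK:
        code = design.block_codes
        ncell = design.n_blocks
    else:
        code = np.zeros(design.N, dtype=int)
        ncell = 1
        for f in term:
            code = code * design.n_levels(f) + design.codes[f]
            ncell *= design.n_levels(f)
    X = np.zeros((design.N, ncell))
    X[np.arange(design.N), code] = 1.0
    return X


def contrast_columns(design: Design, term: Term) -> np.ndarray:
    """Columns spanning exactly one term's effect space (Helmert products)."""
    from scipy.linalg import helmert

    if term == BLOCK:
        H = helmert(design.n_blocks, full=False)
        return H.T[design.block_codes]
    cols = np.ones((design.N, 1))
    for f in term:
        H = helmert(design.n_levels(f), full=False)  # (t-1, t), rows orthonormal
        fac = H.T[design.codes[f]]  # (N, t-1)
        cols = np.einsum("ni,nj->nij", cols, fac).reshape(design.N, -1)
    return cols


def ls_sequential_ss(y: np.ndarray, design: Design, order: list[Term]) -> dict[Term, float]:
    """Sequential least-squares projection SS for each term, in a given order.

    Fits nested models by dense lstsq: the SS of a term is the drop in
    residual sum of squares when its contrast-column block enters the model
    after everything before it. For balanced designs any order gives the same
    SS (orthogonality).
    """
    blocks = [np.ones((design.N, 1))]
    if design.block_name:
        blocks.append(contrast_columns(design, BLOCK))
    out: dict[Term, float] = {}
    prev_rss = _rss(y, np.hstack(blocks))
    if design.block_name:
        base_rss = _rss(y, blocks[0])
        out[BLOCK] = base_rss - prev_rss
    for term in order:
        blocks.append(contrast_columns(design, term))
        rss = _rss(y, np.hstack(blocks))
        out[term] = prev_rss - rss
        prev_rss = rss
    out["__residual__"] = prev_rss
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def bh_stepup_by_hand(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, written out longhand."""
    p = np.asarray(p, dtype=float)
    R = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * R / np.arange(1, R + 1)
    for i in range(R - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(R)
    out[order] = q
    return out


def closed_subsets_by_hand(n_factors: int) -> int:
    """Brute-force count of marginality-closed treatment-term subsets."""
    factors = list(range(n_factors))
    terms = []
    for r in range(1, n_factors + 1):
        terms.extend(itertools.combinations(factors, r))
    count = 0
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            sel = set(combo)
            ok = all(
                all(sub in sel for k in range(1, len(t)) for sub in itertools.combinations(t, k))
                for t in sel
            )
            count += ok
    return count


def residual_noise(design: Design, rng: np.random.Generator) -> np.ndarray:
    """A noise vector lying entirely in the residual space of the design.

    Constructed by projecting random noise off the span of the grand mean,
    block and all treatment indicator spaces via dense least squares.
    """
    e = rng.standard_normal(design.N)
    blocks = [np.ones((design.N, 1))]
    if design.block_name:
        blocks.append(dummy_columns(design, BLOCK))
    blocks.append(dummy_columns(design, tuple(design.factor_names)))
    X = np.hstack(blocks)
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    return e - X @ beta


def effect_pattern(design: Design, term: Term, rng: np.random.Generator) -> np.ndarray:
    """A unit-SS observation-level pattern lying purely in one term's space."""
    code = np.zeros(design.N, dtype=int)
    ncell = 1
    for f in term:
        code = code * design.n_levels(f) + design.codes[f]
        ncell *= design.n_levels(f)
    raw = rng.standard_normal(ncell)
    v = raw[code].astype(float)
    # project off grand mean and all proper-subset term spaces
    blocks = [np.ones((design.N, 1))]
    for r in range(1, len(term)):
        for sub in itertools.combinations(term, r):
            blocks.append(dummy_columns(design, sub))
    X = np.hstack(blocks)
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    v = v - X @ beta
    return v / np.sqrt(float(v @ v))
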