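"""Simulation engine: known-truth response matrices and framework error rates.

The generator emulates replicated factorial experiments analysed on the log
scale: each response draws a true predictive model (null with a configurable
probability, otherwise uniformly over the marginality-closed non-null models),
effect coefficients in an orthonormal contrast basis of each true term's
effect space with magnitudes uniform on a stated range of sigma units, and
independent Gaussian noise. Randomized-complete-block scenarios add per-block
effects and, optionally, a block-diagonal correlation structure between
responses.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert

from .design import Design, ModelSpec, Term, build_design, treatment_terms
from .frameworks import FrameworkResult, run_mrf, run_rfm, run_rmf
from .selection import candidate_models

#: factor layouts of the built-in study designs
DESIGNS: dict[str, tuple[tuple[str, int], ...]] = {
    "2x2": (("A", 2), ("B", 2)),
    "3x2x4": (("A", 3), ("B", 2), ("C", 4)),
    "3x2x4_rcb": (("A", 3), ("B", 2), ("C", 4)),
}

_RUNNERS = {"rfm": run_rfm, "mrf": run_mrf, "rmf": run_rmf}


@dataclass(frozen=True)
class SimScenario:
    """One simulation condition: a design, a truth model and noise structure.

    Defaults are the desk-scale study conditions: half the responses are null,
    non-null effect coefficients have magnitudes uniform on [1, 3] sigma,
    unit error variance, independent responses. ``rho`` > 0 (used with the
    blocked design) imposes a common correlation within contiguous blocks of
    ``corr_block_size`` responses.
    """

    design_id: str = "2x2"
    n_responses: int = 500
    replication: int = 3
    correction: str = "bh"
    alpha: float = 0.05
    seed: int = 0
    null_prob: float = 0.5
    effect_range: tuple[float, float] = (1.0, 3.0)
    sigma2: float = 1.0
    rho: float = 0.0
    corr_block_size: int = 10
    block_sigma2: float = 1.0
    model_probs: tuple[tuple[str, float], ...] | None = None
    sim_index: int = 0

    def __post_init__(self):
        if self.design_id not in DESIGNS:
            raise ValueError(f"unknown design {self.design_id!r}; choose from {sorted(DESIGNS)}")
        if not 0 <= self.null_prob <= 1:
            raise ValueError("null_prob must be in [0, 1]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def blocked(self) -> bool:
        return self.design_id.endswith("_rcb")

    def build_design(self) -> Design:
        block = "block" if self.blocked else None
        return build_design(list(DESIGNS[self.design_id]), self.replication, block_spec=block)


@dataclass
class SimDataset:
    """A simulated response matrix with its generating truth."""

    Y: pd.DataFrame
    design: Design
    truth: list[frozenset[Term]]
    means: np.ndarray  # observation-level true means (N, R)
    scenario: SimScenario


def _term_basis(design: Design, term: Term) -> np.ndarray:
    """Orthonormal basis of a term's effect space over the cell grid.

    Rows are unit vectors of length n_cells: tensor products of Helmert
    contrast rows for the factors in the term and uniform vectors elsewhere.
    """
    parts = []
    for f in design.factor_names:
        t = design.n_levels(f)
        if f in term:
            parts.append(helmert(t, full=False))
        else:
            parts.append(np.full((1, t), 1.0 / np.sqrt(t)))
    basis = parts[0]
    for p in parts[1:]:
        basis = np.einsum("ia,jb->ijab", basis, p).reshape(basis.shape[0] * p.shape[0], -1)
    return basis


def _truth_distribution(scenario: SimScenario, design: Design) -> tuple[list[frozenset[Term]], np.ndarray]:
    if scenario.model_probs is not None:
        models = [ModelSpec.from_label(lbl).terms for lbl, _ in scenario.model_probs]
        probs = np.array([pr for _, pr in scenario.model_probs], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("model probabilities must sum to 1")
        return models, probs
    nonnull = [m.terms for m in candidate_models(design) if m.terms]
    models = [frozenset()] + nonnull
    probs = np.concatenate([
        [scenario.null_prob],
        np.full(len(nonnull), (1.0 - scenario.null_prob) / len(nonnull)),
    ])
    return models, probs


def generate_dataset(scenario: SimScenario) -> SimDataset:
    """Draw one dataset, reproducibly from ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    design = scenario.build_design()
    R = scenario.n_responses
    sigma = float(np.sqrt(scenario.sigma2))
    lo, hi = scenario.effect_range

    models, probs = _truth_distribution(scenario, design)
    truth_idx = rng.choice(len(models), size=R, p=probs)
    truth = [models[i] for i in truth_idx]

    bases = {t: _term_basis(design, t) for t in treatment_terms(design)}
    cell_code, ncell = design.cell_codes()
    mean_cells = np.zeros((ncell, R))
    for r, terms in enumerate(truth):
        for t in sorted(terms, key=lambda t: (len(t), t)):
            basis = bases[t]
            coef = rng.uniform(lo, hi, size=basis.shape[0]) * rng.choice([-1.0, 1.0], size=basis.shape[0]) * sigma
            mean_cells[:, r] += coef @ basis
    means = mean_cells[cell_code]

    noise = rng.standard_normal((design.N, R))
    if scenario.rho > 0:
        b = scenario.corr_block_size
        n_groups = int(np.ceil(R / b))
        shared = rng.standard_normal((design.N, n_groups))
        group = np.arange(R) // b
        noise = np.sqrt(scenario.rho) * shared[:, group] + np.sqrt(1.0 - scenario.rho) * noise
    Y = means + sigma * noise

    if design.block_name:
        block_eff = rng.normal(0.0, np.sqrt(scenario.block_sigma2), size=(design.n_blocks, R))
        Y = Y + block_eff[design.block_codes]

    frame = pd.DataFrame(Y, columns=[f"resp{r + 1}" for r in range(R)])
    return SimDataset(Y=frame, design=design, truth=truth, means=means, scenario=scenario)


def scenario_grid(
    designs: Sequence[str] = ("2x2", "3x2x4", "3x2x4_rcb"),
    n_responses: Sequence[int] = (500, 1000, 20000),
    replications: Sequence[int] = (3, 4, 5),
    n_sims: int = 50,
    correction: str = "bh",
    base_seed: int = 0,
    **overrides,
) -> list[SimScenario]:
    """Full factorial grid of scenarios: designs x R x replicates x simulations.

    The study grid (3 designs, R in {500, 1000, 20000}, 3-5 replicates, 50
    simulations each) enumerates 1350 datasets. Per-scenario seeds are drawn
    once from ``base_seed``.
    """
    combos = list(itertools.product(designs, n_responses, replications, range(n_sims)))
    seed_rng = np.random.default_rng(base_seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=len(combos))
    out = []
    for (d, R, rep, k), seed in zip(combos, seeds):
        rho = overrides.get("rho", 0.7 if d.endswith("_rcb") else 0.0)
        kw = {k2: v for k2, v in overrides.items() if k2 != "rho"}
        out.append(
            SimScenario(design_id=d, n_responses=int(R), replication=int(rep),
                        correction=correction, seed=int(seed), rho=rho, sim_index=k, **kw)
        )
    return out


@dataclass
class ErrorMetrics:
    """Error rates of one framework run against the generating truth.

    fp_pct / fn_pct are percentages of all R responses (falsely declared
    non-constant / falsely declared constant); fdp is the false discovery
    proportion among survivors. The model-fit percentages are over surviving
    responses: correct (= truth), overfit (strict superset), underfit (strict
    subset), misspecified (neither); they are NaN when nothing survives.
    """

    fp_pct: float
    fn_pct: float
    fdp: float
    correct_pct: float
    overfit_pct: float
    underfit_pct: float
    misspec_pct: float
    n_responses: int
    n_discoveries: int

    def as_dict(self) -> dict:
        return asdict(self)


def compute_error_metrics(result: FrameworkResult, truth: Sequence[frozenset]) -> ErrorMetrics:
    ids = list(result.table.index)
    if len(truth) != len(ids):
        raise ValueError("truth length does not match the number of responses")
    passed = result.table["passed"].to_numpy()
    is_null = np.array([len(t) == 0 for t in truth])
    fp = passed & is_null
    fn = (~passed) & (~is_null)
    R = len(ids)
    n_disc = int(passed.sum())
    fdp = float(fp.sum()) / max(1, n_disc)

    cats = {"correct": 0, "overfit": 0, "underfit": 0, "misspec": 0}
    for r, rid in enumerate(ids):
        if not passed[r]:
            continue
        model = result.models[rid]
        fitted = frozenset(model.terms) if model is not None else frozenset()
        true = frozenset(truth[r])
        if fitted == true:
            cats["correct"] += 1
        elif fitted > true:
            cats["overfit"] += 1
        elif fitted < true:
            cats["underfit"] += 1
        else:
            cats["misspec"] += 1
    denom = n_disc if n_disc else np.nan
    return ErrorMetrics(
        fp_pct=100.0 * fp.sum() / R,
        fn_pct=100.0 * fn.sum() / R,
        fdp=fdp,
        correct_pct=100.0 * cats["correct"] / denom if n_disc else float("nan"),
        overfit_pct=100.0 * cats["overfit"] / denom if n_disc else float("nan"),
        underfit_pct=100.0 * cats["underfit"] / denom if n_disc else float("nan"),
        misspec_pct=100.0 * cats["misspec"] / denom if n_disc else float("nan"),
        n_responses=R,
        n_discoveries=n_disc,
    )


def evaluate_scenario(
    scenario: SimScenario,
    frameworks: Sequence[str] = ("rfm", "mrf"),
) -> list[dict]:
    """Generate one dataset and score the requested frameworks on it."""
    ds = generate_dataset(scenario)
    rows = []
    for fw in frameworks:
        runner = _RUNNERS[fw]
        result = runner(ds.Y, ds.design, correction=scenario.correction, alpha=scenario.alpha)
        metrics = compute_error_metrics(result, ds.truth)
        row = {
            "framework": fw,
            "design": scenario.design_id,
            "n_responses": scenario.n_responses,
            "replication": scenario.replication,
            "correction": scenario.correction,
            "sim_index": scenario.sim_index,
            "seed": scenario.seed,
        }
        row.update(metrics.as_dict())
        rows.append(row)
    return rows


def run_grid(scenarios: Sequence[SimScenario], frameworks: Sequence[str] = ("rfm", "mrf")) -> pd.DataFrame:
    """Long-format metrics table: one row per scenario x simulation x framework."""
    rows: list[dict] = []
    for sc in scenarios:
        rows.extend(evaluate_scenario(sc, frameworks))
    return pd.DataFrame(rows)


_METRIC_COLS = ["fp_pct", "fn_pct", "fdp", "correct_pct", "overfit_pct", "underfit_pct", "misspec_pct"]


def summarize_grid(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of each error metric per scenario and framework."""
    if metrics.empty:
        raise ValueError("no metric rows to summarise")
    keys = ["design", "n_responses", "replication", "correction", "framework"]
    keys = [k for k in keys if k in metrics.columns]
    records = []
    for group_keys, sub in metrics.groupby(keys, sort=True):
        rec = dict(zip(keys, group_keys if isinstance(group_keys, tuple) else (group_keys,)))
        rec["n_sims"] = len(sub)
        for col in _METRIC_COLS:
            if col not in sub.columns:
                continue
            vals = sub[col].to_numpy(dtype=float)
            rec[f"{col}_median"] = float(np.nanmedian(vals))
            rec[f"{col}_q1"] = float(np.nanpercentile(vals, 25))
            rec[f"{col}_q3"] = float(np.nanpercentile(vals, 75))
            rec[f"{col}_mean"] = float(np.nanmean(vals))
        records.append(rec)
    return pd.DataFrame(records)
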