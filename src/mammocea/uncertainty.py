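"""One-way deterministic sensitivity analysis (tornado), probabilistic
sensitivity analysis with Gamma/Beta sampling, and cost-effectiveness
acceptability curves over a willingness-to-pay grid.

PSA draws costs from Gamma distributions (coefficient of variation from
the bundle's uncertainty settings) and utilities from Beta distributions
(absolute SD), with shape parameters set by the method of moments.
Structural parameters — test characteristics, compliance, transition
probabilities — are held fixed, which means the cohort trace is
invariant across draws; :func:`run_psa` therefore computes each
strategy's trace once and repeats only the economic accumulation, using
common random parameters across strategies within a draw.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import accumulate, incremental
from .parameters import ParameterBundle, ParameterValidationError
from .pipeline import run_strategy
from .states import N_STAGES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter addressing
# ---------------------------------------------------------------------------


def get_param(bundle: ParameterBundle, path: str) -> float:
    """Read a scalar parameter by dotted path, e.g. ``costs.treatment_cost.1``."""
    obj: object = bundle
    for part in path.split("."):
        if isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            obj = getattr(obj, part)
    return float(obj)  # type: ignore[arg-type]


def with_param(bundle: ParameterBundle, path: str, value: float) -> ParameterBundle:
    """A deep copy of ``bundle`` with the parameter at ``path`` replaced."""
    out = copy.deepcopy(bundle)
    parts = path.split(".")
    obj: object = out
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        setattr(obj, last, value)
    return out


def is_probability_path(path: str) -> bool:
    """Paths whose values must stay in [0, 1] after perturbation."""
    return (
        path.endswith((".sensitivity", ".specificity"))
        or path.endswith("compliance")
        or path.startswith("utilities.")
        or path.endswith(("remission_fraction", "biopsy_fraction_of_recalls"))
        or path.startswith("natural_history.")
    )


def default_dsa_parameters(
    candidate: str = "companion", reference: str = "conventional"
) -> list[str]:
    """Parameters varied in the tornado: test characteristics and scan
    costs of both compared strategies, compliance, biopsy cost, stage-I
    treatment cost, and the recurrence and stage-I utilities."""
    out = []
    for name in (candidate, reference):
        out += [
            f"strategies.{name}.specificity",
            f"strategies.{name}.sensitivity",
            f"strategies.{name}.cost_per_scan",
        ]
    out += [
        "policy.compliance",
        "costs.biopsy_cost",
        "costs.treatment_cost.1",
        "utilities.recurrence",
        "utilities.by_stage.1",
    ]
    return out


# ---------------------------------------------------------------------------
# one-way DSA
# ---------------------------------------------------------------------------


@dataclass
class TornadoTable:
    """Per-parameter ICER range from one-way perturbation.

    ``table`` rows (one per listed parameter, sorted by descending
    range width): parameter, base/low/high parameter values, ICER at the
    low and high side, range width, and whether the base ICER lies
    inside the range (violations are reported, not hidden).
    """

    candidate: str
    reference: str
    perturbation: float
    base_icer: float
    table: pd.DataFrame


def _icer(bundle: ParameterBundle, candidate: str, reference: str) -> float:
    ref = run_strategy(bundle, reference)[1]
    cand = run_strategy(bundle, candidate)[1]
    cmp = incremental(ref, cand, bundle.economics.wtp_threshold)
    return cmp.icer if cmp.icer is not None else float("nan")


def one_way_dsa(
    bundle: ParameterBundle,
    parameters: list[str] | None = None,
    perturbation: float = 0.1,
    candidate: str = "companion",
    reference: str = "conventional",
) -> TornadoTable:
    """Tornado analysis: rerun the full pipeline at ``(1 - p)`` and
    ``(1 + p)`` times each listed parameter's base value (others at
    base) and record both ICERs of ``candidate`` vs ``reference``.

    Probabilities pushed outside [0, 1] are clipped, with a logged
    warning — never silently.
    """
    if parameters is None:
        parameters = default_dsa_parameters(candidate, reference)
    base_icer = _icer(bundle, candidate, reference)
    rows = []
    for path in parameters:
        base = get_param(bundle, path)
        sides = {}
        values = {}
        for label, mult in (("low", 1.0 - perturbation), ("high", 1.0 + perturbation)):
            v = base * mult
            if is_probability_path(path) and not 0.0 <= v <= 1.0:
                clipped = min(max(v, 0.0), 1.0)
                logger.warning(
                    "DSA: %s perturbed to %.6g outside [0, 1]; clipped to %.6g",
                    path,
                    v,
                    clipped,
                )
                v = clipped
            values[label] = v
            sides[label] = _icer(with_param(bundle, path, v), candidate, reference)
        lo, hi = sides["low"], sides["high"]
        width = abs(hi - lo)
        rows.append(
            {
                "parameter": path,
                "base_value": base,
                "low_value": values["low"],
                "high_value": values["high"],
                "icer_low": lo,
                "icer_high": hi,
                "width": width,
                "contains_base": bool(
                    min(lo, hi) - 1e-9 <= base_icer <= max(lo, hi) + 1e-9
                ),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("width", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    for _, row in table.iterrows():
        if not row["contains_base"]:
            logger.warning(
                "DSA: base ICER %.2f outside [%s] range for %s",
                base_icer,
                f"{row['icer_low']:.2f}, {row['icer_high']:.2f}",
                row["parameter"],
            )
    return TornadoTable(candidate, reference, perturbation, base_icer, table)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(alpha, beta) shape parameters by the method of moments."""
    if sd == 0.0:
        raise ValueError("beta_moments: sd must be > 0 (degenerate case handled upstream)")
    if sd * sd >= mean * (1.0 - mean):
        raise ParameterValidationError(
            f"beta_moments: sd {sd} incompatible with mean {mean} "
            "(requires sd^2 < mean x (1 - mean))"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) parameters by the method of moments."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError("gamma_moments: mean and sd must be > 0")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def _draw_cost(mean: float, cv: float, rng: np.random.Generator) -> float:
    if mean == 0.0 or cv == 0.0:  # degenerate point mass
        return mean
    shape, scale = gamma_moments(mean, cv * mean)
    return float(rng.gamma(shape, scale))


def _draw_utility(mean: float, sd: float, rng: np.random.Generator, label: str) -> float:
    if sd == 0.0:
        return mean
    try:
        a, b = beta_moments(mean, sd)
    except ParameterValidationError as err:
        raise ParameterValidationError(f"utility '{label}': {err}") from None
    return float(rng.beta(a, b))


#: cost parameters sampled in PSA, in fixed draw order
_COST_PATHS = tuple(
    [f"costs.treatment_cost.{s}" for s in range(N_STAGES)]
    + [
        "costs.recurrence_cost",
        "costs.ultrasound_cost",
        "costs.biopsy_cost",
        "strategies.conventional.cost_per_scan",
        "strategies.companion.cost_per_scan",
        "strategies.standalone.cost_per_scan",
    ]
)

#: utility parameters sampled in PSA, in fixed draw order
_UTILITY_PATHS = tuple(
    ["utilities.healthy", "utilities.undiagnosed"]
    + [f"utilities.by_stage.{s}" for s in range(N_STAGES)]
    + ["utilities.remission", "utilities.recurrence"]
)


def sample_psa_draw(
    bundle: ParameterBundle, rng: np.random.Generator
) -> ParameterBundle:
    """One PSA draw: every cost parameter resampled from a Gamma with
    mean equal to its base value and CV from the uncertainty settings;
    every utility from a Beta with its base mean and absolute SD.

    Structural parameters (sensitivity, specificity, compliance,
    transition probabilities, the remission and biopsy fractions) stay
    fixed.  The perturbed bundle is returned without re-validating the
    reference set's ordering invariants — sampled worlds may reorder.
    """
    cv = bundle.uncertainty.cost_cv
    sd = bundle.uncertainty.utility_sd
    out = copy.deepcopy(bundle)
    for path in _COST_PATHS:
        out = _set_inplace(out, path, _draw_cost(get_param(bundle, path), cv, rng))
    for path in _UTILITY_PATHS:
        out = _set_inplace(
            out, path, _draw_utility(get_param(bundle, path), sd, rng, path)
        )
    return out


def _set_inplace(bundle: ParameterBundle, path: str, value: float) -> ParameterBundle:
    # like with_param but mutating (bundle is already a private copy)
    parts = path.split(".")
    obj: object = bundle
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        setattr(obj, last, value)
    return bundle


# ---------------------------------------------------------------------------
# PSA / CEAC
# ---------------------------------------------------------------------------


def default_wtp_grid() -> np.ndarray:
    """0 to 100,000 SGD/QALY in 2,500-SGD steps."""
    return np.arange(0.0, 100_000.0 + 1.0, 2_500.0)


@dataclass
class CeacSurface:
    """Probability each strategy is cost-effective across a WTP grid."""

    scenario: str
    wtp_grid: np.ndarray
    probability: pd.DataFrame  # index: wtp, columns: strategies
    n_draws: int


@dataclass
class PsaResult:
    surfaces: list[CeacSurface]
    ledger: pd.DataFrame  # scenario, draw, strategy, cost, qalys
    seed: int
    n_draws: int
    rejected_draws: list[int] = field(default_factory=list)


def run_psa(
    bundle: ParameterBundle,
    n_draws: int,
    wtp_grid: np.ndarray | None = None,
    seed: int = 0,
    compliance_scenarios: tuple[float, ...] | None = None,
) -> PsaResult:
    """Monte Carlo PSA with common random parameters across strategies.

    For each draw the three strategies are evaluated on the same
    perturbed bundle; at each WTP the strategy maximising net monetary
    benefit is counted, giving acceptability probabilities that sum to
    one per WTP.  Fully reproducible from ``seed`` (one root seed,
    per-draw child streams).  Draws producing NaN are rejected and
    logged; more than 1% rejections aborts.
    """
    if n_draws < 1:
        raise ValueError("run_psa: n_draws must be >= 1")
    grid = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("run_psa: wtp_grid must be non-empty and strictly ascending")
    scenarios = (
        compliance_scenarios
        if compliance_scenarios is not None
        else (bundle.policy.compliance,)
    )
    names = list(bundle.strategies)

    traces = {
        c: {name: run_strategy(bundle, name, compliance=c)[0] for name in names}
        for c in scenarios
    }

    children = np.random.SeedSequence(seed).spawn(n_draws)
    costs = np.full((len(scenarios), n_draws, len(names)), np.nan)
    qalys = np.full_like(costs, np.nan)
    rejected: list[int] = []
    hcc = bundle.policy.half_cycle_correction
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        drawn = sample_psa_draw(bundle, rng)
        ok = True
        for ci, c in enumerate(scenarios):
            for si, name in enumerate(names):
                res = accumulate(
                    traces[c][name],
                    drawn.costs,
                    drawn.utilities,
                    drawn.economics,
                    drawn.strategies[name],
                    half_cycle_correction=hcc,
                )
                if not (np.isfinite(res.total_cost) and np.isfinite(res.total_qalys)):
                    ok = False
                costs[ci, i, si] = res.total_cost
                qalys[ci, i, si] = res.total_qalys
        if not ok:
            rejected.append(i)
            logger.warning("PSA: draw %d produced NaN and was rejected", i)
    if len(rejected) > 0.01 * n_draws:
        raise RuntimeError(
            f"PSA: {len(rejected)} of {n_draws} draws rejected (> 1%); aborting"
        )
    valid = np.setdiff1d(np.arange(n_draws), np.asarray(rejected, dtype=int))

    surfaces = []
    ledger_rows = []
    for ci, c in enumerate(scenarios):
        label = f"compliance={c:g}"
        # nmb: (wtp, draw, strategy)
        nmb = grid[:, None, None] * qalys[ci, valid][None] - costs[ci, valid][None]
        best = nmb.argmax(axis=2)
        prob = np.stack(
            [(best == si).mean(axis=1) for si in range(len(names))], axis=1
        )
        surfaces.append(
            CeacSurface(
                scenario=label,
                wtp_grid=grid,
                probability=pd.DataFrame(prob, index=grid, columns=names),
                n_draws=len(valid),
            )
        )
        for si, name in enumerate(names):
            ledger_rows.append(
                pd.DataFrame(
                    {
                        "scenario": label,
                        "draw": valid,
                        "strategy": name,
                        "cost": costs[ci, valid, si],
                        "qalys": qalys[ci, valid, si],
                    }
                )
            )
    ledger = pd.concat(ledger_rows, ignore_index=True)
    return PsaResult(surfaces, ledger, seed, n_draws, rejected)
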