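"""Deterministic and probabilistic sensitivity analysis.

One-way ("tornado") analysis reruns the full two-arm model with each
CI-carrying parameter pushed to its lower and upper 95% bound (discount rates
are swept over a conventional 0-6% range). Probabilistic sensitivity analysis
draws every uncertain parameter at once — beta for probabilities and
utilities, gamma for costs, fitted by method of moments with
SE = (CI_high - CI_low)/3.92 — runs both arms per draw, and summarizes the
incremental cost/QALY cloud as a cost-effectiveness acceptability curve.
Parameters without a CI are held fixed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import compare_strategies
from .engine import run_cohort
from .params import ModelParameters, ParamDistribution

logger = logging.getLogger(__name__)

DISCOUNT_SWEEP = (0.0, 0.06)  # conventional DSA range for the 3% base rates

DEFAULT_WTP_GRID = tuple(range(0, 400_001, 10_000))


@dataclass
class UncertainParam:
    id: str
    kind: str  # probability | utility | cost | rate
    mean: float
    low: float
    high: float
    distribution: ParamDistribution


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def range(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass
class PSAResult:
    n_draws: int
    seed: int
    ref_arm: str
    alt_arm: str
    #: per-draw parameter values, one column per uncertain parameter
    draws: pd.DataFrame
    #: per-draw incremental cost and incremental QALY (alt - ref)
    d_cost: np.ndarray
    d_qaly: np.ndarray

    def plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n_draws),
            "d_cost": self.d_cost,
            "d_qaly": self.d_qaly,
        })


@dataclass
class CEACPoint:
    wtp: float
    p_ref: float
    p_alt: float


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------


def resolve_distribution(
    kind: str, mean: float, low: float, high: float, family: Optional[str] = None
) -> ParamDistribution:
    """Choose a sampling family for a parameter from its kind and 95% CI.

    Probabilities and utilities get a beta, costs a gamma, both moment-matched
    to mean and SE = (high-low)/3.92; a zero-width CI degrades to fixed, and
    an infeasible moment fit (variance too large for the support) falls back
    to uniform over the CI with a logged warning.
    """
    if family is None:
        family = {"probability": "beta", "utility": "beta", "cost": "gamma",
                  "rate": "uniform"}[kind]
    se = (high - low) / 3.92
    if se == 0.0 or family == "fixed":
        return ParamDistribution(family="fixed", mean=mean, ci_low=low, ci_high=high)
    if family == "beta":
        var = se * se
        if not 0.0 < mean < 1.0 or var >= mean * (1.0 - mean):
            logger.warning(
                "beta moment fit infeasible for mean=%s se=%s; using uniform CI", mean, se
            )
            return ParamDistribution(family="uniform", mean=mean, ci_low=low, ci_high=high)
    if family == "gamma" and mean <= 0.0:
        return ParamDistribution(family="fixed", mean=mean, ci_low=low, ci_high=high)
    return ParamDistribution(family=family, mean=mean, ci_low=low, ci_high=high)


def _sample_one(dist: ParamDistribution, rng: np.random.Generator) -> float:
    if dist.family == "fixed":
        return dist.mean
    if dist.family == "uniform":
        return float(rng.uniform(dist.ci_low, dist.ci_high))
    se = (dist.ci_high - dist.ci_low) / 3.92
    var = se * se
    if dist.family == "beta":
        m = dist.mean
        k = m * (1.0 - m) / var - 1.0
        return float(rng.beta(m * k, (1.0 - m) * k))
    if dist.family == "gamma":
        shape = dist.mean**2 / var
        scale = var / dist.mean
        return float(rng.gamma(shape, scale))
    raise ValueError(f"unknown family {dist.family}")


def uncertain_parameters(
    params: ModelParameters, include_discount_rates: bool = False
) -> list[UncertainParam]:
    """Every parameter eligible for sensitivity analysis, sorted by id.

    Only parameters carrying a 95% CI participate; ``include_discount_rates``
    additionally sweeps both discount rates over 0-6% (one-way analysis only).
    """
    out = []
    for pid, kind, entry in params.iter_entries():
        if not entry.has_ci:
            continue
        mean = entry.p if hasattr(entry, "p") else entry.value
        family = params.distributions.get(pid)
        out.append(UncertainParam(
            id=pid, kind=kind, mean=mean, low=entry.ci_low, high=entry.ci_high,
            distribution=resolve_distribution(kind, mean, entry.ci_low, entry.ci_high, family),
        ))
    if include_discount_rates:
        for pid, mean in (("discount_costs", params.discount_rate_costs),
                          ("discount_outcomes", params.discount_rate_outcomes)):
            lo, hi = DISCOUNT_SWEEP
            out.append(UncertainParam(
                id=pid, kind="rate", mean=mean, low=lo, high=hi,
                distribution=ParamDistribution(family="fixed", mean=mean,
                                               ci_low=lo, ci_high=hi),
            ))
    out.sort(key=lambda u: u.id)
    return out


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------


def _icer(params: ModelParameters, scenario: str) -> float:
    ref = run_cohort(params, "CAPD", scenario)
    alt = run_cohort(params, "APD", scenario)
    res = compare_strategies(ref, alt, params.wtp)
    return np.nan if res.icer_per_qaly is None else res.icer_per_qaly


def one_way_sa(params: ModelParameters, scenario: str = "base") -> list[TornadoEntry]:
    """Tornado analysis: ICER (baht/QALY) at each parameter's CI bounds.

    All other parameters stay at base values; entries are sorted by ICER
    range, largest first, ties broken by parameter id.
    """
    swept = uncertain_parameters(params, include_discount_rates=True)
    if not swept:
        raise ValueError("no parameter carries a CI; nothing to sweep")
    entries = []
    for u in swept:
        lo = _icer(params.updated({u.id: u.low}), scenario)
        hi = _icer(params.updated({u.id: u.high}), scenario)
        entries.append(TornadoEntry(parameter=u.id, icer_at_low=lo, icer_at_high=hi))
    entries.sort(key=lambda e: (-(e.range if np.isfinite(e.range) else -np.inf), e.parameter))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter, "icer_at_low": e.icer_at_low,
         "icer_at_high": e.icer_at_high, "range": e.range}
        for e in entries
    ])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> dict[str, float]:
    """One joint draw of every uncertain parameter (independent draws)."""
    return {u.id: _sample_one(u.distribution, rng)
            for u in uncertain_parameters(params)}


def run_psa(
    params: ModelParameters,
    n_draws: int = 1000,
    seed: int = 0,
    scenario: str = "base",
) -> PSAResult:
    """Monte-Carlo PSA: sample all uncertain parameters, rerun both arms.

    Deterministic for a given seed. Each draw records the sampled values and
    the incremental (cost, QALY) pair of APD vs CAPD.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    names = [u.id for u in uncertain_parameters(params)]
    draw_rows = []
    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    for i in range(n_draws):
        values = sample_parameters(params, rng)
        p = params.updated(values) if values else params
        ref = run_cohort(p, "CAPD", scenario)
        alt = run_cohort(p, "APD", scenario)
        d_cost[i] = alt.total_cost - ref.total_cost
        d_qaly[i] = alt.total_qaly - ref.total_qaly
        draw_rows.append(values)
    draws = pd.DataFrame(draw_rows, columns=names)
    return PSAResult(n_draws=n_draws, seed=seed, ref_arm="CAPD", alt_arm="APD",
                     draws=draws, d_cost=d_cost, d_qaly=d_qaly)


def ceac(psa: PSAResult, wtp_grid: Sequence[float] | None = None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from a PSA cloud.

    At each WTP the alternative arm's probability is the fraction of draws in
    which its net monetary benefit strictly exceeds the reference's; exact
    ties are split equally. The two probabilities sum to 1 by construction.
    """
    if psa.n_draws == 0:
        raise ValueError("empty PSA result")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid
    points = []
    for wtp in grid:
        nmb_diff = wtp * psa.d_qaly - psa.d_cost
        p_alt = float(np.mean(nmb_diff > 0) + 0.5 * np.mean(nmb_diff == 0))
        points.append(CEACPoint(wtp=float(wtp), p_ref=1.0 - p_alt, p_alt=p_alt))
    return points


def ceac_frame(points: Sequence[CEACPoint], ref_arm: str = "CAPD", alt_arm: str = "APD") -> pd.DataFrame:
    return pd.DataFrame([
        {"wtp": p.wtp, f"p_{ref_arm}": p.p_ref, f"p_{alt_arm}": p.p_alt}
        for p in points
    ])
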