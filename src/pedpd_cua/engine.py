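"""Markov cohort engine.

Advances a cohort through the four per-arm health states (assigned PD
modality, HD, KT, DEAD) over a lifetime horizon with one-year cycles, and
accumulates discounted costs, life years and QALYs.

Internally the KT state is split into a first-year tunnel (``KT_NEW``) and a
maintenance state (``KT_EST``) so that the transplant-year cost can differ
from maintenance cost; the two collapse back to a single KT column in the
exported trace. Direct medical costs for the dialysis states use the year-1
figure in the first model year and the year-2+ figure afterwards (indexed by
time since model start); the KT year-1 figure follows time since state entry.

Death probabilities in the schedule are merged with age-specific background
mortality (independent competing risks by default) and the stay probability
is the residual of each row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MAX_SCHEDULE_YEAR, ModelParameters, combine_mortality

STATES4 = ("PD", "HD", "KT", "DEAD")
#: internal expansion: KT_NEW = first cycle after transplant, KT_EST = later
STATES5 = ("PD", "HD", "KT_NEW", "KT_EST", "DEAD")

ALIVE_EPS = 1e-6

SCENARIOS = ("base", "year1_forever")


class InfeasibleRowError(ValueError):
    """A transition row's residual stay-probability went negative."""


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortTrace:
    """State-occupancy fractions per cycle for one arm.

    Row ``t`` is the occupancy at the start of cycle ``t`` (cycle 0 = model
    entry, everyone in the PD state); the final row is the occupancy after the
    last simulated transition.
    """

    occupancy: np.ndarray  # shape (n_cycles+1, 4), columns in STATES4 order
    start_age: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, occ in enumerate(self.occupancy):
            for s, frac in zip(STATES4, occ):
                rows.append({"cycle": t, "age": self.start_age + t, "state": s,
                             "occupancy": frac})
        return pd.DataFrame(rows)


@dataclass
class ArmResult:
    """Discounted and undiscounted totals for one simulated arm."""

    arm: str
    scenario: str
    total_cost: float
    total_ly: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_ly: float
    undiscounted_qaly: float
    discount_rate_costs: float
    discount_rate_outcomes: float
    trace: CohortTrace = field(repr=False)

    def totals_dict(self) -> dict:
        return {
            "arm": self.arm,
            "scenario": self.scenario,
            "total_cost": self.total_cost,
            "total_ly": self.total_ly,
            "total_qaly": self.total_qaly,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_ly": self.undiscounted_ly,
            "undiscounted_qaly": self.undiscounted_qaly,
        }


def build_transition_matrix(
    params: ModelParameters, arm: str, model_year: int, age: int
) -> np.ndarray:
    """Row-stochastic 4x4 one-cycle matrix over (PD, HD, KT, DEAD).

    Schedule years beyond 10 reuse the year-10 row; HD->PD and KT->PD route
    back to the arm's own modality; each alive state's death probability is
    merged with background mortality for ``age``; stay is the residual.
    """
    if model_year < 1:
        raise ValueError("model_year starts at 1")
    y = min(model_year, MAX_SCHEDULE_YEAR)
    bg = params.background_mortality(age)
    mode = params.mortality_combination

    def row(frm: str, exits: dict[str, float]) -> np.ndarray:
        r = np.zeros(4)
        p_dead = combine_mortality(exits.pop("DEAD"), bg, mode)
        r[3] = p_dead
        for to, p in exits.items():
            r[STATES4.index(to)] = p
        stay = 1.0 - r.sum()
        if stay < -1e-9:
            raise InfeasibleRowError(
                f"exit probabilities from {frm} exceed 1 after adding background "
                f"mortality (arm={arm}, model_year={model_year}, age={age})"
            )
        r[STATES4.index(frm)] = max(stay, 0.0)
        return r

    t = params.transition
    m = np.zeros((4, 4))
    m[0] = row("PD", {"HD": t(arm, y, "PD", "HD").p,
                      "KT": t(arm, y, "PD", "KT").p,
                      "DEAD": t(arm, y, "PD", "DEAD").p})
    m[1] = row("HD", {"PD": t(arm, y, "HD", "PD").p,
                      "DEAD": t(arm, y, "HD", "DEAD").p})
    m[2] = row("KT", {"HD": t(arm, y, "KT", "HD").p,
                      "PD": t(arm, y, "KT", "PD").p,
                      "DEAD": t(arm, y, "KT", "DEAD").p})
    m[3, 3] = 1.0
    return m


def _expand5(m4: np.ndarray) -> np.ndarray:
    """Expand the 4-state matrix to the internal 5-state (KT tunnel) space."""
    m5 = np.zeros((5, 5))
    # PD and HD rows: transitions into KT land in the first-year tunnel
    for i in (0, 1):
        m5[i, 0] = m4[i, 0]
        m5[i, 1] = m4[i, 1]
        m5[i, 2] = m4[i, 2]
        m5[i, 4] = m4[i, 3]
    # both KT sub-states share the KT row; staying means established graft
    kt = np.array([m4[2, 0], m4[2, 1], 0.0, m4[2, 2], m4[2, 3]])
    m5[2] = kt
    m5[3] = kt
    m5[4, 4] = 1.0
    return m5


def cycle_matrix5(
    params: ModelParameters, arm: str, cycle: int, scenario: str = "base"
) -> np.ndarray:
    """Internal 5-state matrix applied at the end of cycle ``cycle`` (0-based)."""
    model_year = 1 if scenario == "year1_forever" else cycle + 1
    age = params.start_age + cycle
    return _expand5(build_transition_matrix(params, arm, model_year, age))


def cost_vector5(params: ModelParameters, arm: str, cycle: int) -> np.ndarray:
    """Annual cost accrued by a member of each internal state during ``cycle``."""
    first_year = cycle == 0
    pd_c = params.cost_set(arm, "PD")
    hd_c = params.cost_set(arm, "HD")
    kt_c = params.cost_set(arm, "KT")
    return np.array([
        (pd_c.dmc_year1 if first_year else pd_c.dmc_year2plus) + pd_c.dnmc,
        (hd_c.dmc_year1 if first_year else hd_c.dmc_year2plus) + hd_c.dnmc,
        kt_c.dmc_year1 + kt_c.dnmc,
        kt_c.dmc_year2plus + kt_c.dnmc,
        0.0,
    ])


def utility_vector5(params: ModelParameters, arm: str) -> np.ndarray:
    return np.array([
        params.utility(arm, "PD"),
        params.utility(arm, "HD"),
        params.utility(arm, "KT"),
        params.utility(arm, "KT"),
        0.0,
    ])


def run_cohort(
    params: ModelParameters, arm: str, scenario: str = "base"
) -> ArmResult:
    """Simulate one arm's cohort and return discounted totals.

    The cohort starts fully in the assigned PD modality at ``start_age``.
    Cycle ``t`` accrues cost and utility for the states occupied during that
    cycle, discounted by ``(1+r)^-t`` (first cycle undiscounted), then
    transitions through the cycle's matrix. The run stops at ``max_age``
    (default 100) or when the alive fraction falls below 1e-6. With
    ``half_cycle_correction`` enabled in the parameters, accruals use the
    trapezoid of start- and end-of-cycle occupancy.
    """
    if arm not in params.arms:
        raise ConfigurationError(f"unknown arm {arm!r}")
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")

    rc = params.discount_rate_costs
    ro = params.discount_rate_outcomes
    vc = 1.0 / (1.0 + rc)
    vo = 1.0 / (1.0 + ro)
    util = utility_vector5(params, arm)

    occ = np.zeros(5)
    occ[0] = 1.0
    max_cycles = params.max_age - params.start_age + 1

    trace_rows = []
    cost_d = ly_d = qaly_d = 0.0
    cost_u = ly_u = qaly_u = 0.0
    dfc = dfo = 1.0

    for t in range(max_cycles):
        alive = occ[:4].sum()
        if alive < ALIVE_EPS:
            break
        trace_rows.append(_collapse4(occ))
        m5 = cycle_matrix5(params, arm, t, scenario)
        nxt = occ @ m5
        if params.half_cycle_correction:
            w = 0.5 * (occ + nxt)
        else:
            w = occ
        costs = cost_vector5(params, arm, t)
        c = float(w @ costs)
        ly = float(w[:4].sum())
        q = float(w @ util)
        cost_d += dfc * c
        ly_d += dfo * ly
        qaly_d += dfo * q
        cost_u += c
        ly_u += ly
        qaly_u += q
        occ = nxt
        dfc *= vc
        dfo *= vo
    trace_rows.append(_collapse4(occ))

    return ArmResult(
        arm=arm,
        scenario=scenario,
        total_cost=cost_d,
        total_ly=ly_d,
        total_qaly=qaly_d,
        undiscounted_cost=cost_u,
        undiscounted_ly=ly_u,
        undiscounted_qaly=qaly_u,
        discount_rate_costs=rc,
        discount_rate_outcomes=ro,
        trace=CohortTrace(occupancy=np.array(trace_rows), start_age=params.start_age),
    )


def _collapse4(occ5: np.ndarray) -> np.ndarray:
    return np.array([occ5[0], occ5[1], occ5[2] + occ5[3], occ5[4]])
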