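"""Reference fixtures, a random-parameter generator, and an individual-level
microsimulation oracle.

The packaged fixture under ``data/`` carries every model input that is
printed in the main text of the source analysis (utilities of the two PD
modalities, discount rates, starting age, the WTP threshold, and the full
budget-impact configuration). The per-year transition schedule, HD/KT
utilities and the cost tables live in that study's supplementary variables
table, which is not redistributed here: the fixture ships clearly-tagged
synthetic placeholder values in those slots so the whole pipeline runs end to
end, and a provenance manifest records, value by value, which numbers are
real and which are placeholders. Transcribing the supplementary table into
``supplementary_template.json`` (flipping tags to ``supplementary_transcribed``)
activates the reproduction checks that need it.

The generator emits random *valid* parameter sets — monotone survival curves
pushed through the survival-to-probability chain, utilities in [0, 1],
positive costs — for property testing, and the microsimulation oracle
replays the exact same cycle matrices one individual at a time as an
independent check on the cohort engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from . import engine
from .budget import BIAConfig
from .params import (
    ALLOWED_TRANSITIONS,
    MAX_SCHEDULE_YEAR,
    ModelParameters,
    SurvivalCurve,
    extrapolate_survival,
    parameters_from_dict,
    survival_to_cycle_probs,
)

PROVENANCE_TAGS = ("main_text", "supplementary_transcribed", "synthetic_placeholder")


class FixtureManifest(BaseModel):
    """Provenance tag and source note for every fixture value."""

    provenance: dict[str, str]
    sources: dict[str, str] = {}

    @model_validator(mode="after")
    def _check(self) -> "FixtureManifest":
        for key, tag in self.provenance.items():
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"unknown provenance tag {tag!r} for {key!r}")
        return self

    def has_transcribed_supplementary(self) -> bool:
        """True once the supplementary variables table has been transcribed
        (no placeholder remains among the model parameters)."""
        return all(tag != "synthetic_placeholder" for tag in self.provenance.values())


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("pedpd_cua").joinpath("data", name).read_text()


def load_reference_parameters() -> tuple[ModelParameters, FixtureManifest]:
    """The packaged parameter fixture plus its provenance manifest."""
    doc = json.loads(_data_text("supplementary_template.json"))
    params = parameters_from_dict(doc["parameters"])
    manifest = FixtureManifest(provenance=doc["provenance"],
                               sources=doc.get("sources", {}))
    # the manifest must tag every scalar parameter and every global setting
    wanted = {pid for pid, _, _ in params.iter_entries()}
    wanted |= {"mortality", "discount_costs", "discount_outcomes", "start_age", "wtp"}
    missing = wanted - set(manifest.provenance)
    if missing:
        raise ValueError(f"fixture manifest lacks provenance for: {sorted(missing)[:5]}...")
    return params, manifest


def load_bia_reference() -> BIAConfig:
    """Budget-impact configuration with the published yearly patient counts."""
    doc = json.loads(_data_text("bia_reference.json"))
    return BIAConfig.model_validate(doc)


def load_main_text_values() -> dict:
    """The raw main-text value dictionary (utilities, discounting, WTP, BIA)."""
    return json.loads(_data_text("reference_main_text.json"))


# ---------------------------------------------------------------------------
# random parameter-set generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic parameter-set generator.

    ``profile="realistic"`` draws values in ranges typical of a pediatric
    dialysis cohort (low single-digit percent annual event probabilities,
    six-figure baht annual costs); ``"small"`` produces short-horizon,
    high-mortality sets that a microsimulation can resolve quickly;
    ``"fuzz"`` stretches probabilities toward 0 and 1 to exercise edge cases.
    """

    profile: Literal["realistic", "small", "fuzz"] = "realistic"
    start_age: int = 1
    max_age: Optional[int] = None
    with_ci: bool = True
    ci_rel_width: float = 0.25
    apd_utility_geq_capd: bool = True


def _draw_prob(rng: np.random.Generator, lo: float, hi: float, fuzz: bool) -> float:
    if fuzz:
        # occasionally pull toward the edges of [0, 1]
        u = rng.random()
        if u < 0.15:
            return float(rng.uniform(0.0, 0.02))
        if u < 0.30:
            return float(rng.uniform(0.7, 0.98))
    return float(rng.uniform(lo, hi))


def generate_parameter_set(seed: int, config: GeneratorConfig | None = None) -> ModelParameters:
    """Random, fully valid parameter set (deterministic for a given seed).

    Dialysis-state death probabilities come from a randomly drawn monotone
    survival curve observed to year 3 and extrapolated to year 10 through the
    constant-hazard rule, then converted to per-cycle probabilities — the same
    chain a real parameterization would use.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    fuzz = cfg.profile == "fuzz"
    small = cfg.profile == "small"

    max_age = cfg.max_age
    if max_age is None:
        max_age = cfg.start_age + int(rng.integers(25, 40)) if small else 100

    transitions: list[dict] = []

    def add(arm, year, frm, to, p):
        p = float(min(max(p, 0.0), 1.0))
        entry = {"arm": arm, "year": year, "from": frm, "to": to, "p": p}
        if cfg.with_ci:
            w = cfg.ci_rel_width
            entry["ci_low"] = max(0.0, p * (1 - w))
            entry["ci_high"] = min(1.0, p * (1 + w) if p > 0 else 0.02)
        transitions.append(entry)

    # per-arm survival curve for the dialysis state -> PD->DEAD schedule
    death_probs = {}
    for arm in ("APD", "CAPD"):
        lo, hi = (0.08, 0.35) if small else (0.01, 0.10)
        d = [_draw_prob(rng, lo, hi, fuzz) for _ in range(3)]
        s = [1.0]
        for dec in d:
            s.append(s[-1] * (1.0 - min(dec, 0.98)))
        curve = extrapolate_survival(SurvivalCurve(values=s), MAX_SCHEDULE_YEAR)
        death_probs[arm] = survival_to_cycle_probs(curve)

    # shared between arms; capped so arm-specific PD exits keep room below 1
    pd_kt = [min(_draw_prob(rng, 0.02, 0.10, fuzz), 0.45)
             for _ in range(MAX_SCHEDULE_YEAR)]

    for arm in ("APD", "CAPD"):
        pd_hd = [_draw_prob(rng, 0.02, 0.12 if small else 0.08, fuzz)
                 for _ in range(MAX_SCHEDULE_YEAR)]
        hd_pd = [_draw_prob(rng, 0.03, 0.15, fuzz) for _ in range(MAX_SCHEDULE_YEAR)]
        hd_dead = [min(p * float(rng.uniform(1.0, 1.6)), 0.95)
                   for p in death_probs[arm]]
        kt_hd = [_draw_prob(rng, 0.005, 0.05, fuzz) for _ in range(MAX_SCHEDULE_YEAR)]
        kt_pd = [_draw_prob(rng, 0.002, 0.03, fuzz) for _ in range(MAX_SCHEDULE_YEAR)]
        kt_dead = [_draw_prob(rng, 0.002, 0.05, fuzz) for _ in range(MAX_SCHEDULE_YEAR)]
        for y in range(1, MAX_SCHEDULE_YEAR + 1):
            i = y - 1
            # keep each source state's exits comfortably below 1 (background
            # mortality still has to fit into the residual); the shared
            # PD->KT probability is left untouched so both arms stay equal,
            # and the arm-specific PD exits are squeezed into the remainder
            pd_budget = 0.95 - pd_kt[i]
            pd_own = pd_hd[i] + death_probs[arm][i]
            s_pd = min(1.0, pd_budget / pd_own) if pd_own > 0 else 1.0
            hd_sum = hd_pd[i] + hd_dead[i]
            s_hd = min(1.0, 0.95 / hd_sum) if hd_sum > 0 else 1.0
            kt_sum = kt_hd[i] + kt_pd[i] + kt_dead[i]
            s_kt = min(1.0, 0.95 / kt_sum) if kt_sum > 0 else 1.0
            add(arm, y, "PD", "HD", pd_hd[i] * s_pd)
            add(arm, y, "PD", "DEAD", death_probs[arm][i] * s_pd)
            add(arm, y, "HD", "PD", hd_pd[i] * s_hd)
            add(arm, y, "HD", "DEAD", hd_dead[i] * s_hd)
            add(arm, y, "KT", "HD", kt_hd[i] * s_kt)
            add(arm, y, "KT", "PD", kt_pd[i] * s_kt)
            add(arm, y, "KT", "DEAD", kt_dead[i] * s_kt)
            if arm == "APD":  # PD->KT is shared between arms by assumption
                add(None, y, "PD", "KT", pd_kt[i])

    costs: list[dict] = []

    def add_cost(arm, state, component, value):
        entry = {"arm": arm, "state": state, "component": component,
                 "value": float(value)}
        if cfg.with_ci:
            w = cfg.ci_rel_width
            entry["ci_low"] = value * (1 - w)
            entry["ci_high"] = value * (1 + w)
        costs.append(entry)

    for arm, base in (("APD", 600_000.0), ("CAPD", 500_000.0)):
        y1 = base * float(rng.lognormal(0.0, 0.15))
        add_cost(arm, "PD", "dmc_year1", y1)
        add_cost(arm, "PD", "dmc_year2plus", y1 * float(rng.uniform(0.7, 0.95)))
        add_cost(arm, "PD", "dnmc", base * 0.15 * float(rng.lognormal(0.0, 0.2)))
    hd1 = 800_000.0 * float(rng.lognormal(0.0, 0.15))
    add_cost(None, "HD", "dmc_year1", hd1)
    add_cost(None, "HD", "dmc_year2plus", hd1 * float(rng.uniform(0.8, 1.0)))
    add_cost(None, "HD", "dnmc", 120_000.0 * float(rng.lognormal(0.0, 0.2)))
    kt1 = 900_000.0 * float(rng.lognormal(0.0, 0.15))
    add_cost(None, "KT", "dmc_year1", kt1)
    add_cost(None, "KT", "dmc_year2plus", kt1 * float(rng.uniform(0.15, 0.35)))
    add_cost(None, "KT", "dnmc", 40_000.0 * float(rng.lognormal(0.0, 0.2)))

    utilities: list[dict] = []
    u_pd = sorted(rng.uniform(0.6, 0.98, size=2))
    u_capd, u_apd = (u_pd if cfg.apd_utility_geq_capd
                     else rng.uniform(0.6, 0.98, size=2))

    def add_util(arm, state, value):
        value = float(min(max(value, 0.0), 1.0))
        entry = {"arm": arm, "state": state, "value": value}
        if cfg.with_ci:
            entry["ci_low"] = max(0.0, value - 0.05)
            entry["ci_high"] = min(1.0, value + 0.05)
        utilities.append(entry)

    add_util("APD", "PD", u_apd)
    add_util("CAPD", "PD", u_capd)
    add_util(None, "HD", rng.uniform(0.4, 0.85))
    add_util(None, "KT", rng.uniform(0.75, 0.98))

    # background mortality stays small enough (<= 0.04) that merging it into
    # any generated row's death entry cannot push the exits above 1
    c1 = float(rng.uniform(1e-5, 1e-4))
    g = float(rng.uniform(0.05, 0.08))
    mortality = {
        age: float(min(0.04, 2e-4 + c1 * np.exp(g * age)))
        for age in range(cfg.start_age, max_age + 1)
    }

    return parameters_from_dict({
        "transitions": transitions,
        "costs": costs,
        "utilities": utilities,
        "mortality": mortality,
        "discount_rate_costs": 0.03,
        "discount_rate_outcomes": 0.03,
        "start_age": cfg.start_age,
        "max_age": max_age,
        "wtp": 160_000.0,
    })


# ---------------------------------------------------------------------------
# individual-level microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Monte-Carlo estimate of one arm's discounted totals."""

    arm: str
    n_individuals: int
    cost: float
    ly: float
    qaly: float
    se_cost: float
    se_ly: float
    se_qaly: float


def microsim_oracle(
    params: ModelParameters,
    arm: str,
    n_individuals: int,
    seed: int,
    scenario: str = "base",
) -> MicrosimResult:
    """Simulate individuals one by one through the same cycle matrices as the
    cohort engine and average their discounted outcomes.

    This is a deliberately independent realization of the model — categorical
    sampling per person per cycle instead of matrix-vector cohort algebra —
    so agreement with :func:`pedpd_cua.engine.run_cohort` within Monte-Carlo
    error is evidence both are right. Returns means and standard errors.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_individuals
    dead_idx = len(engine.STATES5) - 1

    states = np.zeros(n, dtype=np.int64)  # everyone starts in the PD state
    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)

    util = engine.utility_vector5(params, arm)
    vc = 1.0 / (1.0 + params.discount_rate_costs)
    vo = 1.0 / (1.0 + params.discount_rate_outcomes)
    dfc = dfo = 1.0
    max_cycles = params.max_age - params.start_age + 1

    for t in range(max_cycles):
        alive = states != dead_idx
        if not alive.any():
            break
        costs_t = engine.cost_vector5(params, arm, t)
        cost += dfc * costs_t[states]
        ly += dfo * alive
        qaly += dfo * util[states]
        cum = np.cumsum(engine.cycle_matrix5(params, arm, t, scenario), axis=1)
        u = rng.random(n)
        states = np.minimum((u[:, None] > cum[states]).sum(axis=1), dead_idx)
        dfc *= vc
        dfo *= vo

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("inf")

    return MicrosimResult(
        arm=arm, n_individuals=n,
        cost=float(cost.mean()), ly=float(ly.mean()), qaly=float(qaly.mean()),
        se_cost=se(cost), se_ly=se(ly), se_qaly=se(qaly),
    )
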