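"""Ten-year budget-impact projection for adopting APD nationwide.

Projects the pediatric peritoneal-dialysis population year by year — survivors
retained after attrition to transplantation, hemodialysis and death, plus
incident cases — and prices each projected year under CAPD and APD annual
direct medical costs from the payer perspective (no discounting, full
first-year uptake).

The printed-table arithmetic rounds each arm's budget and the incremental
budget (computed from the exact cost difference, not from the two already
rounded budgets) to whole millions of baht, then divides the rounded
incremental by the patient count for the per-patient net budget impact; an
``exact`` mode keeps full precision instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class BIAConfig(BaseModel):
    """Configuration of the budget-impact projection.

    Patient counts can be supplied directly per year (``counts``) or projected
    from a base-year count with incident-case inflow and attrition. Incident
    cases may be given directly or derived from an all-age ESKD incidence
    series times the pediatric proportion and the PD probability.
    """

    years: list[int]
    counts: Optional[list[float]] = None

    base_year: Optional[int] = None
    base_count: Optional[float] = None
    incident_cases: Optional[list[float] | float] = None
    incidence_all_age: Optional[list[float]] = None
    proportion_pediatric: float = Field(default=0.004, ge=0.0, le=1.0)
    proportion_pd: float = Field(default=0.76, ge=0.0, le=1.0)

    p_kt: float = Field(default=0.079, ge=0.0, le=1.0)
    p_hd: float = Field(default=0.031, ge=0.0, le=1.0)
    p_death: float = Field(default=0.023, ge=0.0, le=1.0)

    annual_cost_capd: float = Field(default=433_641.0, gt=0.0)
    annual_cost_apd: float = Field(default=496_836.0, gt=0.0)
    uptake: float = Field(default=1.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "BIAConfig":
        if self.p_kt + self.p_hd + self.p_death > 1.0:
            raise ValueError("attrition probabilities sum above 1")
        if self.counts is not None and len(self.counts) != len(self.years):
            raise ValueError("counts must align with years")
        if self.counts is None and (self.base_year is None or self.base_count is None):
            raise ValueError("need either explicit counts or a base-year count to project")
        return self


@dataclass
class BIAYear:
    year: int
    n_patients: int
    budget_capd_m: int  # million baht, rounded as printed
    budget_apd_m: int
    incremental_m: int
    nbi_per_patient: Optional[int]  # baht; None when no patients


@dataclass
class BIATable:
    rows: list[BIAYear]
    avg_patients: int
    avg_budget_capd_m: int
    avg_budget_apd_m: int
    avg_incremental_m: int
    avg_nbi_per_patient: int

    def to_frame(self, include_average: bool = True) -> pd.DataFrame:
        data = [{
            "year": r.year,
            "n_patients": r.n_patients,
            "budget_capd_million": r.budget_capd_m,
            "budget_apd_million": r.budget_apd_m,
            "incremental_million": r.incremental_m,
            "nbi_per_patient": r.nbi_per_patient,
        } for r in self.rows]
        if include_average:
            data.append({
                "year": "Average",
                "n_patients": self.avg_patients,
                "budget_capd_million": self.avg_budget_capd_m,
                "budget_apd_million": self.avg_budget_apd_m,
                "incremental_million": self.avg_incremental_m,
                "nbi_per_patient": self.avg_nbi_per_patient,
            })
        return pd.DataFrame(data)


def _incident_for(config: BIAConfig, i: int) -> float:
    """Incident pediatric PD cases entering in projection step i (1-based)."""
    if config.incidence_all_age is not None:
        series = [x * config.proportion_pediatric * config.proportion_pd
                  for x in config.incidence_all_age]
        return series[min(i - 1, len(series) - 1)]
    if config.incident_cases is None:
        return 0.0
    if isinstance(config.incident_cases, (int, float)):
        return float(config.incident_cases)
    return config.incident_cases[min(i - 1, len(config.incident_cases) - 1)]


def project_patients(config: BIAConfig) -> list[float]:
    """Yearly pediatric PD patient counts over the projection years.

    Each step retains last year's patients net of attrition to KT, HD and
    death and adds the year's incident cases:
    ``count(y+1) = count(y) * (1 - p_kt - p_hd - p_death) + incident(y+1)``.
    Counts are kept fractional here; rounding happens at report time.
    """
    if config.counts is not None:
        return list(config.counts)
    retention = 1.0 - config.p_kt - config.p_hd - config.p_death
    count = float(config.base_count)  # at base_year
    year = config.base_year
    out = []
    step = 0
    first, last = config.years[0], config.years[-1]
    while year < last:
        year += 1
        step += 1
        count = count * retention + _incident_for(config, step)
        if count < 0:
            raise ValueError(f"projected count went negative in {year}")
        if year >= first:
            out.append(count)
    if len(out) != len(config.years):
        raise ValueError("projection did not cover the requested years; "
                         "base_year must precede the first projection year")
    return out


def compute_bia(
    counts: Sequence[float], config: BIAConfig, mode: str = "printed"
) -> BIATable:
    """Budget table from yearly patient counts.

    ``printed`` mode reproduces published-table arithmetic: patient counts,
    per-arm million-baht budgets and the incremental budget (from the exact
    cost difference) are each rounded half-up, and NBI per patient divides the
    rounded incremental by the count — so the incremental cell can differ by
    1 M from the difference of the two rounded budget cells. ``exact`` mode
    carries full precision (the unrounded NBI per patient is simply the
    APD/CAPD unit-cost difference).
    """
    if mode not in ("printed", "exact"):
        raise ValueError("mode must be 'printed' or 'exact'")
    rows = []
    for year, n in zip(config.years, counts):
        if n < 0:
            raise ValueError(f"negative patient count in {year}")
        if mode == "printed":
            n_pat = round_half_up(n)
            b_capd = round_half_up(n_pat * config.annual_cost_capd / 1e6)
            b_apd = round_half_up(n_pat * config.annual_cost_apd / 1e6)
            inc = round_half_up(
                n_pat * (config.annual_cost_apd - config.annual_cost_capd) / 1e6)
            nbi = round_half_up(inc * 1e6 / n_pat) if n_pat > 0 else None
            rows.append(BIAYear(year, n_pat, b_capd, b_apd, inc, nbi))
        else:
            b_capd = n * config.annual_cost_capd / 1e6
            b_apd = n * config.annual_cost_apd / 1e6
            inc = b_apd - b_capd
            nbi = (config.annual_cost_apd - config.annual_cost_capd) if n > 0 else None
            rows.append(BIAYear(year, n, b_capd, b_apd, inc, nbi))

    def mean(vals):
        return sum(vals) / len(vals)

    nbi_rows = [r.nbi_per_patient for r in rows if r.nbi_per_patient is not None]
    if mode == "printed":
        return BIATable(
            rows=rows,
            avg_patients=round_half_up(mean([r.n_patients for r in rows])),
            avg_budget_capd_m=round_half_up(mean([r.budget_capd_m for r in rows])),
            avg_budget_apd_m=round_half_up(mean([r.budget_apd_m for r in rows])),
            avg_incremental_m=round_half_up(mean([r.incremental_m for r in rows])),
            avg_nbi_per_patient=round_half_up(mean(nbi_rows)) if nbi_rows else 0,
        )
    return BIATable(
        rows=rows,
        avg_patients=mean([r.n_patients for r in rows]),
        avg_budget_capd_m=mean([r.budget_capd_m for r in rows]),
        avg_budget_apd_m=mean([r.budget_apd_m for r in rows]),
        avg_incremental_m=mean([r.incremental_m for r in rows]),
        avg_nbi_per_patient=mean(nbi_rows) if nbi_rows else 0,
    )


def run_bia(config: BIAConfig, mode: str = "printed") -> BIATable:
    """Project patients (or take supplied counts) and price the budgets."""
    return compute_bia(project_patients(config), config, mode=mode)
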