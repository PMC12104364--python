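"""Two-strategy cost-effectiveness comparison.

Incremental cost, life years and QALYs between a reference arm (CAPD) and an
alternative (APD); ICER per QALY and per LY; dominance labels; net monetary
benefit; and a table-style report of per-arm totals and incrementals. All
ratios are computed from unrounded totals — rounding is presentation only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .engine import ArmResult, ConfigurationError


@dataclass
class CEAResult:
    ref_arm: str
    alt_arm: str
    ref_cost: float
    ref_ly: float
    ref_qaly: float
    alt_cost: float
    alt_ly: float
    alt_qaly: float
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer_per_qaly: Optional[float]  # None when the QALY increment is zero
    icer_per_ly: Optional[float]
    dominance: str  # on the QALY axis: none | dominated | dominant
    dominance_ly: str
    wtp: float
    cost_effective_at_wtp: bool


def net_monetary_benefit(result: ArmResult, wtp: float) -> float:
    """NMB = wtp * QALY - cost, in baht (discounted totals)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.total_qaly - result.total_cost


def _dominance(d_cost: float, d_effect: float) -> str:
    if d_cost > 0 and d_effect < 0:
        return "dominated"
    if d_cost < 0 and d_effect > 0:
        return "dominant"
    return "none"


def _ratio(num: float, den: float) -> Optional[float]:
    if den == 0:
        return None
    return num / den


def compare_strategies(ref: ArmResult, alt: ArmResult, wtp: float) -> CEAResult:
    """Compare the alternative against the reference arm at a WTP threshold.

    Increments are alternative minus reference; an undefined ICER (zero
    effect difference) is reported as ``None`` rather than raising. The
    cost-effectiveness flag is the NMB ordering, which for the common
    north-east quadrant reduces to ICER <= WTP.
    """
    if (ref.discount_rate_costs, ref.discount_rate_outcomes) != (
        alt.discount_rate_costs, alt.discount_rate_outcomes
    ):
        raise ConfigurationError("arms were run with different discount rates")
    if ref.scenario != alt.scenario:
        raise ConfigurationError("arms were run under different scenarios")

    d_cost = alt.total_cost - ref.total_cost
    d_ly = alt.total_ly - ref.total_ly
    d_qaly = alt.total_qaly - ref.total_qaly
    nmb_diff = wtp * d_qaly - d_cost
    return CEAResult(
        ref_arm=ref.arm,
        alt_arm=alt.arm,
        ref_cost=ref.total_cost,
        ref_ly=ref.total_ly,
        ref_qaly=ref.total_qaly,
        alt_cost=alt.total_cost,
        alt_ly=alt.total_ly,
        alt_qaly=alt.total_qaly,
        incremental_cost=d_cost,
        incremental_ly=d_ly,
        incremental_qaly=d_qaly,
        icer_per_qaly=_ratio(d_cost, d_qaly),
        icer_per_ly=_ratio(d_cost, d_ly),
        dominance=_dominance(d_cost, d_qaly),
        dominance_ly=_dominance(d_cost, d_ly),
        wtp=wtp,
        cost_effective_at_wtp=nmb_diff >= 0,
    )


def report_frame(result: CEAResult) -> pd.DataFrame:
    """Cost-utility results laid out like a published summary table."""

    def fmt_icer(icer: Optional[float], dom: str) -> str:
        if icer is None:
            return "undefined"
        s = f"{icer:,.0f}"
        if dom == "dominated":
            s += " (Dominated)"
        return s

    rows = [
        ("Total costs (baht)", f"{result.ref_cost:,.0f}", f"{result.alt_cost:,.0f}"),
        ("Total life years", f"{result.ref_ly:.2f}", f"{result.alt_ly:.2f}"),
        ("Total QALYs", f"{result.ref_qaly:.2f}", f"{result.alt_qaly:.2f}"),
        ("Incremental costs", "", f"{result.incremental_cost:,.0f}"),
        ("Incremental LYs", "", f"{result.incremental_ly:.2f}"),
        ("Incremental QALYs", "", f"{result.incremental_qaly:.2f}"),
        ("ICER (baht/LY gained)", "",
         fmt_icer(result.icer_per_ly, result.dominance_ly)),
        ("ICER (baht/QALY gained)", "",
         fmt_icer(result.icer_per_qaly, result.dominance)),
    ]
    return pd.DataFrame(rows, columns=["Results", result.ref_arm, result.alt_arm])


def write_report(result: CEAResult, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    report_frame(result).to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {k: (None if isinstance(v, float) and math.isnan(v) else v)
               for k, v in result.__dict__.items()}
        Path(json_path).write_text(json.dumps(doc, indent=2))
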