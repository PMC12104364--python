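"""Model parameters for the pediatric peritoneal-dialysis cost-utility model.

Defines the health-state vocabulary, the per-arm transition schedule, cost and
utility sets, the background-mortality table, and the survival-curve
manipulations used to derive annual transition probabilities:

* ``survival_to_cycle_probs`` — turn a survival curve S(0..T) into per-cycle
  event probabilities via the conditional-survival / rate round trip,
* ``extrapolate_survival`` — extend a 3-year observed curve to year 10 using
  the year-2 to year-3 conditional survival ratio (constant hazard),
* ``combine_mortality`` — merge disease-specific and background death
  probabilities as independent competing risks.

Parameter files are a single JSON document (schema ``pedpd-cua-params-v1``)
or an equivalent CSV bundle (one file per table); :func:`load_parameters` and
:func:`write_parameters` round-trip both.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, PrivateAttr, model_validator

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "pedpd-cua-params-v1"

ARMS = ("APD", "CAPD")

#: transitions that carry an explicit probability; anything else is either the
#: residual "stay" probability or forbidden (e.g. no direct HD -> KT moves).
ALLOWED_TRANSITIONS = (
    ("PD", "HD"),
    ("PD", "KT"),
    ("PD", "DEAD"),
    ("HD", "PD"),
    ("HD", "DEAD"),
    ("KT", "HD"),
    ("KT", "PD"),
    ("KT", "DEAD"),
)

COST_COMPONENTS = ("dmc_year1", "dmc_year2plus", "dnmc")

MAX_SCHEDULE_YEAR = 10


class HealthState(str, enum.Enum):
    """Health states of the per-arm model.

    ``PD`` denotes the arm's assigned peritoneal-dialysis modality (APD in the
    APD arm, CAPD in the CAPD arm); the two arms share the HD, KT and DEAD
    states, and DEAD is absorbing.
    """

    PD = "PD"
    HD = "HD"
    KT = "KT"
    DEAD = "DEAD"


class SchemaError(ValueError):
    """A parameter file or parameter set violates the published schema."""


class DegenerateCurveError(ValueError):
    """A survival curve reaches zero where a conditional ratio is needed."""


# ---------------------------------------------------------------------------
# survival-curve operations
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Survival probabilities S(t) for integer years t = 0..T.

    S(0) must be 1 and the curve must be non-increasing.
    """

    values: list[float]

    def __post_init__(self) -> None:
        v = self.values = [float(x) for x in self.values]
        if len(v) < 2:
            raise SchemaError("survival curve needs at least S(0) and S(1)")
        if abs(v[0] - 1.0) > 1e-12:
            raise SchemaError(f"S(0) must be 1, got {v[0]}")
        for t in range(1, len(v)):
            if not (0.0 <= v[t] <= 1.0):
                raise SchemaError(f"S({t})={v[t]} outside [0, 1]")
            if v[t] > v[t - 1] + 1e-12:
                raise SchemaError(f"survival increases at year {t}: {v[t - 1]} -> {v[t]}")

    @property
    def horizon(self) -> int:
        return len(self.values) - 1


def prob_to_rate(p: float, cycle: float = 1.0) -> float:
    """Annualized event rate for a per-cycle probability, r = -ln(1-p)/cycle."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 1.0:
        return math.inf
    return -math.log1p(-p) / cycle


def rate_to_prob(r: float, cycle: float = 1.0) -> float:
    """Per-cycle event probability for a rate, p = 1 - exp(-r*cycle)."""
    if r < 0:
        raise ValueError(f"rate {r} must be non-negative")
    if math.isinf(r):
        return 1.0
    return -math.expm1(-r * cycle)


def survival_to_cycle_probs(curve: SurvivalCurve) -> list[float]:
    """Per-cycle transition probabilities tp(u) from a survival curve.

    For each year t >= 1 the conditional survival is S(u) = S(t)/S(t-1), the
    cycle event probability tp(t) = 1 - S(u); converting through the annual
    rate r = -ln(1-tp(t)) and back via 1 - exp(-r) is the identity for a
    one-year cycle, and both directions are exercised here so the round trip
    stays honest.
    """
    out: list[float] = []
    s = curve.values
    for t in range(1, len(s)):
        if s[t - 1] == 0.0:
            raise DegenerateCurveError(
                f"S({t - 1}) = 0: conditional survival undefined at year {t}"
            )
        tp = 1.0 - s[t] / s[t - 1]
        tp = min(max(tp, 0.0), 1.0)  # guard float dust on flat segments
        out.append(rate_to_prob(prob_to_rate(tp)))
    return out


def extrapolate_survival(curve: SurvivalCurve, target_year: int = MAX_SCHEDULE_YEAR) -> SurvivalCurve:
    """Extend an observed 3-year curve to ``target_year``.

    The conditional survival ratio between years 2 and 3, q = S(3)/S(2), is
    applied multiplicatively for every later year (constant hazard beyond the
    observation window): S(t) = S(t-1) * q for t >= 4. A curve observed to
    fewer than three years falls back to the ratio of its last two points.
    """
    s = list(curve.values)
    if len(s) < 3:
        raise SchemaError("need at least two observed years to extrapolate")
    i = 3 if len(s) >= 4 else len(s) - 1
    if s[i - 1] == 0.0:
        raise DegenerateCurveError(
            f"S({i - 1}) = 0: survival ratio for extrapolation undefined"
        )
    q = s[i] / s[i - 1]
    while len(s) - 1 < target_year:
        s.append(s[-1] * q)
    return SurvivalCurve(values=s)


def combine_mortality(
    p_state_death: float,
    p_background: float,
    mode: Literal["competing", "max"] = "competing",
) -> float:
    """Merge a disease-specific and a background annual death probability.

    Default treats the two as independent competing risks,
    1 - (1-p_state)*(1-p_background); ``mode="max"`` instead takes whichever
    risk is larger (useful to avoid double counting when the state-specific
    estimate already embeds all-cause mortality).
    """
    for name, p in (("p_state_death", p_state_death), ("p_background", p_background)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if mode == "max":
        return max(p_state_death, p_background)
    return 1.0 - (1.0 - p_state_death) * (1.0 - p_background)


# ---------------------------------------------------------------------------
# parameter entries
# ---------------------------------------------------------------------------


class _CIEntry(BaseModel):
    """Shared value + optional 95% CI behaviour."""

    model_config = ConfigDict(populate_by_name=True)

    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def _check_ci(self, value: float) -> None:
        if (self.ci_low is None) != (self.ci_high is None):
            raise SchemaError(f"{self.param_id()}: CI must give both bounds or neither")
        if self.ci_low is not None:
            if not self.ci_low <= value <= self.ci_high:  # type: ignore[operator]
                raise SchemaError(
                    f"{self.param_id()}: CI ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket the point value {value}"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None

    def param_id(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError


class TransitionEntry(_CIEntry):
    """One scheduled transition probability.

    ``arm=None`` means the row applies identically to both arms (used for the
    shared PD->KT probability and for the years where the two modalities share
    a common source cohort).
    """

    arm: Optional[Literal["APD", "CAPD"]] = None
    year: int = Field(ge=1, le=MAX_SCHEDULE_YEAR)
    frm: Literal["PD", "HD", "KT"] = Field(alias="from")
    to: Literal["PD", "HD", "KT", "DEAD"]
    p: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "TransitionEntry":
        if (self.frm, self.to) not in ALLOWED_TRANSITIONS:
            raise SchemaError(f"transition {self.frm}->{self.to} is not part of the model")
        self._check_ci(self.p)
        if self.ci_low is not None and not (0.0 <= self.ci_low and self.ci_high <= 1.0):
            raise SchemaError(f"{self.param_id()}: CI outside [0, 1]")
        return self

    def param_id(self) -> str:
        arm = self.arm or "both"
        return f"p_{arm}_{self.frm}to{self.to}_y{self.year}"


class CostEntry(_CIEntry):
    """One annual cost component (baht/year) for a state, optionally per arm."""

    arm: Optional[Literal["APD", "CAPD"]] = None
    state: Literal["PD", "HD", "KT"]
    component: Literal["dmc_year1", "dmc_year2plus", "dnmc"]
    value: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CostEntry":
        self._check_ci(self.value)
        if self.ci_low is not None and self.ci_low < 0:
            raise SchemaError(f"{self.param_id()}: negative CI bound for a cost")
        return self

    def param_id(self) -> str:
        arm = self.arm or "shared"
        return f"c_{arm}_{self.state}_{self.component}"


class UtilityEntry(_CIEntry):
    """Per-state utility weight in [0, 1], arm-specific for the PD state."""

    arm: Optional[Literal["APD", "CAPD"]] = None
    state: Literal["PD", "HD", "KT"]
    value: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "UtilityEntry":
        self._check_ci(self.value)
        if self.ci_low is not None and not (0.0 <= self.ci_low and self.ci_high <= 1.0):
            raise SchemaError(f"{self.param_id()}: CI outside [0, 1]")
        return self

    def param_id(self) -> str:
        if self.state == "PD":
            return f"u_{self.arm}"
        return f"u_{self.state}"


class CostSet(BaseModel):
    """Annual costs for one state: direct medical in the first year, direct
    medical from year 2 onward, and direct non-medical (all years)."""

    dmc_year1: float
    dmc_year2plus: float
    dnmc: float


class ParamDistribution(BaseModel):
    """Resolved sampling distribution for one uncertain parameter."""

    family: Literal["beta", "gamma", "uniform", "fixed"]
    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------


class ModelParameters(BaseModel):
    """Complete, validated parameter set for the two-arm model."""

    model_config = ConfigDict(populate_by_name=True)

    schema_version: str = SCHEMA_VERSION
    arms: tuple[str, str] = ("APD", "CAPD")
    transitions: list[TransitionEntry]
    costs: list[CostEntry]
    utilities: list[UtilityEntry]
    mortality: dict[int, float]
    discount_rate_costs: float = 0.03
    discount_rate_outcomes: float = 0.03
    start_age: int = 1
    max_age: int = 100
    wtp: float = 160_000.0
    mortality_combination: Literal["competing", "max"] = "competing"
    half_cycle_correction: bool = False
    #: per-parameter sampling-family overrides, keyed by parameter id
    distributions: dict[str, Literal["beta", "gamma", "uniform", "fixed"]] = {}

    _transition_index: dict[tuple[str, int, str, str], TransitionEntry] = PrivateAttr(default=None)
    _cost_index: dict[tuple[str, str, str], CostEntry] = PrivateAttr(default=None)
    _utility_index: dict[tuple[str, str], UtilityEntry] = PrivateAttr(default=None)

    # -- validation --------------------------------------------------------

    @model_validator(mode="after")
    def _validate(self) -> "ModelParameters":
        if tuple(self.arms) != ARMS:
            raise SchemaError(f"arms must be {ARMS}, got {self.arms}")
        if not 0.0 <= self.discount_rate_costs <= 0.10:
            raise SchemaError(f"discount_rate_costs={self.discount_rate_costs} outside [0, 0.10]")
        if not 0.0 <= self.discount_rate_outcomes <= 0.10:
            raise SchemaError(f"discount_rate_outcomes={self.discount_rate_outcomes} outside [0, 0.10]")
        if not 0 <= self.start_age < self.max_age:
            raise SchemaError("need 0 <= start_age < max_age")

        self._build_indexes()

        # completeness: every arm/year/transition resolvable exactly once
        for arm in ARMS:
            for year in range(1, MAX_SCHEDULE_YEAR + 1):
                for frm, to in ALLOWED_TRANSITIONS:
                    specific = self._transition_index.get((arm, year, frm, to))
                    shared = self._transition_index.get(("both", year, frm, to))
                    if specific is None and shared is None:
                        raise SchemaError(f"missing transition p_{arm}_{frm}to{to}_y{year}")
                    if specific is not None and shared is not None:
                        raise SchemaError(
                            f"transition {frm}->{to} year {year} defined both per-arm and shared"
                        )
        # exit-probability cap and the shared-KT assumption
        for arm in ARMS:
            for year in range(1, MAX_SCHEDULE_YEAR + 1):
                for frm in ("PD", "HD", "KT"):
                    total = sum(
                        self.transition(arm, year, frm, to).p
                        for f, to in ALLOWED_TRANSITIONS
                        if f == frm
                    )
                    if total > 1.0 + 1e-9:
                        raise SchemaError(
                            f"exit probabilities from {frm} sum to {total:.6f} > 1 "
                            f"(arm={arm}, year={year})"
                        )
        for year in range(1, MAX_SCHEDULE_YEAR + 1):
            a = self.transition("APD", year, "PD", "KT").p
            c = self.transition("CAPD", year, "PD", "KT").p
            if abs(a - c) > 1e-12:
                raise SchemaError(
                    f"PD->KT must be equal across arms (year {year}): APD {a} vs CAPD {c}"
                )

        # costs and utilities resolvable for every arm/state
        for arm in ARMS:
            for state in ("PD", "HD", "KT"):
                for comp in COST_COMPONENTS:
                    if (
                        self._cost_index.get((arm, state, comp)) is None
                        and self._cost_index.get(("shared", state, comp)) is None
                    ):
                        raise SchemaError(f"missing cost c_{arm}_{state}_{comp}")
                if (
                    self._utility_index.get((arm, state)) is None
                    and self._utility_index.get(("shared", state)) is None
                ):
                    raise SchemaError(f"missing utility for state {state} (arm {arm})")
            if self._utility_index.get((arm, "PD")) is None:
                raise SchemaError(f"utility of the PD state must be arm-specific ({arm})")

        # mortality table covers every age reachable within the horizon
        for age in range(self.start_age, self.max_age + 1):
            q = self.mortality.get(age)
            if q is None:
                raise SchemaError(f"mortality table does not cover age {age}")
            if not 0.0 <= q <= 1.0:
                raise SchemaError(f"mortality[{age}]={q} outside [0, 1]")
        return self

    def _build_indexes(self) -> None:
        ti: dict[tuple[str, int, str, str], TransitionEntry] = {}
        for e in self.transitions:
            key = (e.arm or "both", e.year, e.frm, e.to)
            if key in ti:
                raise SchemaError(f"duplicate transition entry {e.param_id()}")
            ti[key] = e
        ci: dict[tuple[str, str, str], CostEntry] = {}
        for e in self.costs:
            key = (e.arm or "shared", e.state, e.component)
            if key in ci:
                raise SchemaError(f"duplicate cost entry {e.param_id()}")
            ci[key] = e
        ui: dict[tuple[str, str], UtilityEntry] = {}
        for e in self.utilities:
            key = (e.arm or "shared", e.state)
            if key in ui:
                raise SchemaError(f"duplicate utility entry {e.param_id()}")
            ui[key] = e
        self._transition_index = ti
        self._cost_index = ci
        self._utility_index = ui

    # -- accessors ---------------------------------------------------------

    def transition(self, arm: str, year: int, frm: str, to: str) -> TransitionEntry:
        """Scheduled transition entry; years beyond 10 use the year-10 row."""
        year = min(year, MAX_SCHEDULE_YEAR)
        e = self._transition_index.get((arm, year, frm, to))
        if e is None:
            e = self._transition_index.get(("both", year, frm, to))
        if e is None:
            raise KeyError(f"no transition {frm}->{to} for arm {arm}, year {year}")
        return e

    def cost_entry(self, arm: str, state: str, component: str) -> CostEntry:
        e = self._cost_index.get((arm, state, component))
        if e is None:
            e = self._cost_index.get(("shared", state, component))
        if e is None:
            raise KeyError(f"no cost {component} for state {state}, arm {arm}")
        return e

    def cost_set(self, arm: str, state: str) -> CostSet:
        return CostSet(
            dmc_year1=self.cost_entry(arm, state, "dmc_year1").value,
            dmc_year2plus=self.cost_entry(arm, state, "dmc_year2plus").value,
            dnmc=self.cost_entry(arm, state, "dnmc").value,
        )

    def utility_entry(self, arm: str, state: str) -> UtilityEntry:
        e = self._utility_index.get((arm, state))
        if e is None:
            e = self._utility_index.get(("shared", state))
        if e is None:
            raise KeyError(f"no utility for state {state}, arm {arm}")
        return e

    def utility(self, arm: str, state: str) -> float:
        if state == "DEAD":
            return 0.0
        return self.utility_entry(arm, state).value

    def background_mortality(self, age: int) -> float:
        try:
            return self.mortality[age]
        except KeyError:
            raise KeyError(f"mortality table does not cover age {age}") from None

    # -- parameter registry (used by sensitivity analyses) ----------------

    def iter_entries(self) -> Iterator[tuple[str, str, _CIEntry]]:
        """Yield (param_id, kind, entry) for every scalar model parameter."""
        for e in self.transitions:
            yield e.param_id(), "probability", e
        for e in self.costs:
            yield e.param_id(), "cost", e
        for e in self.utilities:
            yield e.param_id(), "utility", e

    def updated(self, values: dict[str, float], clamp: bool = True) -> "ModelParameters":
        """Return a new validated parameter set with the given parameter ids
        set to new point values.

        With ``clamp=True`` (the default), values outside a parameter's
        support are clamped and any source state whose exit probabilities then
        exceed 1 has them scaled back proportionally, each with a logged
        warning — the behaviour wanted when sweeping CI bounds or sampling.
        """
        copy = self.model_copy(deep=True)
        index = {pid: (kind, entry) for pid, kind, entry in copy.iter_entries()}
        unknown = set(values) - set(index) - {"discount_costs", "discount_outcomes"}
        if unknown:
            raise KeyError(f"unknown parameter ids: {sorted(unknown)}")
        for pid, value in values.items():
            if pid == "discount_costs":
                copy.discount_rate_costs = float(value)
                continue
            if pid == "discount_outcomes":
                copy.discount_rate_outcomes = float(value)
                continue
            kind, entry = index[pid]
            if kind in ("probability", "utility"):
                if clamp and not 0.0 <= value <= 1.0:
                    logger.warning("clamping %s=%s to [0, 1]", pid, value)
                    value = min(max(value, 0.0), 1.0)
            elif kind == "cost":
                if clamp and value < 0.0:
                    logger.warning("clamping negative cost %s=%s to 0", pid, value)
                    value = 0.0
            if isinstance(entry, TransitionEntry):
                entry.p = value
            else:
                entry.value = value
            # the stored CI described the original point estimate; a moved
            # value may fall outside it, so the perturbed copy drops it
            entry.ci_low = entry.ci_high = None
        if clamp:
            _repair_exit_sums(copy)
        return ModelParameters.model_validate(copy.model_dump(by_alias=True))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = self.model_dump(by_alias=True, exclude_none=True)
        d["mortality"] = {str(k): v for k, v in sorted(self.mortality.items())}
        return d


def _repair_exit_sums(params: ModelParameters) -> None:
    """Proportionally scale exit probabilities that sum above 1 after a
    perturbation (in place, on unvalidated entries)."""
    index: dict[tuple[str, int, str, str], TransitionEntry] = {}
    for e in params.transitions:
        index[(e.arm or "both", e.year, e.frm, e.to)] = e

    def lookup(arm: str, year: int, frm: str, to: str) -> TransitionEntry:
        return index.get((arm, year, frm, to)) or index[("both", year, frm, to)]

    for arm in ARMS:
        for year in range(1, MAX_SCHEDULE_YEAR + 1):
            for frm in ("PD", "HD", "KT"):
                entries = {
                    id(lookup(arm, year, frm, to)): lookup(arm, year, frm, to)
                    for f, to in ALLOWED_TRANSITIONS
                    if f == frm
                }
                total = sum(e.p for e in entries.values())
                if total > 1.0:
                    logger.warning(
                        "exit probabilities from %s sum to %.6f (arm=%s, year=%d); rescaling",
                        frm, total, arm, year,
                    )
                    for e in entries.values():
                        e.p /= total
                        e.ci_low = e.ci_high = None


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_parameters(params: ModelParameters, path: str | Path, fmt: Optional[str] = None) -> Path:
    """Write a parameter set as a JSON document or a CSV bundle (directory)."""
    path = Path(path)
    fmt = fmt or ("csv-bundle" if path.suffix == "" else "json")
    if fmt == "json":
        path.write_text(json.dumps(params.to_dict(), indent=2))
        return path
    if fmt != "csv-bundle":
        raise ValueError(f"unknown format {fmt!r}")
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "transitions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "year", "from", "to", "p", "ci_low", "ci_high"])
        for e in params.transitions:
            w.writerow([e.arm or "both", e.year, e.frm, e.to, repr(e.p),
                        _opt(e.ci_low), _opt(e.ci_high)])
    with open(path / "costs.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "state", "component", "value", "ci_low", "ci_high"])
        for e in params.costs:
            w.writerow([e.arm or "shared", e.state, e.component, repr(e.value),
                        _opt(e.ci_low), _opt(e.ci_high)])
    with open(path / "utilities.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "state", "value", "ci_low", "ci_high"])
        for e in params.utilities:
            w.writerow([e.arm or "shared", e.state, repr(e.value),
                        _opt(e.ci_low), _opt(e.ci_high)])
    with open(path / "mortality.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age", "p_death"])
        for age in sorted(params.mortality):
            w.writerow([age, repr(params.mortality[age])])
    settings = params.to_dict()
    for key in ("transitions", "costs", "utilities", "mortality"):
        settings.pop(key)
    (path / "settings.json").write_text(json.dumps(settings, indent=2))
    return path


def _opt(x: Optional[float]) -> str:
    return "" if x is None else repr(x)


def _parse_opt(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def load_parameters(path: str | Path, fmt: Optional[str] = None) -> ModelParameters:
    """Load and fully validate a parameter set (JSON file or CSV-bundle dir)."""
    path = Path(path)
    fmt = fmt or ("csv-bundle" if path.is_dir() else "json")
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
        return parameters_from_dict(doc)
    if fmt != "csv-bundle":
        raise ValueError(f"unknown format {fmt!r}")
    doc = json.loads((path / "settings.json").read_text())
    doc["transitions"] = _read_csv(path / "transitions.csv", _transition_row)
    doc["costs"] = _read_csv(path / "costs.csv", _cost_row)
    doc["utilities"] = _read_csv(path / "utilities.csv", _utility_row)
    doc["mortality"] = {
        int(r["age"]): float(r["p_death"])
        for r in csv.DictReader(open(path / "mortality.csv"))
    }
    return parameters_from_dict(doc)


def parameters_from_dict(doc: dict) -> ModelParameters:
    try:
        doc = dict(doc)
        doc["mortality"] = {int(k): float(v) for k, v in doc.get("mortality", {}).items()}
        return ModelParameters.model_validate(doc)
    except SchemaError:
        raise
    except Exception as exc:  # pydantic error -> schema error with field info
        raise SchemaError(str(exc)) from exc


def _read_csv(path: Path, parse) -> list[dict]:
    with open(path) as fh:
        return [parse(row) for row in csv.DictReader(fh)]


def _transition_row(row: dict) -> dict:
    return {
        "arm": None if row["arm"] == "both" else row["arm"],
        "year": int(row["year"]),
        "from": row["from"],
        "to": row["to"],
        "p": float(row["p"]),
        "ci_low": _parse_opt(row["ci_low"]),
        "ci_high": _parse_opt(row["ci_high"]),
    }


def _cost_row(row: dict) -> dict:
    return {
        "arm": None if row["arm"] == "shared" else row["arm"],
        "state": row["state"],
        "component": row["component"],
        "value": float(row["value"]),
        "ci_low": _parse_opt(row["ci_low"]),
        "ci_high": _parse_opt(row["ci_high"]),
    }


def _utility_row(row: dict) -> dict:
    return {
        "arm": None if row["arm"] == "shared" else row["arm"],
        "state": row["state"],
        "value": float(row["value"]),
        "ci_low": _parse_opt(row["ci_low"]),
        "ci_high": _parse_opt(row["ci_high"]),
    }
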