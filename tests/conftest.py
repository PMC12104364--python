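import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from pedpd_cua.params import ALLOWED_TRANSITIONS, MAX_SCHEDULE_YEAR, parameters_from_dict
from pedpd_cua.synthetic import load_reference_parameters


def make_params(
    *,
    cost: float = 100.0,
    utility: float = 0.9,
    utility_apd: float | None = None,
    discount_costs: float = 0.0,
    discount_outcomes: float = 0.0,
    start_age: int = 1,
    max_age: int = 10,
    transitions: dict | None = None,
    transition_cis: dict | None = None,
    mortality_q: float = 0.0,
    cost_apd: float | None = None,
    cost_ci: tuple | None = None,
    utility_ci: tuple | None = None,
):
    """Minimal valid parameter set for closed-form tests.

    All scheduled transitions default to zero (the cohort never leaves its
    modality), every state costs ``cost``/year with utility ``utility``, and
    background mortality is flat at ``mortality_q``. ``transitions`` overrides
    individual probabilities, keyed ``(year, from, to)`` (applied to both
    arms); ``transition_cis`` adds CIs keyed the same way.
    """
    transitions = transitions or {}
    transition_cis = transition_cis or {}
    t_entries = []
    for year in range(1, MAX_SCHEDULE_YEAR + 1):
        for frm, to in ALLOWED_TRANSITIONS:
            e = {"arm": None, "year": year, "from": frm, "to": to,
                 "p": float(transitions.get((year, frm, to), 0.0))}
            if (year, frm, to) in transition_cis:
                e["ci_low"], e["ci_high"] = transition_cis[(year, frm, to)]
            t_entries.append(e)
    c_entries = []
    for state in ("PD", "HD", "KT"):
        if state == "PD" and cost_apd is not None:
            arms_costs = [("APD", cost_apd), ("CAPD", cost)]
        else:
            arms_costs = [(None, cost)]
        for arm, value in arms_costs:
            for comp in ("dmc_year1", "dmc_year2plus", "dnmc"):
                e = {"arm": arm, "state": state, "component": comp,
                     "value": value if comp != "dnmc" else 0.0}
                if (cost_ci and state == "PD" and comp == "dmc_year2plus"
                        and arm in ("APD", None)):
                    e["ci_low"], e["ci_high"] = cost_ci
                c_entries.append(e)
    u_entries = [
        {"arm": "APD", "state": "PD",
         "value": utility if utility_apd is None else utility_apd},
        {"arm": "CAPD", "state": "PD", "value": utility},
        {"arm": None, "state": "HD", "value": utility},
        {"arm": None, "state": "KT", "value": utility},
    ]
    if utility_ci:
        u_entries[0]["ci_low"], u_entries[0]["ci_high"] = utility_ci
    return parameters_from_dict({
        "transitions": t_entries,
        "costs": c_entries,
        "utilities": u_entries,
        "mortality": {age: mortality_q for age in range(start_age, max_age + 1)},
        "discount_rate_costs": discount_costs,
        "discount_rate_outcomes": discount_outcomes,
        "start_age": start_age,
        "max_age": max_age,
    })


@pytest.fixture(scope="session")
def reference():
    """Packaged parameter fixture and its provenance manifest."""
    return load_reference_parameters()


@pytest.fixture(scope="session")
def reference_params(reference):
    return reference[0]
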