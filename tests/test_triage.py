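"""Expected-harm triage, red-flag escalation, and safety classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayestriage import (
    Evidence,
    TriageAction,
    classify_triage,
    expected_harm,
    triage_decision,
)
from bayestriage.actions import ACTIONS
from bayestriage.inference import PosteriorResult
from bayestriage.knowledge_base import kb_from_dict

from conftest import two_node_kb_dict


def posteriors(marginals):
    return PosteriorResult(
        marginals=marginals,
        method="enumeration",
        mc_std_err={d: 0.0 for d in marginals},
        evidence_log_likelihood=0.0,
    )


def toy_kb(harm_by_outcome_action, action_cost, outcome_dists, rules=()):
    """Two diseases (d1, d2), one red-flag-capable symptom s1."""
    outcomes = sorted({o for o, _ in harm_by_outcome_action})
    raw = {
        "meta": {"schema_version": 1},
        "nodes": [
            {"id": "d1", "name": "d1", "layer": "disease"},
            {"id": "d2", "name": "d2", "layer": "disease"},
            {"id": "s1", "name": "s1", "layer": "symptom"},
        ],
        "families": [
            {"child_id": "d1", "leak": 0.01, "links": []},
            {"child_id": "d2", "leak": 0.01, "links": []},
            {
                "child_id": "s1",
                "leak": 0.01,
                "links": [{"parent_id": "d1", "activation": 0.5}],
            },
        ],
        "disease_attributes": [
            {
                "disease_id": d,
                "severity_band": 1,
                "annual_incidence": 0.01,
                "outcome_distribution": outcome_dists[d],
            }
            for d in ("d1", "d2")
        ],
        "triage_rules": [
            {"rule_id": rid, "trigger": list(trig), "action": act}
            for rid, trig, act in rules
        ],
        "decision_model": {
            "outcomes": outcomes,
            "harm_cost": {
                o: {a.name: harm_by_outcome_action[(o, a)] for a in ACTIONS}
                for o in outcomes
            },
            "action_cost": {a.name: action_cost[a] for a in ACTIONS},
        },
        "display_policy": {"modes": {"mode1": [0.05]}},
    }
    return kb_from_dict(raw)


def random_toy(seed):
    rng = np.random.default_rng(seed)
    outcomes = ["o0", "o1", "o2"]
    harm = {
        (o, a): float(rng.uniform(0, 10)) for o in outcomes for a in ACTIONS
    }
    cost = dict(zip(ACTIONS, np.sort(rng.uniform(0, 3, size=6))))
    dists = {}
    for d in ("d1", "d2"):
        w = rng.dirichlet(np.ones(3))
        w = np.round(w, 9)
        w[0] += 1.0 - w.sum()
        dists[d] = dict(zip(outcomes, (float(x) for x in w)))
    return toy_kb(harm, cost, dists), harm, cost, dists


def brute_force_action(marginals, harm, cost, dists):
    """Independent six-way argmin with the documented low-urgency tie-break."""
    best, best_u = None, None
    for a in ACTIONS:  # increasing urgency; strict < keeps the first minimizer
        u = cost[a] + sum(
            p * sum(q * harm[(o, a)] for o, q in dists[d].items())
            for d, p in marginals.items()
        )
        if best_u is None or u < best_u:
            best, best_u = a, u
    return best


def test_expected_harm_zero_posteriors():
    kb, harm, cost, dists = random_toy(0)
    assert expected_harm(posteriors({"d1": 0.0, "d2": 0.0}), kb, TriageAction.ae) == 0.0


def test_expected_harm_degenerate_sums():
    harm = {(o, a): 5.0 for o in ["o0"] for a in ACTIONS}
    cost = {a: 0.0 for a in ACTIONS}
    dists = {"d1": {"o0": 1.0}, "d2": {"o0": 1.0}}
    kb = toy_kb(harm, cost, dists)
    assert expected_harm(
        posteriors({"d1": 1.0, "d2": 0.0}), kb, TriageAction.self_care
    ) == pytest.approx(5.0)


def test_expected_harm_hand_summed():
    """Two diseases at 0.3/0.2 with a tabulated toy model, summed by hand."""
    harm = {(o, a): 0.0 for o in ("o0", "o1") for a in ACTIONS}
    harm[("o1", TriageAction.self_care)] = 10.0
    harm[("o0", TriageAction.self_care)] = 1.0
    cost = {a: 0.0 for a in ACTIONS}
    dists = {"d1": {"o0": 0.6, "o1": 0.4}, "d2": {"o0": 1.0, "o1": 0.0}}
    kb = toy_kb(harm, cost, dists)
    # 0.3*(0.6*1 + 0.4*10) + 0.2*(1.0*1) = 0.3*4.6 + 0.2 = 1.58
    got = expected_harm(posteriors({"d1": 0.3, "d2": 0.2}), kb, TriageAction.self_care)
    assert got == pytest.approx(1.58, abs=1e-12)


@pytest.mark.parametrize("seed", range(25))
def test_decision_matches_brute_force_argmin(seed):
    kb, harm, cost, dists = random_toy(seed)
    rng = np.random.default_rng(seed + 500)
    marg = {"d1": float(rng.random()), "d2": float(rng.random())}
    got = triage_decision(posteriors(marg), kb, Evidence()).action
    assert got == brute_force_action(marg, harm, cost, dists)


def test_zero_harm_picks_self_care():
    harm = {(o, a): 0.0 for o in ["o0"] for a in ACTIONS}
    cost = dict(zip(ACTIONS, [0.0, 1, 2, 3, 4, 5.0]))
    kb = toy_kb(harm, cost, {"d1": {"o0": 1.0}, "d2": {"o0": 1.0}})
    t = triage_decision(posteriors({"d1": 0.5, "d2": 0.5}), kb, Evidence())
    assert t.action == TriageAction.self_care and not t.escalated


def test_tie_breaks_toward_lower_urgency():
    harm = {(o, a): 0.0 for o in ["o0"] for a in ACTIONS}
    cost = {a: 1.0 for a in ACTIONS}  # all utilities equal
    kb = toy_kb(harm, cost, {"d1": {"o0": 1.0}, "d2": {"o0": 1.0}})
    t = triage_decision(posteriors({"d1": 0.5, "d2": 0.5}), kb, Evidence())
    assert t.action == TriageAction.self_care


def test_red_flag_escalates_and_never_lowers():
    harm = {(o, a): 0.0 for o in ["o0"] for a in ACTIONS}
    cost = dict(zip(ACTIONS, [0.0, 1, 2, 3, 4, 5.0]))
    kb = toy_kb(
        harm,
        cost,
        {"d1": {"o0": 1.0}, "d2": {"o0": 1.0}},
        rules=[("rule_amb", ("s1",), "ambulance")],
    )
    t = triage_decision(posteriors({"d1": 0.5, "d2": 0.5}), kb, Evidence({"s1": True}))
    assert t.action == TriageAction.ambulance
    assert t.escalated and t.fired_rules == ("rule_amb",)
    # trigger absent: no escalation
    t2 = triage_decision(posteriors({"d1": 0.5, "d2": 0.5}), kb, Evidence({"s1": False}))
    assert t2.action == TriageAction.self_care and not t2.escalated


@pytest.mark.parametrize("seed", range(10))
def test_raising_urgent_costs_never_raises_urgency(seed):
    """Adding a strictly-increasing cost vector penalizes urgency harder and
    can only move the argmin down."""
    kb, harm, cost, dists = random_toy(seed)
    rng = np.random.default_rng(seed + 900)
    marg = {"d1": float(rng.random()), "d2": float(rng.random())}
    before = triage_decision(posteriors(marg), kb, Evidence()).action
    bump = np.cumsum(rng.uniform(0.01, 0.5, size=6))
    cost2 = {a: cost[a] + float(bump[i]) for i, a in enumerate(ACTIONS)}
    kb2 = toy_kb(harm, cost2, dists)
    after = triage_decision(posteriors(marg), kb2, Evidence()).action
    assert after <= before


@settings(max_examples=200, deadline=None)
@given(
    action=st.sampled_from(list(ACTIONS)),
    lo=st.sampled_from(list(ACTIONS)),
    hi=st.sampled_from(list(ACTIONS)),
)
def test_appropriate_implies_safe(action, lo, hi):
    if lo > hi:
        lo, hi = hi, lo
    flags = classify_triage(action, lo, hi)
    if flags["appropriate"]:
        assert flags["safe"]
    assert flags["under"] == (not flags["safe"])
    assert flags["over"] == (flags["safe"] and not flags["appropriate"])


def test_classify_boundaries():
    lo, hi = TriageAction.pharmacy, TriageAction.gp_urgent
    at_min = classify_triage(TriageAction.pharmacy, lo, hi)
    assert at_min["safe"] and at_min["appropriate"]
    above = classify_triage(TriageAction.ambulance, lo, hi)
    assert above["safe"] and not above["appropriate"] and above["over"]
    below = classify_triage(TriageAction.self_care, lo, hi)
    assert not below["safe"] and below["under"]


def test_inverted_judge_range_rejected():
    with pytest.raises(ValueError, match="inverted"):
        classify_triage(TriageAction.ae, TriageAction.ae, TriageAction.self_care)
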