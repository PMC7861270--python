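"""Expected-harm triage decisions and their safety classification.

The triage decision network extends the diagnostic Bayesian network with a
utility model.  For each candidate action *a* the expected harm is

    EH(a) = sum_d P(d | E) * sum_o P(o | d) * harm_cost(o, a)

where P(o | d) is the disease's clinical-outcome distribution.  The total
(negative) expected utility is EH(a) + action_cost(a), where the action cost
depends only on the action and is nondecreasing in urgency — this is the
over-triage penalty.  The recommended action is the argmin, with ties broken
toward the *less* urgent action (consistent with penalizing over-triage).

Red-flag rules guarantee safe handling of symptom combinations that demand
a minimum urgency regardless of cause: every rule whose full trigger set is
present in the evidence escalates the decision to at least its action's
urgency.  Escalation never lowers urgency.

Decisions are classified against a judge's acceptable range [judge_min,
judge_max]: *safe* means at-or-above the minimum urgency, *appropriate*
means within the range, hence appropriate implies safe.
"""

from __future__ import annotations

from dataclasses import dataclass

from .actions import ACTIONS, TriageAction
from .inference import Evidence, PosteriorResult
from .knowledge_base import KnowledgeBase

__all__ = [
    "TriageAction",
    "TriageAssessment",
    "classify_triage",
    "expected_harm",
    "triage_decision",
]


@dataclass(frozen=True)
class TriageAssessment:
    """Final decision with the per-action utilities and any fired red flags."""

    action: TriageAction
    expected_utilities: dict[TriageAction, float]
    fired_rules: tuple[str, ...]
    escalated: bool


def expected_harm(
    posteriors: PosteriorResult, kb: KnowledgeBase, action: TriageAction
) -> float:
    """Posterior-weighted expected harm of routing the patient to ``action``."""
    dm = kb.decision_model
    total = 0.0
    for d, p in posteriors.marginals.items():
        if p == 0.0:
            continue
        dist = kb.disease_attributes[d].outcome_distribution
        total += p * sum(
            q * dm.harm_cost[(o, action)] for o, q in dist.items()
        )
    return total


def triage_decision(
    posteriors: PosteriorResult,
    kb: KnowledgeBase,
    evidence: Evidence,
) -> TriageAssessment:
    """Minimize expected harm + over-triage cost, then apply red-flag escalation."""
    utilities = {
        a: expected_harm(posteriors, kb, a) + kb.decision_model.action_cost[a]
        for a in ACTIONS
    }
    # argmin; ACTIONS is ordered by increasing urgency and strict '<' keeps the
    # first (least urgent) minimizer, which is the documented tie-break
    utility_action = ACTIONS[0]
    for a in ACTIONS[1:]:
        if utilities[a] < utilities[utility_action]:
            utility_action = a

    present = {c for c, s in evidence.states.items() if s}
    fired = tuple(
        r.rule_id for r in kb.triage_rules if r.trigger <= present
    )
    floor = max(
        (r.action for r in kb.triage_rules if r.rule_id in fired),
        default=utility_action,
    )
    final = max(utility_action, floor)
    return TriageAssessment(
        action=final,
        expected_utilities=utilities,
        fired_rules=fired,
        escalated=final != utility_action,
    )


def classify_triage(
    action: TriageAction, judge_min: TriageAction, judge_max: TriageAction
) -> dict[str, bool]:
    """Flags {safe, appropriate, under, over} versus the judge's range."""
    if judge_min > judge_max:
        raise ValueError(
            f"inverted judge range: {judge_min.name} > {judge_max.name}"
        )
    return {
        "safe": action >= judge_min,
        "appropriate": judge_min <= action <= judge_max,
        "under": action < judge_min,
        "over": action > judge_max,
    }
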