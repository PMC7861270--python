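"""Greedy value-of-information question selection.

To decide what to ask next, each unobserved candidate concept is scored by
its expected information gain about the diseases currently under
consideration:

    gain(c) = H_now - sum_{a in {present, absent}} P(c = a | E) * H(E + {c = a})

where H is the sum of binary entropies of the top-k disease posterior
marginals (k highest-posterior diseases at the *current* evidence; the set
is frozen while evaluating a candidate, for determinism and cost), and the
predictive probability of each answer comes from the model itself via the
likelihood ratio of the extended evidence.  Summing marginal entropies
rather than using the joint entropy is a deliberate tractable approximation,
consistent with the marginal-based display of the differential.

The production criterion this emulates is not published; this gain formula
is one defensible instantiation of "ask what most confirms or rules out the
diseases under consideration".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import BayesTriageError
from .inference import Evidence, PosteriorResult, posterior
from .knowledge_base import KnowledgeBase

__all__ = ["QuestionPolicy", "expected_information_gain", "next_question"]


@dataclass(frozen=True)
class QuestionPolicy:
    """Tunables of the greedy questioner.

    top_k_diseases: entropy is computed over the k highest-posterior diseases.
    min_gain: stop when the best candidate gains fewer bits than this.
    max_questions: hard budget on directed questions per consultation.
    candidate_scope: whether risk factors may also be asked about.
    """

    top_k_diseases: int = 10
    min_gain: float = 1e-3
    max_questions: int = 30
    candidate_scope: str = "symptoms_only"  # or "symptoms_and_risk_factors"
    backend: str = "quickscore"

    def __post_init__(self):
        if self.top_k_diseases < 1 or self.max_questions < 0 or self.min_gain < 0:
            raise ValueError("policy parameters must be positive where stated")
        if self.candidate_scope not in ("symptoms_only", "symptoms_and_risk_factors"):
            raise ValueError(f"unknown candidate_scope {self.candidate_scope!r}")


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def _topk_entropy(result: PosteriorResult, top_k: set[str]) -> float:
    return sum(_binary_entropy(result.marginals[d]) for d in top_k)


def expected_information_gain(
    kb: KnowledgeBase,
    evidence: Evidence,
    candidate: str,
    policy: QuestionPolicy = QuestionPolicy(),
    *,
    current: PosteriorResult | None = None,
) -> float:
    """Expected reduction (bits) in top-k disease entropy from asking ``candidate``.

    ``current`` may pass a precomputed posterior for the present evidence to
    avoid recomputation.  Always >= 0 (clamped; exact arithmetic can dip a
    hair below zero).  Raises if the candidate is already observed.
    """
    if evidence.is_observed(candidate):
        raise BayesTriageError(f"candidate {candidate!r} is already observed")
    if current is None:
        current = posterior(kb, evidence, policy.backend)
    top_k = {d for d, _ in current.top(policy.top_k_diseases)}
    h_now = _topk_entropy(current, top_k)

    expected_after = 0.0
    p_remaining = 1.0
    for answer in (True, False):
        branch = evidence.with_observation(candidate, answer)
        try:
            post = posterior(kb, branch, policy.backend)
        except BayesTriageError:
            continue  # impossible answer: predictive probability is zero
        # P(candidate = answer | E) from the evidence-likelihood ratio
        p_answer = math.exp(
            post.evidence_log_likelihood - current.evidence_log_likelihood
        )
        p_answer = min(p_answer, p_remaining)
        p_remaining -= p_answer
        expected_after += p_answer * _topk_entropy(post, top_k)
    return max(0.0, h_now - expected_after)


def next_question(
    kb: KnowledgeBase,
    evidence: Evidence,
    policy: QuestionPolicy = QuestionPolicy(),
    exclude: set[str] | None = None,
) -> str | None:
    """The unobserved candidate with maximal expected information gain.

    Returns None when no candidate reaches ``policy.min_gain``.  Ties break
    to the lexicographically smallest concept id, so the choice is a
    deterministic function of (kb, evidence, policy).  ``exclude`` drops
    candidates already asked (needed when unanswered questions leave no
    trace in the evidence).
    """
    exclude = exclude or set()
    candidates = [
        s for s in kb.symptoms if not evidence.is_observed(s) and s not in exclude
    ]
    if policy.candidate_scope == "symptoms_and_risk_factors":
        candidates += [
            r for r in kb.risk_factors if not evidence.is_observed(r) and r not in exclude
        ]
    if not candidates:
        return None
    current = posterior(kb, evidence, policy.backend)
    best_id, best_gain = None, -1.0
    for cand in sorted(candidates):
        gain = expected_information_gain(kb, evidence, cand, policy, current=current)
        if gain > best_gain + 1e-12:
            best_id, best_gain = cand, gain
    if best_gain < policy.min_gain:
        return None
    return best_id
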