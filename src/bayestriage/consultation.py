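"""OSCE-style simulated consultations.

A vignette scripts a single-condition patient the way standardized
role-play cases do: demographics, a presenting complaint volunteered up
front, facts offered on open questioning, and facts revealed only when
directly asked.  ``run_consultation`` drives the engine against such a
patient: seed evidence with the presenting facts and demographics, take the
one open-questioning disclosure, then loop value-of-information questions
until the stop rule (gain threshold or budget), and finish with the
displayed differential and the triage decision.

Facts the vignette does not list are answered "absent" by default — the
role-player's script is taken as complete.  Setting ``default_answer`` to
"unknown" instead leaves unlisted queried concepts unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .actions import TriageAction
from .differential import Differential, build_differential
from .errors import EvidenceError, SchemaError
from .inference import Evidence, posterior
from .knowledge_base import KnowledgeBase
from .question_selection import QuestionPolicy, next_question
from .triage import TriageAssessment, triage_decision

__all__ = [
    "Vignette",
    "ConsultationRecord",
    "demographic_evidence",
    "load_vignette",
    "save_vignette",
    "patient_answer",
    "run_consultation",
]

MIN_AGE = 16


@dataclass(frozen=True)
class Vignette:
    """A scripted single-condition patient with tiered fact disclosure."""

    id: str
    age: int
    sex: str
    modeled_disease: str
    presenting: dict[str, bool]
    open_facts: dict[str, bool]
    direct_facts: dict[str, bool]
    judge_min: TriageAction
    judge_max: TriageAction
    annual_incidence: float = 1.0

    def __post_init__(self):
        if self.age < MIN_AGE:
            raise ValueError(f"vignette age {self.age} below minimum of {MIN_AGE}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"vignette sex must be female or male, got {self.sex!r}")
        tiers = [set(self.presenting), set(self.open_facts), set(self.direct_facts)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = tiers[i] & tiers[j]
                if overlap:
                    raise ValueError(
                        f"fact tiers must be disjoint; {sorted(overlap)} appear twice"
                    )
        if self.judge_min > self.judge_max:
            raise ValueError("judge_min urgency exceeds judge_max")

    def all_facts(self) -> dict[str, bool]:
        return {**self.presenting, **self.open_facts, **self.direct_facts}


@dataclass(frozen=True)
class ConsultationRecord:
    vignette_id: str
    question_trail: tuple[tuple[str, bool | None], ...]
    final_evidence: Evidence
    differential: Differential
    triage: TriageAssessment
    n_questions: int = field(default=0)


def demographic_evidence(kb: KnowledgeBase, age: int, sex: str) -> dict[str, bool]:
    """Deterministic states of all demographic-tagged risk factors.

    Age nodes carry ``{"kind": "age", "min": a, "max": b}`` (either bound may
    be omitted); sex nodes ``{"kind": "sex", "value": "female"|"male"}``.
    """
    states: dict[str, bool] = {}
    for rid in kb.risk_factors:
        demo = kb.nodes[rid].demographic
        if not demo:
            continue
        kind = demo.get("kind")
        if kind == "age":
            lo = demo.get("min", 0)
            hi = demo.get("max")
            states[rid] = age >= lo and (hi is None or age <= hi)
        elif kind == "sex":
            states[rid] = sex == demo.get("value")
    return states


def patient_answer(
    vignette: Vignette,
    query: str,
    kb: KnowledgeBase,
    default_answer: str = "absent",
) -> bool | None:
    """Answer one directed question from the vignette script.

    Returns the scripted state if the concept is in any fact tier, the
    demographic mapping for age/sex risk factors, otherwise the default
    convention: False ("absent", the standard OSCE reading of a complete
    script) or None ("unknown")."""
    if query not in kb.nodes:
        raise EvidenceError(f"query {query!r} is not a concept of this knowledge base")
    facts = vignette.all_facts()
    if query in facts:
        return facts[query]
    demo = demographic_evidence(kb, vignette.age, vignette.sex)
    if query in demo:
        return demo[query]
    return False if default_answer == "absent" else None


def run_consultation(
    kb: KnowledgeBase,
    vignette: Vignette,
    question_policy: QuestionPolicy = QuestionPolicy(),
    mode_id: str = "mode1",
    default_answer: str = "absent",
) -> ConsultationRecord:
    """Simulate one full consultation; deterministic given its inputs."""
    for cid in vignette.all_facts():
        if cid not in kb.nodes:
            raise EvidenceError(
                f"vignette {vignette.id!r} references unknown concept {cid!r}"
            )

    states: dict[str, bool] = {}
    states.update(demographic_evidence(kb, vignette.age, vignette.sex))
    states.update(vignette.presenting)
    # single open-questioning disclosure before any directed question
    states.update(vignette.open_facts)
    evidence = Evidence(dict(states))

    trail: list[tuple[str, bool | None]] = []
    asked: set[str] = set()
    n_questions = 0
    while n_questions < question_policy.max_questions:
        query = next_question(kb, evidence, question_policy, exclude=asked)
        if query is None:
            break
        answer = patient_answer(vignette, query, kb, default_answer)
        trail.append((query, answer))
        asked.add(query)
        n_questions += 1
        if answer is not None:
            evidence = evidence.with_observation(query, answer)

    post = posterior(kb, evidence, question_policy.backend)
    diff = build_differential(post, kb, mode_id)
    tri = triage_decision(post, kb, evidence)
    return ConsultationRecord(
        vignette_id=vignette.id,
        question_trail=tuple(trail),
        final_evidence=evidence,
        differential=diff,
        triage=tri,
        n_questions=n_questions,
    )


# -----------------------------------------------------------------------------
# vignette files (YAML, one vignette per document)
# -----------------------------------------------------------------------------

_STATE = {"present": True, "absent": False}
_STATE_NAME = {True: "present", False: "absent"}


def _facts_from(raw: Mapping, key: str, path: str) -> dict[str, bool]:
    out = {}
    for cid, state in (raw.get(key) or {}).items():
        if state not in _STATE:
            raise SchemaError(f"{path}.{key}.{cid}", f"state must be present/absent, got {state!r}")
        out[str(cid)] = _STATE[state]
    return out


def vignette_from_dict(raw: Mapping) -> Vignette:
    vid = str(raw.get("id", ""))
    if not vid:
        raise SchemaError("id", "missing vignette id")
    path = f"vignette.{vid}"
    judge = raw.get("judge_range") or {}
    try:
        return Vignette(
            id=vid,
            age=int(raw["age"]),
            sex=str(raw["sex"]),
            modeled_disease=str(raw["modeled_disease"]),
            presenting=_facts_from(raw, "presenting", path),
            open_facts=_facts_from(raw, "open_facts", path),
            direct_facts=_facts_from(raw, "direct_facts", path),
            judge_min=TriageAction.from_name(judge["min"]),
            judge_max=TriageAction.from_name(judge["max"]),
            annual_incidence=float(raw.get("annual_incidence", 1.0)),
        )
    except KeyError as e:
        raise SchemaError(f"{path}.{e.args[0]}", "missing required field") from None
    except ValueError as e:
        raise SchemaError(path, str(e)) from None


def vignette_to_dict(v: Vignette) -> dict:
    return {
        "id": v.id,
        "age": v.age,
        "sex": v.sex,
        "modeled_disease": v.modeled_disease,
        "presenting": {c: _STATE_NAME[s] for c, s in sorted(v.presenting.items())},
        "open_facts": {c: _STATE_NAME[s] for c, s in sorted(v.open_facts.items())},
        "direct_facts": {c: _STATE_NAME[s] for c, s in sorted(v.direct_facts.items())},
        "judge_range": {"min": v.judge_min.name, "max": v.judge_max.name},
        "annual_incidence": v.annual_incidence,
    }


def load_vignette(path: str | Path) -> Vignette:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise SchemaError("$", "vignette file must contain a mapping")
    return vignette_from_dict(raw)


def save_vignette(v: Vignette, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(vignette_to_dict(v), sort_keys=False))
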