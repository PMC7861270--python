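"""Synthetic knowledge bases and closed-loop vignettes.

No deposited knowledge base or vignette set exists for this kind of system,
so everything downstream is exercised against synthetic data drawn from the
model family itself: ``generate_kb`` samples a structured three-layer
noisy-OR network with epidemiology-scale disease baselines, and
``generate_vignette`` samples a scripted patient *from that KB's own
generative model* — risk factors from their priors, the modeled disease
forced present, symptoms from their noisy-OR CPTs — so the engine can be
evaluated closed-loop against ground truth it should be able to recover.

The synthetic judge (:func:`oracle_judge_range`) stands in for the human
judges of a real study: it runs the triage decision model with the true
disease's posterior clamped to 1 and full disclosure, and widens the
resulting action upward by a configurable number of urgency steps.  It is
explicitly a closed-loop testing construct, not a model of clinical
judgement.

All generation is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .actions import ACTIONS, TriageAction
from .consultation import Vignette, demographic_evidence
from .errors import InvariantError
from .inference import Evidence, PosteriorResult, posterior_quickscore
from .knowledge_base import (
    ConceptNode,
    DecisionModel,
    DiseaseAttributes,
    DisplayPolicy,
    KnowledgeBase,
    NoisyOrFamily,
    NoisyOrLink,
    TriageRule,
    cpt_entry,
    validate_kb,
)
from .triage import triage_decision

__all__ = [
    "SynthConfig",
    "generate_kb",
    "generate_vignette",
    "generate_vignettes",
    "oracle_judge_range",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shape and parameter ranges of a generated knowledge base.

    Disease baselines default to [1e-5, 1e-2] per person-year, sampled
    log-uniformly — the scale of real annual disease incidences, so that
    posteriors behave like those of a diagnostic network rather than a toy
    with coin-flip priors.  Edge densities and activation ranges give each
    disease a handful of moderately reliable symptoms, the regime in which
    questioning is informative but single findings are rarely conclusive.
    """

    n_risk_factors: int = 6
    n_diseases: int = 10
    n_symptoms: int = 24
    p_edge_rf_d: float = 0.3
    p_edge_d_s: float = 0.25
    rf_prior_range: tuple[float, float] = (0.02, 0.3)
    disease_prior_range: tuple[float, float] = (1e-5, 1e-2)
    lambda_rf_d_range: tuple[float, float] = (0.5, 0.95)
    lambda_d_s_range: tuple[float, float] = (0.2, 0.95)
    symptom_leak_range: tuple[float, float] = (1e-4, 0.02)
    n_severity_bands: int = 5
    n_outcomes: int = 4
    include_demographics: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_risk_factors", "n_diseases", "n_symptoms",
                     "n_severity_bands", "n_outcomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("rf_prior_range", "disease_prior_range", "lambda_rf_d_range",
                     "lambda_d_s_range", "symptom_leak_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an interval within [0, 1]")
        if self.p_edge_d_s == 0.0:
            raise ValueError(
                "p_edge_d_s = 0 cannot satisfy the every-disease-has-a-symptom "
                "constraint"
            )


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_kb(config: SynthConfig = SynthConfig()) -> KnowledgeBase:
    """Sample a valid three-layer KB; byte-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    S = config.n_severity_bands
    K = config.n_outcomes

    nodes: dict[str, ConceptNode] = {}
    rf_ids = [f"rf_{i:02d}" for i in range(config.n_risk_factors)]
    d_ids = [f"d_{i:02d}" for i in range(config.n_diseases)]
    s_ids = [f"s_{i:02d}" for i in range(config.n_symptoms)]

    demo: dict[str, dict] = {}
    if config.include_demographics and config.n_risk_factors >= 2:
        demo[rf_ids[0]] = {"kind": "age", "min": 65}
        demo[rf_ids[1]] = {"kind": "sex", "value": "female"}

    families: dict[str, NoisyOrFamily] = {}
    for rid in rf_ids:
        nodes[rid] = ConceptNode(
            id=rid, name=rid.replace("_", " "), layer="risk_factor",
            demographic=demo.get(rid),
        )
        if demo.get(rid, {}).get("kind") == "sex":
            prior = 0.5
        elif demo.get(rid, {}).get("kind") == "age":
            prior = 0.25
        else:
            prior = float(rng.uniform(*config.rf_prior_range))
        families[rid] = NoisyOrFamily(child_id=rid, leak=prior)

    severities = rng.integers(1, S + 1, size=config.n_diseases)
    for j, did in enumerate(d_ids):
        nodes[did] = ConceptNode(id=did, name=did.replace("_", " "), layer="disease")
        links = []
        for rid in rf_ids:
            if rng.random() < config.p_edge_rf_d:
                links.append(
                    NoisyOrLink(rid, float(rng.uniform(*config.lambda_rf_d_range)))
                )
        families[did] = NoisyOrFamily(
            child_id=did,
            leak=float(_loguniform(rng, *config.disease_prior_range)),
            links=tuple(links),
        )

    # disease -> symptom adjacency; every disease needs at least one child
    adj = rng.random((config.n_diseases, config.n_symptoms)) < config.p_edge_d_s
    for j in range(config.n_diseases):
        if not adj[j].any():
            adj[j, rng.integers(config.n_symptoms)] = True
    for i, sid in enumerate(s_ids):
        nodes[sid] = ConceptNode(id=sid, name=sid.replace("_", " "), layer="symptom")
        links = tuple(
            NoisyOrLink(d_ids[j], float(rng.uniform(*config.lambda_d_s_range)))
            for j in range(config.n_diseases)
            if adj[j, i]
        )
        families[sid] = NoisyOrFamily(
            child_id=sid,
            leak=float(_loguniform(rng, *config.symptom_leak_range)),
            links=links,
        )

    # outcome distributions concentrate on worse outcomes for severer bands
    outcomes = tuple(f"outcome_{k}" for k in range(K))
    disease_attributes: dict[str, DiseaseAttributes] = {}
    for j, did in enumerate(d_ids):
        sev = int(severities[j])
        peak = (sev - 1) / max(S - 1, 1) * (K - 1)
        alpha = 0.4 + 3.0 * np.exp(-0.5 * (np.arange(K) - peak) ** 2)
        dist = rng.dirichlet(alpha)
        dist = dist / dist.sum()
        disease_attributes[did] = DiseaseAttributes(
            disease_id=did,
            severity_band=sev,
            annual_incidence=families[did].leak,
            outcome_distribution={
                o: float(p) for o, p in zip(outcomes, np.round(dist, 12))
            },
        )
    # re-normalize rounding drift exactly
    for did, attrs in disease_attributes.items():
        total = sum(attrs.outcome_distribution.values())
        first = outcomes[0]
        fixed = dict(attrs.outcome_distribution)
        fixed[first] = fixed[first] + (1.0 - total)
        disease_attributes[did] = replace(attrs, outcome_distribution=fixed)

    # harm grows geometrically with outcome badness; urgent care mitigates it
    base_harm = np.concatenate([[0.0], 2.0 * 4.0 ** np.arange(K - 1)])
    mitigation = np.array([0.0, 0.15, 0.35, 0.6, 0.8, 0.95])
    harm_cost = {
        (o, a): float(base_harm[k] * (1.0 - mitigation[a - 1]))
        for k, o in enumerate(outcomes)
        for a in ACTIONS
    }
    action_cost = {
        a: c for a, c in zip(ACTIONS, [0.0, 0.02, 0.06, 0.15, 0.45, 1.2])
    }
    decision_model = DecisionModel(
        outcomes=outcomes, harm_cost=harm_cost, action_cost=action_cost
    )

    # red flags: one strongly linked symptom of each most-severe disease
    rules = []
    for j, did in enumerate(d_ids):
        if severities[j] == S and len(rules) < 2:
            children = [
                (sid, families[sid].activation_of(did))
                for sid in s_ids
                if did in families[sid].parent_ids
            ]
            sid = max(children, key=lambda e: (e[1], e[0]))[0]
            rules.append(
                TriageRule(
                    rule_id=f"redflag_{len(rules)}",
                    trigger=frozenset({sid}),
                    action=TriageAction.ae if len(rules) == 0 else TriageAction.ambulance,
                )
            )

    # display floors fall with severity; mode2 trades recall for precision
    mode1 = tuple(float(t) for t in np.geomspace(0.05, 0.005, S))
    mode2 = tuple(min(0.999, 3.0 * t) for t in mode1)
    display_policy = DisplayPolicy(modes={"mode1": mode1, "mode2": mode2})

    kb = KnowledgeBase(
        nodes=nodes,
        disease_attributes=disease_attributes,
        families=families,
        triage_rules=tuple(rules),
        decision_model=decision_model,
        display_policy=display_policy,
        meta={"schema_version": 1, "generator": "synthetic", "seed": config.seed},
    )
    errors = [d for d in validate_kb(kb) if d.startswith("error:")]
    if errors:  # pragma: no cover - generator bug guard
        raise InvariantError("generated KB invalid:\n" + "\n".join(errors))
    return kb


def oracle_judge_range(
    kb: KnowledgeBase,
    vignette: Vignette,
    width: int = 1,
) -> tuple[TriageAction, TriageAction]:
    """Synthetic judge: triage under full disclosure with the true disease certain.

    Computes the decision-model action with the vignette's complete evidence
    and the modeled disease's posterior clamped to 1, then widens the range
    one step upward (``width`` steps, clamped at the urgency ceiling).
    """
    states = demographic_evidence(kb, vignette.age, vignette.sex)
    states.update(vignette.all_facts())
    evidence = Evidence(states)
    post = posterior_quickscore(kb, evidence)
    clamped = PosteriorResult(
        marginals={**post.marginals, vignette.modeled_disease: 1.0},
        method=post.method,
        mc_std_err=post.mc_std_err,
        evidence_log_likelihood=post.evidence_log_likelihood,
    )
    action = triage_decision(clamped, kb, evidence).action
    judge_max = TriageAction(min(int(action) + width, int(TriageAction.ambulance)))
    return action, judge_max


def generate_vignette(
    kb: KnowledgeBase,
    disease_id: str | None = None,
    seed: int = 0,
    disclosure_split: tuple[float, float, float] = (0.3, 0.4, 0.3),
    *,
    suppress_codiseases: bool = True,
    judge_width: int = 1,
) -> Vignette:
    """Sample one vignette from the KB's generative model.

    Risk factors are drawn from their priors (demographic nodes from a
    sampled age/sex), the modeled disease is forced present, incidental
    co-diseases are suppressed by default (the single-condition study
    design; enable them for robustness testing), and symptoms are drawn
    from their noisy-OR CPTs.  Present symptoms are split into
    presenting/open/direct tiers with the given probabilities; present
    non-demographic risk factors (past medical history) go to the open or
    direct tier.  The judge range comes from :func:`oracle_judge_range`.
    """
    if abs(sum(disclosure_split) - 1.0) > 1e-9:
        raise ValueError("disclosure_split must sum to 1")
    rng = np.random.default_rng(seed)

    if disease_id is None:
        disease_id = kb.diseases[rng.integers(len(kb.diseases))]
    if not any(disease_id in kb.families[s].parent_ids for s in kb.symptoms):
        raise InvariantError(
            f"disease {disease_id!r} has no symptom children; its vignettes "
            "would be unobservable"
        )

    age = int(rng.integers(16, 91))
    sex = "female" if rng.random() < 0.5 else "male"
    demo_states = demographic_evidence(kb, age, sex)

    rf_states: dict[str, bool] = {}
    for rid in kb.risk_factors:
        if rid in demo_states:
            rf_states[rid] = demo_states[rid]
        else:
            rf_states[rid] = bool(rng.random() < kb.families[rid].leak)

    d_states: dict[str, bool] = {}
    for did in kb.diseases:
        if did == disease_id:
            d_states[did] = True
        elif suppress_codiseases:
            d_states[did] = False
        else:
            d_states[did] = bool(rng.random() < cpt_entry(kb.families[did], rf_states))

    s_states = {
        sid: bool(rng.random() < cpt_entry(kb.families[sid], d_states))
        for sid in kb.symptoms
    }

    present_symptoms = sorted(s for s, st in s_states.items() if st)
    tiers: dict[str, dict[str, bool]] = {"presenting": {}, "open": {}, "direct": {}}
    names = ("presenting", "open", "direct")
    for sid in present_symptoms:
        tier = names[rng.choice(3, p=disclosure_split)]
        tiers[tier][sid] = True
    # a consultation needs a presenting complaint if anything is present
    if present_symptoms and not tiers["presenting"]:
        donor = "open" if tiers["open"] else "direct"
        moved = sorted(tiers[donor])[0]
        del tiers[donor][moved]
        tiers["presenting"][moved] = True

    p_open, p_direct = disclosure_split[1], disclosure_split[2]
    denom = p_open + p_direct
    p_open_rf = 0.5 if denom == 0 else p_open / denom
    for rid in sorted(r for r, st in rf_states.items() if st and r not in demo_states):
        tier = "open" if rng.random() < p_open_rf else "direct"
        tiers[tier][rid] = True

    provisional = Vignette(
        id=f"v_{disease_id}_{seed}",
        age=age,
        sex=sex,
        modeled_disease=disease_id,
        presenting=tiers["presenting"],
        open_facts=tiers["open"],
        direct_facts=tiers["direct"],
        judge_min=TriageAction.self_care,
        judge_max=TriageAction.ambulance,
        annual_incidence=kb.disease_attributes[disease_id].annual_incidence,
    )
    judge_min, judge_max = oracle_judge_range(kb, provisional, judge_width)
    return replace(provisional, judge_min=judge_min, judge_max=judge_max)


def generate_vignettes(
    kb: KnowledgeBase,
    n: int,
    seed: int = 0,
    disclosure_split: tuple[float, float, float] = (0.3, 0.4, 0.3),
    **kwargs,
) -> list[Vignette]:
    """n vignettes with modeled diseases cycling uniformly over the KB.

    Uniform coverage (rather than incidence-weighted sampling) mirrors a
    vignette study's deliberate mix of common and rare conditions; incidence
    reweighting at evaluation time undoes it when a real-world case mix is
    wanted.
    """
    diseases = kb.diseases
    out = []
    for i in range(n):
        out.append(
            generate_vignette(
                kb,
                diseases[i % len(diseases)],
                seed=seed * 1_000_003 % (2**31) + i,
                disclosure_split=disclosure_split,
                **kwargs,
            )
        )
    return out
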