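"""Shared fixtures: hand-built toy networks and random network factories."""

from __future__ import annotations

import numpy as np
import pytest

from bayestriage import SynthConfig, generate_kb
from bayestriage.actions import ACTIONS
from bayestriage.knowledge_base import KnowledgeBase, kb_from_dict


def _flat_decision_model(outcomes=("o_benign", "o_severe")):
    return {
        "outcomes": list(outcomes),
        "harm_cost": {
            o: {a.name: 0.0 for a in ACTIONS} for o in outcomes
        },
        "action_cost": {a.name: float(i) * 0.1 for i, a in enumerate(ACTIONS)},
    }


def two_node_kb_dict(prior=0.01, lam=0.9, leak=0.01) -> dict:
    """One disease with a baseline prior and one symptom: the closed-form net."""
    return {
        "meta": {"schema_version": 1},
        "nodes": [
            {"id": "d1", "name": "disease", "layer": "disease"},
            {"id": "s1", "name": "symptom", "layer": "symptom"},
        ],
        "families": [
            {"child_id": "d1", "leak": prior, "links": []},
            {
                "child_id": "s1",
                "leak": leak,
                "links": [{"parent_id": "d1", "activation": lam}],
            },
        ],
        "disease_attributes": [
            {
                "disease_id": "d1",
                "severity_band": 1,
                "annual_incidence": prior,
                "outcome_distribution": {"o_benign": 0.9, "o_severe": 0.1},
            }
        ],
        "triage_rules": [],
        "decision_model": _flat_decision_model(),
        "display_policy": {"modes": {"mode1": [0.05]}},
    }


@pytest.fixture
def two_node_kb() -> KnowledgeBase:
    return kb_from_dict(two_node_kb_dict())


@pytest.fixture
def explaining_away_kb() -> KnowledgeBase:
    """Two diseases share symptom s_shared; d1 also has private symptom s_d1."""
    return kb_from_dict(
        {
            "meta": {"schema_version": 1},
            "nodes": [
                {"id": "d1", "name": "d1", "layer": "disease"},
                {"id": "d2", "name": "d2", "layer": "disease"},
                {"id": "s_shared", "name": "shared", "layer": "symptom"},
                {"id": "s_d1", "name": "private", "layer": "symptom"},
            ],
            "families": [
                {"child_id": "d1", "leak": 0.02, "links": []},
                {"child_id": "d2", "leak": 0.02, "links": []},
                {
                    "child_id": "s_shared",
                    "leak": 0.001,
                    "links": [
                        {"parent_id": "d1", "activation": 0.8},
                        {"parent_id": "d2", "activation": 0.8},
                    ],
                },
                {
                    "child_id": "s_d1",
                    "leak": 0.001,
                    "links": [{"parent_id": "d1", "activation": 0.95}],
                },
            ],
            "disease_attributes": [
                {
                    "disease_id": d,
                    "severity_band": 1,
                    "annual_incidence": 0.02,
                    "outcome_distribution": {"o_benign": 1.0, "o_severe": 0.0},
                }
                for d in ("d1", "d2")
            ],
            "triage_rules": [],
            "decision_model": _flat_decision_model(),
            "display_policy": {"modes": {"mode1": [0.01]}},
        }
    )


def random_small_kb(seed: int) -> KnowledgeBase:
    """Random network within the exact-inference comfort zone (<=6/<=8/<=12)."""
    rng = np.random.default_rng(seed)
    cfg = SynthConfig(
        n_risk_factors=int(rng.integers(1, 7)),
        n_diseases=int(rng.integers(2, 9)),
        n_symptoms=int(rng.integers(3, 13)),
        p_edge_rf_d=float(rng.uniform(0.2, 0.6)),
        p_edge_d_s=float(rng.uniform(0.2, 0.6)),
        disease_prior_range=(1e-4, 0.05),
        include_demographics=bool(rng.random() < 0.5),
        seed=int(rng.integers(2**31)),
    )
    return generate_kb(cfg)


def random_evidence(kb: KnowledgeBase, seed: int) -> dict[str, bool]:
    """Random partial present/absent assignment on risk factors and symptoms."""
    rng = np.random.default_rng(seed)
    states: dict[str, bool] = {}
    for cid in kb.risk_factors + kb.symptoms:
        u = rng.random()
        if u < 0.25:
            states[cid] = True
        elif u < 0.5:
            states[cid] = False
    return states


@pytest.fixture(scope="session")
def synth_kb() -> KnowledgeBase:
    """The default-condition synthetic knowledge base used across modules."""
    return generate_kb(SynthConfig(seed=0))
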