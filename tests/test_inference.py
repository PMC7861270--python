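"""Posterior inference: closed forms, backend agreement, stability."""

import math

import numpy as np
import pytest

from bayestriage import (
    Evidence,
    posterior,
    posterior_enumeration,
    posterior_quickscore,
    posterior_sampling,
)
from bayestriage.errors import EvidenceError, InferenceError
from bayestriage.knowledge_base import kb_from_dict

from conftest import random_evidence, random_small_kb, two_node_kb_dict


def closed_form_posterior(prior, lam, leak, present):
    """Independent Bayes oracle for the one-disease one-symptom network."""
    p_s_given_d = 1 - (1 - leak) * (1 - lam)
    if present:
        num = prior * p_s_given_d
        den = num + (1 - prior) * leak
    else:
        num = prior * (1 - p_s_given_d)
        den = num + (1 - prior) * (1 - leak)
    return num / den


@pytest.mark.parametrize("backend", [posterior_enumeration, posterior_quickscore])
def test_two_node_closed_form(two_node_kb, backend):
    res = backend(two_node_kb, Evidence({"s1": True}))
    assert res.marginals["d1"] == pytest.approx(
        closed_form_posterior(0.01, 0.9, 0.01, True), abs=1e-12
    )
    assert res.marginals["d1"] == pytest.approx(0.4765, abs=5e-5)
    assert res.mc_std_err["d1"] == 0.0


def test_negative_evidence_lowers_posterior(two_node_kb):
    res = posterior_enumeration(two_node_kb, Evidence({"s1": False}))
    assert res.marginals["d1"] < 0.01
    assert res.marginals["d1"] == pytest.approx(
        closed_form_posterior(0.01, 0.9, 0.01, False), abs=1e-12
    )


def test_empty_evidence_recovers_priors(two_node_kb, synth_kb):
    assert (
        posterior_enumeration(two_node_kb, Evidence()).marginals["d1"]
        == pytest.approx(0.01, abs=1e-12)
    )
    # on the full synthetic KB, quickscore's empty-evidence marginals equal
    # the enumeration prior marginals to near machine precision
    pe = posterior_enumeration(synth_kb, Evidence())
    pq = posterior_quickscore(synth_kb, Evidence())
    for d in synth_kb.diseases:
        assert pq.marginals[d] == pytest.approx(pe.marginals[d], abs=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_quickscore_matches_enumeration_on_random_networks(seed):
    kb = random_small_kb(seed)
    ev = Evidence(random_evidence(kb, seed + 10_000))
    pe = posterior_enumeration(kb, ev)
    pq = posterior_quickscore(kb, ev)
    for d in kb.diseases:
        assert abs(pe.marginals[d] - pq.marginals[d]) < 1e-9
    assert pq.evidence_log_likelihood == pytest.approx(
        pe.evidence_log_likelihood, abs=1e-9
    )


def test_quickscore_no_present_findings_matches_enumeration(synth_kb):
    ev = Evidence({s: False for s in synth_kb.symptoms[:5]})
    pe = posterior_enumeration(synth_kb, ev)
    pq = posterior_quickscore(synth_kb, ev)
    for d in synth_kb.diseases:
        assert abs(pe.marginals[d] - pq.marginals[d]) < 1e-9


def test_single_parent_monotonicity(two_node_kb):
    prior = posterior_enumeration(two_node_kb, Evidence()).marginals["d1"]
    up = posterior_enumeration(two_node_kb, Evidence({"s1": True})).marginals["d1"]
    down = posterior_enumeration(two_node_kb, Evidence({"s1": False})).marginals["d1"]
    assert down < prior < up


def test_explaining_away(explaining_away_kb):
    """Independent evidence for d1 lowers d2's posterior given a shared finding."""
    kb = explaining_away_kb
    base = posterior_enumeration(kb, Evidence({"s_shared": True}))
    more = posterior_enumeration(kb, Evidence({"s_shared": True, "s_d1": True}))
    assert more.marginals["d1"] > base.marginals["d1"]
    assert more.marginals["d2"] < base.marginals["d2"]
    # quickscore reproduces both
    for ev in ({"s_shared": True}, {"s_shared": True, "s_d1": True}):
        pq = posterior_quickscore(kb, Evidence(ev))
        pe = posterior_enumeration(kb, Evidence(ev))
        for d in kb.diseases:
            assert abs(pq.marginals[d] - pe.marginals[d]) < 1e-12


def test_many_tiny_negative_findings_stay_finite():
    """50 absent findings with leak 1e-6 must not underflow or drift."""
    n = 50
    raw = two_node_kb_dict()
    raw["nodes"] += [
        {"id": f"neg_{i:02d}", "name": f"neg {i}", "layer": "symptom"}
        for i in range(n)
    ]
    raw["families"] += [
        {
            "child_id": f"neg_{i:02d}",
            "leak": 1e-6,
            "links": [{"parent_id": "d1", "activation": 0.3}],
        }
        for i in range(n)
    ]
    kb = kb_from_dict(raw)
    ev = Evidence({f"neg_{i:02d}": False for i in range(n)} | {"s1": True})
    pe = posterior_enumeration(kb, ev)
    pq = posterior_quickscore(kb, ev)
    assert math.isfinite(pe.evidence_log_likelihood)
    assert abs(pe.marginals["d1"] - pq.marginals["d1"]) < 1e-9
    # 50 independent 0.7 survival factors shrink d1's odds by 0.7^50
    assert 0.0 < pe.marginals["d1"] < 1e-6


def test_sampling_deterministic_and_consistent(two_node_kb):
    a = posterior_sampling(two_node_kb, Evidence({"s1": True}), 20_000, seed=42)
    b = posterior_sampling(two_node_kb, Evidence({"s1": True}), 20_000, seed=42)
    assert a.marginals == b.marginals
    assert a.method == "sampling" and a.mc_std_err["d1"] > 0


def test_sampling_within_three_se_of_closed_form(two_node_kb):
    res = posterior_sampling(two_node_kb, Evidence({"s1": True}), 200_000, seed=7)
    truth = closed_form_posterior(0.01, 0.9, 0.01, True)
    assert abs(res.marginals["d1"] - truth) <= 3 * res.mc_std_err["d1"]


def test_impossible_evidence_raises():
    raw = two_node_kb_dict(prior=0.5, lam=1.0, leak=0.0)
    kb = kb_from_dict(raw)
    ev = Evidence({"d1": True, "s1": False})
    with pytest.raises(InferenceError, match="s1"):
        posterior_sampling(kb, ev, 1000, seed=0, allow_disease_override=True)
    with pytest.raises(InferenceError):
        posterior_enumeration(kb, ev, allow_disease_override=True)


def test_disease_evidence_requires_override_flag(two_node_kb):
    with pytest.raises(EvidenceError, match="override"):
        posterior_enumeration(two_node_kb, Evidence({"d1": True}))
    res = posterior_enumeration(
        two_node_kb, Evidence({"d1": True}), allow_disease_override=True
    )
    assert res.marginals["d1"] == 1.0


def test_enumeration_cap_suggests_sampling():
    kb = random_small_kb(3)
    with pytest.raises(InferenceError, match="sampling"):
        posterior_enumeration(kb, Evidence(), max_unobserved=1)


def test_quickscore_present_cap_suggests_sampling(synth_kb):
    ev = Evidence({s: True for s in synth_kb.symptoms[:4]})
    with pytest.raises(InferenceError, match="sampling"):
        posterior_quickscore(synth_kb, ev, max_present=3)


def test_auto_backend_falls_back_to_sampling(synth_kb):
    ev = Evidence({synth_kb.symptoms[0]: True})
    assert posterior(synth_kb, ev, "auto").method == "quickscore"


def test_overridden_disease_agrees_across_exact_backends(explaining_away_kb):
    ev = Evidence({"s_shared": True, "d1": True})
    pe = posterior_enumeration(explaining_away_kb, ev, allow_disease_override=True)
    pq = posterior_quickscore(explaining_away_kb, ev, allow_disease_override=True)
    for d in explaining_away_kb.diseases:
        assert abs(pe.marginals[d] - pq.marginals[d]) < 1e-12
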