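"""Study metrics: recall/precision/F1, pooling, ratings, sweeps, reweighting.

The fixed numeric identities asserted here are the arithmetic relationships
between published per-agent precision/recall/F1 and pooled-average values in
the vignette study this harness mirrors; they pin down the aggregation
conventions (aggregate F1 as harmonic mean of aggregate P and R, pooled rows
as unweighted means of per-agent cells, one-decimal display rounding).
"""

import numpy as np
import pytest

from bayestriage import (
    EvalCase,
    EvalReport,
    TriageAction,
    aggregate,
    case_precision,
    case_recall,
    cases_from_csv,
    f1_score,
    generate_kb,
    generate_vignettes,
    pool_agents,
    pr_sweep,
    rate_okay_or_better,
)
from bayestriage.evaluation import round1


def case(differential, modeled="dx", **kw):
    return EvalCase(
        vignette_id="v", differential=tuple(differential), modeled_disease=modeled, **kw
    )


@pytest.mark.parametrize(
    "differential,k,expected",
    [
        (("dx", "a", "b"), 1, 1),
        (("a", "b", "dx"), 1, 0),
        (("a", "b", "dx"), 3, 1),
        (("a", "b", "c", "dx"), 3, 0),
        ((), None, 0),
        (("a", "dx"), None, 1),
    ],
)
def test_case_recall(differential, k, expected):
    assert case_recall(case(differential), k) == expected


@pytest.mark.parametrize(
    "differential,expected",
    [(("dx",), 1.0), (("a", "dx", "b", "c"), 0.25), (("a", "b", "c", "d", "e"), 0.0), ((), 0.0)],
)
def test_case_precision(differential, expected):
    assert case_precision(case(differential)) == pytest.approx(expected)


def test_f1_identities_from_published_rows():
    """F1 = 2PR/(P+R) reproduces each published (P, R, F1) row within the
    rounding of the printed inputs (+-0.1)."""
    rows = [  # (precision %, recall %, published F1 %)
        (42.9, 80.9, 56.1),
        (36.8, 64.1, 46.7),
        (53.5, 93.8, 68.1),
        (38.1, 84.3, 52.5),
        (33.9, 90.0, 49.2),
        (43.3, 90.2, 58.5),
        (56.5, 84.3, 67.7),
        (44.4, 80.0, 57.1),  # the engine's row
    ]
    for p, r, f1 in rows:
        assert abs(f1_score(p, r) - f1) <= 0.1 + 1e-9


def test_aggregate_matches_hand_computation():
    cases = [
        case(("dx", "a")),            # recall 1, precision 0.5
        case(("a", "b")),             # recall 0, precision 0
        case(("dx",)),                # recall 1, precision 1
        case(("a", "dx", "b", "c")),  # recall 1, precision 0.25
    ]
    rep = aggregate(cases)
    assert rep.recall == pytest.approx(75.0)
    assert rep.precision == pytest.approx(100 * (0.5 + 0 + 1 + 0.25) / 4)
    assert rep.f1 == pytest.approx(f1_score(rep.precision, rep.recall))
    assert rep.top1_recall == pytest.approx(50.0)


def test_equal_weights_reproduce_unweighted():
    cases = [case(("dx",)), case(("a",)), case(("dx", "a", "b"))]
    w = aggregate(cases, [2.0, 2.0, 2.0])
    u = aggregate(cases)
    assert (w.recall, w.precision, w.f1) == (u.recall, u.precision, u.f1)


def test_aggregate_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        aggregate([])
    with pytest.raises(ValueError):
        aggregate([case(("dx",))], [0.0])


def test_safety_and_appropriateness_aggregation():
    kw = dict(judge_min=TriageAction.pharmacy, judge_max=TriageAction.gp_urgent)
    cases = [
        case(("dx",), triage_action=TriageAction.pharmacy, **kw),   # safe + appr
        case(("dx",), triage_action=TriageAction.ambulance, **kw),  # safe, over
        case(("dx",), triage_action=TriageAction.self_care, **kw),  # under
    ]
    rep = aggregate(cases)
    assert rep.safety == pytest.approx(100 * 2 / 3)
    assert rep.appropriateness == pytest.approx(100 * 1 / 3)
    assert rep.safety >= rep.appropriateness


def test_pooled_doctor_rows_match_published_averages():
    """Pooling per-agent published cells reproduces the published averages:
    recall 83.9, precision 43.6, F1 57.0, n 56.6; safety 93.1, appr 90.5."""
    diag = [  # (recall, precision, f1, n)
        (80.9, 42.9, 56.1, 47),
        (64.1, 36.8, 46.7, 78),
        (93.8, 53.5, 68.1, 48),
        (84.3, 38.1, 52.5, 51),
        (90.0, 33.9, 49.2, 70),
        (90.2, 43.3, 58.5, 51),
        (84.3, 56.5, 67.7, 51),
    ]
    triage = [(95.7, 91.5), (89.7, 89.7), (100.0, 93.8), (94.1, 94.1),
              (90.0, 85.7), (94.1, 90.2), (88.2, 88.2)]
    reports = [
        EvalReport(
            agent_id=f"doctor_{i}", n_cases=n, recall=r, precision=p, f1=f1,
            top1_recall=0.0, top3_recall=0.0, safety=s, appropriateness=a,
        )
        for i, ((r, p, f1, n), (s, a)) in enumerate(zip(diag, triage))
    ]
    pooled = pool_agents(reports)
    assert round1(pooled.recall) == 83.9
    assert round1(pooled.precision) == 43.6
    assert round1(pooled.f1) == 57.0
    assert round1(pooled.n_cases) == 56.6
    assert round1(pooled.safety) == 93.1
    assert round1(pooled.appropriateness) == 90.5


def test_pool_single_report_is_identity():
    rep = EvalReport("a", 10, 50.0, 25.0, f1_score(25.0, 50.0), 30.0, 40.0)
    pooled = pool_agents([rep])
    assert (pooled.recall, pooled.precision, pooled.f1) == (
        rep.recall, rep.precision, rep.f1,
    )


@pytest.mark.parametrize(
    "ratings,expected",
    [
        (["poor", "okay", "good", "excellent"], 75.0),
        (["poor", "poor"], 0.0),
        (["excellent"] * 3, 100.0),
    ],
)
def test_rate_okay_or_better(ratings, expected):
    assert rate_okay_or_better(ratings) == pytest.approx(expected)


def test_rate_okay_or_better_rejects_unknown():
    with pytest.raises(ValueError, match="unknown rating"):
        rate_okay_or_better(["fine"])


def test_incidence_reweighting_sensitivity():
    """Weight concentrated on a single missed vignette collapses weighted
    recall even when unweighted recall is high."""
    cases = [case(("dx",), weight=1e-5) for _ in range(9)]
    cases.append(case(("a", "b"), weight=10.0))  # missed, heavy weight
    unweighted = aggregate(cases)
    weighted = aggregate(cases, "incidence")
    assert unweighted.recall == pytest.approx(90.0)
    assert weighted.recall < 1.0


def test_cases_from_csv_grouping(tmp_path):
    kb = generate_kb()
    vs = {v.id: v for v in generate_vignettes(kb, 4, seed=3)}
    vids = list(vs)
    lines = ["agent_id,vignette_id,differential,triage_action"]
    for vid in vids:
        lines.append(f"docA,{vid},{vs[vid].modeled_disease};d_99,gp_urgent")
        lines.append(f"docB,{vid},,self_care")
    csv = tmp_path / "agents.csv"
    csv.write_text("\n".join(lines) + "\n")
    grouped = cases_from_csv(csv, vs)
    assert set(grouped) == {"docA", "docB"}
    repA = aggregate(grouped["docA"], agent_id="docA")
    repB = aggregate(grouped["docB"], agent_id="docB")
    assert repA.recall == 100.0 and repA.precision == pytest.approx(50.0)
    assert repB.recall == 0.0 and repB.precision == 0.0
    assert repB.safety is not None


def test_pr_sweep_limits_and_monotonicity():
    kb = generate_kb()
    vs = generate_vignettes(kb, 12, seed=5)
    n_bands = len(kb.display_policy.modes["mode1"])
    grid = [
        [1e-12] * n_bands,   # show everything with nonzero posterior
        [0.01] * n_bands,
        [0.05] * n_bands,
        [1.0] * n_bands,     # nothing can reach a floor of 1 here
    ]
    res = pr_sweep(kb, vs, grid)
    recalls = [r for _, _, r in res]
    assert recalls[0] == 100.0  # every modeled disease has nonzero posterior
    assert all(a >= b for a, b in zip(recalls, recalls[1:]))
    assert res[-1][1] == 0.0 and res[-1][2] == 0.0
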