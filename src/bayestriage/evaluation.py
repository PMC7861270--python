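"""Vignette-study evaluation metrics.

Implements the OSCE-study scoring conventions for differential diagnosis and
triage:

* **recall** (per vignette): 1 iff the modeled disease appears in the
  differential — optionally only within the top-k entries;
* **precision** (per vignette): 1/|differential| if the modeled disease is
  included, else 0 (an empty differential scores 0);
* aggregate recall/precision are (weighted) means of the per-case values,
  reported as percentages; the aggregate **F1** is the harmonic mean
  2PR/(P+R) of the aggregate precision and recall;
* **safety** / **appropriateness**: proportion of triage decisions at or
  above the judge's minimum urgency / within the judge's [min, max] range —
  appropriateness never exceeds safety;
* incidence **reweighting**: the same aggregates with each vignette weighted
  by the annual incidence of its modeled disease, emulating how a
  vignette-mix result would shift in a real-world case mix (and exposing its
  sensitivity to a few heavily weighted vignettes);
* **rating aggregation**: percentage of four-point judge ratings (poor /
  okay / good / excellent) that are "okay or better";
* **pr_sweep**: the recall-precision trade-off traced by sweeping display
  thresholds, which is non-increasing in recall along any coordinatewise
  increase of the thresholds.

Agent pooling averages per-agent report columns arithmetically (so a pooled
F1 is the mean of per-agent F1 values, not the harmonic mean of pooled P
and R).  Display rounding is one decimal, half away from zero; internal
arithmetic keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .actions import TriageAction
from .consultation import ConsultationRecord, Vignette, demographic_evidence
from .inference import Evidence, posterior
from .knowledge_base import KnowledgeBase
from .triage import classify_triage

__all__ = [
    "EvalCase",
    "EvalReport",
    "aggregate",
    "case_precision",
    "case_recall",
    "cases_from_csv",
    "cases_from_records",
    "f1_score",
    "pool_agents",
    "pr_sweep",
    "rate_okay_or_better",
    "round1",
]

RATING_SCALE = ("poor", "okay", "good", "excellent")


def round1(x: float) -> float:
    """One-decimal display rounding, half away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalCase:
    """One scored (agent, vignette) pair."""

    vignette_id: str
    differential: tuple[str, ...]
    modeled_disease: str
    triage_action: TriageAction | None = None
    judge_min: TriageAction | None = None
    judge_max: TriageAction | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("case weight must be nonnegative")


@dataclass(frozen=True)
class EvalReport:
    """Aggregate metrics for one agent.  All percentages in [0, 100]."""

    agent_id: str
    n_cases: float
    recall: float
    precision: float
    f1: float
    top1_recall: float
    top3_recall: float
    safety: float | None = None
    appropriateness: float | None = None

    def to_row(self) -> dict:
        return {
            "agent": self.agent_id,
            "recall": round1(self.recall),
            "precision": round1(self.precision),
            "f1": round1(self.f1),
            "top1_recall": round1(self.top1_recall),
            "top3_recall": round1(self.top3_recall),
            "safety": None if self.safety is None else round1(self.safety),
            "appropriateness": (
                None if self.appropriateness is None else round1(self.appropriateness)
            ),
            "n": self.n_cases,
        }


def case_recall(case: EvalCase, k: int | None = None) -> int:
    """1 iff the modeled disease is in the differential (top-k when k given)."""
    diff = case.differential if k is None else case.differential[:k]
    return int(case.modeled_disease in diff)


def case_precision(case: EvalCase) -> float:
    """Fraction of the differential that is the modeled disease; 0 if empty."""
    if not case.differential:
        return 0.0
    return case_recall(case) / len(case.differential)


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of aggregate precision and recall (percent scale)."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def _wmean(values: Sequence[float], weights: np.ndarray) -> float:
    return float(np.average(np.asarray(values, dtype=float), weights=weights))


def aggregate(
    cases: Sequence[EvalCase],
    weights: Sequence[float] | str | None = None,
    agent_id: str = "agent",
) -> EvalReport:
    """Aggregate per-case metrics into one report.

    ``weights`` may be an explicit vector, the string ``"incidence"`` (use
    each case's stored weight, i.e. the annual incidence of its modeled
    disease), or None for the unweighted study aggregate.  Equal weights
    reproduce the unweighted report exactly.
    """
    if not cases:
        raise ValueError("cannot aggregate an empty case list")
    if weights is None:
        w = np.ones(len(cases))
    elif isinstance(weights, str):
        if weights != "incidence":
            raise ValueError(f"unknown weighting scheme {weights!r}")
        w = np.array([c.weight for c in cases], dtype=float)
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != len(cases):
            raise ValueError("weights length must match cases")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")

    recall = 100.0 * _wmean([case_recall(c) for c in cases], w)
    precision = 100.0 * _wmean([case_precision(c) for c in cases], w)
    top1 = 100.0 * _wmean([case_recall(c, 1) for c in cases], w)
    top3 = 100.0 * _wmean([case_recall(c, 3) for c in cases], w)

    triaged = [
        (i, c) for i, c in enumerate(cases)
        if c.triage_action is not None and c.judge_min is not None
    ]
    safety = appropriateness = None
    if triaged:
        idx = [i for i, _ in triaged]
        flags = [
            classify_triage(c.triage_action, c.judge_min, c.judge_max)
            for _, c in triaged
        ]
        safety = 100.0 * _wmean([f["safe"] for f in flags], w[idx])
        appropriateness = 100.0 * _wmean([f["appropriate"] for f in flags], w[idx])

    return EvalReport(
        agent_id=agent_id,
        n_cases=len(cases),
        recall=recall,
        precision=precision,
        f1=f1_score(precision, recall),
        top1_recall=top1,
        top3_recall=top3,
        safety=safety,
        appropriateness=appropriateness,
    )


def pool_agents(reports: Sequence[EvalReport], agent_id: str = "pooled") -> EvalReport:
    """Unweighted arithmetic mean of per-agent report columns.

    The pooled row averages each agent's published numbers (including F1 —
    the mean of per-agent F1 cells, not the harmonic mean of pooled P and
    R); ``n_cases`` is the mean per-agent case count.
    """
    if not reports:
        raise ValueError("cannot pool zero reports")
    mean = lambda xs: float(np.mean(xs))
    opt = lambda xs: None if any(x is None for x in xs) else mean(xs)
    return EvalReport(
        agent_id=agent_id,
        n_cases=mean([r.n_cases for r in reports]),
        recall=mean([r.recall for r in reports]),
        precision=mean([r.precision for r in reports]),
        f1=mean([r.f1 for r in reports]),
        top1_recall=mean([r.top1_recall for r in reports]),
        top3_recall=mean([r.top3_recall for r in reports]),
        safety=opt([r.safety for r in reports]),
        appropriateness=opt([r.appropriateness for r in reports]),
    )


def rate_okay_or_better(ratings: Sequence[str]) -> float:
    """Percentage of four-point ratings that are okay, good or excellent."""
    if not ratings:
        raise ValueError("no ratings to aggregate")
    for r in ratings:
        if r not in RATING_SCALE:
            raise ValueError(f"unknown rating {r!r}; expected one of {RATING_SCALE}")
    ok = sum(1 for r in ratings if RATING_SCALE.index(r) >= RATING_SCALE.index("okay"))
    return 100.0 * ok / len(ratings)


# -----------------------------------------------------------------------------
# case construction
# -----------------------------------------------------------------------------

def cases_from_records(
    records: Sequence[ConsultationRecord], vignettes: Mapping[str, Vignette]
) -> list[EvalCase]:
    """Score the engine's own consultation records against their vignettes."""
    cases = []
    for rec in records:
        v = vignettes[rec.vignette_id]
        cases.append(
            EvalCase(
                vignette_id=v.id,
                differential=tuple(rec.differential.disease_ids),
                modeled_disease=v.modeled_disease,
                triage_action=rec.triage.action,
                judge_min=v.judge_min,
                judge_max=v.judge_max,
                weight=v.annual_incidence,
            )
        )
    return cases


def cases_from_csv(
    path: str | Path, vignettes: Mapping[str, Vignette]
) -> dict[str, list[EvalCase]]:
    """Ingest externally supplied agent outputs (e.g. human doctors).

    CSV columns: ``agent_id, vignette_id, differential, triage_action``;
    ``differential`` is a semicolon-separated disease-id list (may be
    empty), ``triage_action`` one of the six action names or blank.
    Returns cases grouped by agent, scored identically to the engine's.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"agent_id", "vignette_id", "differential"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"agent CSV missing columns: {sorted(missing)}")
    out: dict[str, list[EvalCase]] = {}
    for row in df.itertuples(index=False):
        v = vignettes[row.vignette_id]
        diff = tuple(d for d in row.differential.split(";") if d)
        action = (
            TriageAction.from_name(row.triage_action)
            if getattr(row, "triage_action", "") else None
        )
        out.setdefault(row.agent_id, []).append(
            EvalCase(
                vignette_id=v.id,
                differential=diff,
                modeled_disease=v.modeled_disease,
                triage_action=action,
                judge_min=v.judge_min,
                judge_max=v.judge_max,
                weight=v.annual_incidence,
            )
        )
    return out


# -----------------------------------------------------------------------------
# recall-precision sweep over display thresholds
# -----------------------------------------------------------------------------

def pr_sweep(
    kb: KnowledgeBase,
    vignettes: Sequence[Vignette],
    threshold_grid: Sequence[Sequence[float]],
    backend: str = "quickscore",
) -> list[tuple[tuple[float, ...], float, float]]:
    """Aggregate (precision, recall) at each display-threshold vector.

    Each vignette contributes its posterior under *full* disclosure (all fact
    tiers plus demographics), so the sweep isolates the display policy from
    the questioning loop.  Returns ``(thresholds, precision_pct, recall_pct)``
    per grid point; recall is non-increasing along any coordinatewise
    increase of the thresholds (higher floors can only shrink differentials).
    """
    if not threshold_grid:
        raise ValueError("threshold grid is empty")
    posts = []
    for v in vignettes:
        states = demographic_evidence(kb, v.age, v.sex)
        states.update(v.all_facts())
        posts.append((v, posterior(kb, Evidence(states), backend)))

    results = []
    for taus in threshold_grid:
        taus = tuple(taus)
        cases = []
        for v, post in posts:
            kept = sorted(
                (
                    (d, p)
                    for d, p in post.marginals.items()
                    if p >= taus[kb.severity_band(d) - 1]
                ),
                key=lambda e: (-e[1], e[0]),
            )
            cases.append(
                EvalCase(
                    vignette_id=v.id,
                    differential=tuple(d for d, _ in kept),
                    modeled_disease=v.modeled_disease,
                )
            )
        rep = aggregate(cases)
        results.append((taus, rep.precision, rep.recall))
    return results
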