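"""Three-layer noisy-OR knowledge base.

The network has three layers of Boolean medical concepts — risk factors,
diseases and symptoms — arranged as a layered DAG: edges run only from risk
factors to diseases and from diseases to symptoms.  Every disease and every
symptom owns exactly one noisy-OR family describing its conditional
probability table (CPT):

    P(child present | parents) = 1 - (1 - leak) * prod_{present parents} (1 - lambda_p)

where ``lambda_p`` is the activation (link) probability of parent *p* and
``leak`` is the probability the child is present with every parent absent.
Risk factors are parentless families whose leak is their prior probability;
a disease's leak is its baseline prevalence when no modelled risk factor is
active.  This keeps the parameter count linear in the number of edges.

On top of the network sit the decision-model parameters used for triage
(per-disease clinical-outcome distributions, outcome/action harm costs, a
monotone over-triage cost), conjunctive red-flag rules, and the display
policy (per-severity probability thresholds, one vector per operating mode).

Files are canonical JSON (YAML accepted on input); :func:`save_kb` is
deterministic, so save -> load -> save is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .actions import ACTIONS, TriageAction
from .errors import InvariantError, SchemaError

__all__ = [
    "LAYERS",
    "ConceptNode",
    "DiseaseAttributes",
    "NoisyOrLink",
    "NoisyOrFamily",
    "TriageRule",
    "DecisionModel",
    "DisplayPolicy",
    "KnowledgeBase",
    "cpt_entry",
    "load_kb",
    "save_kb",
    "validate_kb",
]

LAYERS = ("risk_factor", "disease", "symptom")

#: parent layer required for a child in each (non-top) layer
_PARENT_OF = {"disease": "risk_factor", "symptom": "disease"}


@dataclass(frozen=True)
class ConceptNode:
    """A medical concept: risk factor, disease or symptom.

    ``demographic`` optionally marks a risk factor as a deterministic function
    of the patient's demographics, e.g. ``{"kind": "age", "min": 65}`` or
    ``{"kind": "sex", "value": "female"}``; the consultation layer answers
    such nodes from the vignette's age/sex instead of its fact lists.

    ``group`` marks membership of a mutually exclusive indicator group used
    to encode ordinal concepts (e.g. symptom-duration bins): at most one
    member of a group may be present in any evidence set.
    """

    id: str
    name: str
    layer: str
    demographic: dict | None = None
    group: str | None = None

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise SchemaError(f"nodes.{self.id}.layer", f"unknown layer {self.layer!r}")


@dataclass(frozen=True)
class DiseaseAttributes:
    """Severity band, annual incidence and clinical-outcome distribution of a disease."""

    disease_id: str
    severity_band: int
    annual_incidence: float
    outcome_distribution: dict[str, float]


@dataclass(frozen=True)
class NoisyOrLink:
    parent_id: str
    activation: float


@dataclass(frozen=True)
class NoisyOrFamily:
    """Noisy-OR CPT of one child node.

    A parentless family (``links == ()``) reduces to a Bernoulli prior with
    success probability ``leak``.
    """

    child_id: str
    leak: float
    links: tuple[NoisyOrLink, ...] = ()

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(l.parent_id for l in self.links)

    def activation_of(self, parent_id: str) -> float:
        for l in self.links:
            if l.parent_id == parent_id:
                return l.activation
        raise KeyError(parent_id)


@dataclass(frozen=True)
class TriageRule:
    """Red-flag rule: if *all* trigger symptoms are present, care urgency is
    escalated to at least ``action``'s urgency."""

    rule_id: str
    trigger: frozenset[str]
    action: TriageAction


@dataclass(frozen=True)
class DecisionModel:
    """Harm and cost parameters of the triage decision network.

    ``harm_cost[(outcome, action)]`` is the harm incurred if a patient who
    will experience ``outcome`` is routed to ``action``.  ``action_cost`` is
    the over-triage penalty: a nonnegative cost, nondecreasing in urgency,
    that depends only on the action taken.
    """

    outcomes: tuple[str, ...]
    harm_cost: Mapping[tuple[str, TriageAction], float]
    action_cost: Mapping[TriageAction, float]


@dataclass(frozen=True)
class DisplayPolicy:
    """Operating modes for the displayed differential.

    ``modes[mode_id]`` is a threshold vector tau indexed by severity band
    (band ``b`` uses ``tau[b - 1]``): disease *d* is shown iff its posterior
    is at least the threshold of its band.  Lower thresholds for more severe
    bands let dangerous conditions surface at lower probability.
    """

    modes: dict[str, tuple[float, ...]]

    def thresholds(self, mode_id: str) -> tuple[float, ...]:
        try:
            return self.modes[mode_id]
        except KeyError:
            raise KeyError(
                f"unknown display mode {mode_id!r}; available: {sorted(self.modes)}"
            ) from None


@dataclass
class KnowledgeBase:
    """The validated three-layer network plus decision-model parameters."""

    nodes: dict[str, ConceptNode]
    disease_attributes: dict[str, DiseaseAttributes]
    families: dict[str, NoisyOrFamily]
    triage_rules: tuple[TriageRule, ...]
    decision_model: DecisionModel
    display_policy: DisplayPolicy
    meta: dict = field(default_factory=lambda: {"schema_version": 1})

    # -- convenience accessors -------------------------------------------------

    def ids_in_layer(self, layer: str) -> list[str]:
        return sorted(i for i, n in self.nodes.items() if n.layer == layer)

    @property
    def risk_factors(self) -> list[str]:
        return self.ids_in_layer("risk_factor")

    @property
    def diseases(self) -> list[str]:
        return self.ids_in_layer("disease")

    @property
    def symptoms(self) -> list[str]:
        return self.ids_in_layer("symptom")

    def layer_of(self, concept_id: str) -> str:
        return self.nodes[concept_id].layer

    def severity_band(self, disease_id: str) -> int:
        return self.disease_attributes[disease_id].severity_band


# -----------------------------------------------------------------------------
# noisy-OR CPT
# -----------------------------------------------------------------------------

def cpt_entry(family: NoisyOrFamily, parent_states: Mapping[str, bool]) -> float:
    """P(child present | parents) under the noisy-OR model.

    ``parent_states`` maps every parent id to True (present) / False (absent).
    Returns ``1 - (1 - leak) * prod over present parents of (1 - activation)``.
    """
    missing = [l.parent_id for l in family.links if l.parent_id not in parent_states]
    if missing:
        raise KeyError(
            f"missing parent state(s) for {family.child_id!r}: {sorted(missing)}"
        )
    fail = 1.0 - family.leak
    for link in family.links:
        if parent_states[link.parent_id]:
            fail *= 1.0 - link.activation
    return 1.0 - fail


# -----------------------------------------------------------------------------
# validation
# -----------------------------------------------------------------------------

def validate_kb(kb: KnowledgeBase) -> list[str]:
    """Check every structural invariant; return diagnostics (empty iff valid).

    Error diagnostics start with ``"error:"``, warnings with ``"warning:"``;
    a KB is valid iff no error diagnostics are returned.  Diseases with no
    symptom children are unobservable through findings and yield a warning.
    """
    diags: list[str] = []
    err = lambda m: diags.append("error: " + m)
    warn = lambda m: diags.append("warning: " + m)

    for nid, node in kb.nodes.items():
        if node.id != nid:
            err(f"nodes[{nid}]: key does not match node id {node.id!r}")

    # families: one per disease and symptom, layered parents, probability ranges
    for layer in ("disease", "symptom"):
        for cid in kb.ids_in_layer(layer):
            if cid not in kb.families:
                err(f"{layer} {cid!r} has no noisy-OR family")
    for cid, fam in kb.families.items():
        if fam.child_id != cid:
            err(f"families[{cid}]: child_id mismatch ({fam.child_id!r})")
            continue
        if cid not in kb.nodes:
            err(f"families[{cid}]: unknown child concept")
            continue
        child_layer = kb.nodes[cid].layer
        if not (0.0 <= fam.leak < 1.0):
            err(f"families[{cid}].leak = {fam.leak} outside [0, 1)")
        seen: set[str] = set()
        for link in fam.links:
            if link.parent_id in seen:
                err(f"families[{cid}]: duplicate parent {link.parent_id!r}")
            seen.add(link.parent_id)
            if not (0.0 <= link.activation <= 1.0):
                err(
                    f"families[{cid}].links[{link.parent_id}].activation = "
                    f"{link.activation} outside [0, 1]"
                )
            parent = kb.nodes.get(link.parent_id)
            if parent is None:
                err(f"families[{cid}]: unknown parent {link.parent_id!r}")
            else:
                want = _PARENT_OF.get(child_layer)
                if want is None:
                    err(f"families[{cid}]: risk factors may not have parents")
                elif parent.layer != want:
                    err(
                        f"families[{cid}]: parent {link.parent_id!r} is a "
                        f"{parent.layer}, expected a {want} "
                        f"(edges run risk_factor->disease and disease->symptom only)"
                    )

    # disease attributes
    for did in kb.diseases:
        attrs = kb.disease_attributes.get(did)
        if attrs is None:
            err(f"disease {did!r} has no disease_attributes entry")
            continue
        if attrs.severity_band < 1:
            err(f"disease_attributes[{did}].severity_band must be >= 1")
        if attrs.annual_incidence < 0:
            err(f"disease_attributes[{did}].annual_incidence must be >= 0")
        total = sum(attrs.outcome_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            err(
                f"disease_attributes[{did}].outcome_distribution sums to "
                f"{total!r}, expected 1"
            )
        unknown = set(attrs.outcome_distribution) - set(kb.decision_model.outcomes)
        if unknown:
            err(f"disease_attributes[{did}]: unknown outcomes {sorted(unknown)}")
        if not any(
            did in kb.families[s].parent_ids for s in kb.symptoms if s in kb.families
        ):
            warn(f"disease {did!r} has no symptom children")

    # triage rules
    for rule in kb.triage_rules:
        if not rule.trigger:
            err(f"triage rule {rule.rule_id!r} has an empty trigger set")
        for sid in rule.trigger:
            node = kb.nodes.get(sid)
            if node is None or node.layer != "symptom":
                err(f"triage rule {rule.rule_id!r}: trigger {sid!r} is not a KB symptom")

    # decision model: complete cost tables, monotone over-triage penalty
    dm = kb.decision_model
    for action in ACTIONS:
        if action not in dm.action_cost:
            err(f"decision_model.action_cost missing action {action.name}")
        for outcome in dm.outcomes:
            if (outcome, action) not in dm.harm_cost:
                err(f"decision_model.harm_cost missing ({outcome}, {action.name})")
    costs = [dm.action_cost.get(a, 0.0) for a in ACTIONS]
    if any(c < 0 for c in costs) or any(
        (o_a := dm.harm_cost.get(k, 0.0)) < 0 for k in dm.harm_cost
    ):
        err("decision_model costs must be nonnegative")
    if any(b < a for a, b in zip(costs, costs[1:])):
        err("decision_model.action_cost must be nondecreasing in urgency")

    # display policy
    if not kb.display_policy.modes:
        err("display_policy defines no modes")
    for mode, taus in kb.display_policy.modes.items():
        if not taus:
            err(f"display_policy.modes[{mode}] is empty")
        if any(not (0.0 < t < 1.0) for t in taus):
            err(f"display_policy.modes[{mode}] thresholds must lie in (0, 1)")
    n_bands = max(
        (a.severity_band for a in kb.disease_attributes.values()), default=0
    )
    for mode, taus in kb.display_policy.modes.items():
        if len(taus) < n_bands:
            err(
                f"display_policy.modes[{mode}] has {len(taus)} thresholds but "
                f"severity bands go up to {n_bands}"
            )

    return diags


def _require_valid(kb: KnowledgeBase) -> KnowledgeBase:
    errors = [d for d in validate_kb(kb) if d.startswith("error:")]
    if errors:
        raise InvariantError("invalid knowledge base:\n" + "\n".join(errors))
    return kb


# -----------------------------------------------------------------------------
# (de)serialization
# -----------------------------------------------------------------------------

def _get(d: Mapping, key: str, path: str, typ=None):
    if key not in d:
        raise SchemaError(f"{path}.{key}", "missing required field")
    value = d[key]
    if typ is not None and not isinstance(value, typ):
        raise SchemaError(f"{path}.{key}", f"expected {typ}, got {type(value).__name__}")
    return value


def _prob(value, path: str, *, upper_exclusive: bool = False) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise SchemaError(path, f"expected a probability, got {value!r}")
    v = float(value)
    hi_ok = v < 1.0 if upper_exclusive else v <= 1.0
    if not (0.0 <= v and hi_ok):
        rng = "[0, 1)" if upper_exclusive else "[0, 1]"
        raise SchemaError(path, f"probability {v} outside {rng}")
    return v


def kb_from_dict(raw: Mapping) -> KnowledgeBase:
    """Build and validate a KnowledgeBase from a parsed schema dict."""
    nodes: dict[str, ConceptNode] = {}
    for nd in _get(raw, "nodes", "$", list):
        nid = _get(nd, "id", "nodes[]", str)
        path = f"nodes.{nid}"
        if nid in nodes:
            raise SchemaError(path, "duplicate node id")
        layer = _get(nd, "layer", path, str)
        if layer not in LAYERS:
            raise SchemaError(f"{path}.layer", f"unknown layer {layer!r}")
        nodes[nid] = ConceptNode(
            id=nid,
            name=nd.get("name", nid),
            layer=layer,
            demographic=nd.get("demographic"),
            group=nd.get("group"),
        )

    families: dict[str, NoisyOrFamily] = {}
    for fd in _get(raw, "families", "$", list):
        cid = _get(fd, "child_id", "families[]", str)
        path = f"families.{cid}"
        if cid in families:
            raise SchemaError(path, "duplicate family for child")
        links = []
        for i, ld in enumerate(fd.get("links", [])):
            lp = f"{path}.links[{i}]"
            links.append(
                NoisyOrLink(
                    parent_id=_get(ld, "parent_id", lp, str),
                    activation=_prob(_get(ld, "activation", lp), f"{lp}.activation"),
                )
            )
        families[cid] = NoisyOrFamily(
            child_id=cid,
            leak=_prob(_get(fd, "leak", path), f"{path}.leak", upper_exclusive=True),
            links=tuple(links),
        )

    disease_attributes: dict[str, DiseaseAttributes] = {}
    for ad in raw.get("disease_attributes", []):
        did = _get(ad, "disease_id", "disease_attributes[]", str)
        path = f"disease_attributes.{did}"
        dist = {
            str(o): _prob(p, f"{path}.outcome_distribution.{o}")
            for o, p in _get(ad, "outcome_distribution", path, dict).items()
        }
        disease_attributes[did] = DiseaseAttributes(
            disease_id=did,
            severity_band=int(_get(ad, "severity_band", path, int)),
            annual_incidence=float(_get(ad, "annual_incidence", path, (int, float))),
            outcome_distribution=dist,
        )

    rules = []
    for rd in raw.get("triage_rules", []):
        rid = _get(rd, "rule_id", "triage_rules[]", str)
        path = f"triage_rules.{rid}"
        rules.append(
            TriageRule(
                rule_id=rid,
                trigger=frozenset(_get(rd, "trigger", path, list)),
                action=TriageAction.from_name(_get(rd, "action", path, str)),
            )
        )

    dmd = _get(raw, "decision_model", "$", dict)
    outcomes = tuple(_get(dmd, "outcomes", "decision_model", list))
    harm_cost: dict[tuple[str, TriageAction], float] = {}
    for o, per_action in _get(dmd, "harm_cost", "decision_model", dict).items():
        for a, c in per_action.items():
            harm_cost[(str(o), TriageAction.from_name(a))] = float(c)
    action_cost = {
        TriageAction.from_name(a): float(c)
        for a, c in _get(dmd, "action_cost", "decision_model", dict).items()
    }
    decision_model = DecisionModel(
        outcomes=outcomes, harm_cost=harm_cost, action_cost=action_cost
    )

    dpd = _get(raw, "display_policy", "$", dict)
    modes = {
        str(m): tuple(
            _prob(t, f"display_policy.modes.{m}[{i}]") for i, t in enumerate(taus)
        )
        for m, taus in _get(dpd, "modes", "display_policy", dict).items()
    }

    kb = KnowledgeBase(
        nodes=nodes,
        disease_attributes=disease_attributes,
        families=families,
        triage_rules=tuple(rules),
        decision_model=decision_model,
        display_policy=DisplayPolicy(modes=modes),
        meta=dict(raw.get("meta", {"schema_version": 1})),
    )
    return _require_valid(kb)


def kb_to_dict(kb: KnowledgeBase) -> dict:
    """Canonical plain-dict form (deterministically ordered)."""

    def node_dict(n: ConceptNode) -> dict:
        d = {"id": n.id, "name": n.name, "layer": n.layer}
        if n.demographic is not None:
            d["demographic"] = n.demographic
        if n.group is not None:
            d["group"] = n.group
        return d

    return {
        "meta": kb.meta,
        "nodes": [node_dict(kb.nodes[i]) for i in sorted(kb.nodes)],
        "families": [
            {
                "child_id": cid,
                "leak": kb.families[cid].leak,
                "links": [
                    {"parent_id": l.parent_id, "activation": l.activation}
                    for l in sorted(kb.families[cid].links, key=lambda l: l.parent_id)
                ],
            }
            for cid in sorted(kb.families)
        ],
        "disease_attributes": [
            {
                "disease_id": did,
                "severity_band": kb.disease_attributes[did].severity_band,
                "annual_incidence": kb.disease_attributes[did].annual_incidence,
                "outcome_distribution": {
                    o: p
                    for o, p in sorted(
                        kb.disease_attributes[did].outcome_distribution.items()
                    )
                },
            }
            for did in sorted(kb.disease_attributes)
        ],
        "triage_rules": [
            {
                "rule_id": r.rule_id,
                "trigger": sorted(r.trigger),
                "action": r.action.name,
            }
            for r in sorted(kb.triage_rules, key=lambda r: r.rule_id)
        ],
        "decision_model": {
            "outcomes": list(kb.decision_model.outcomes),
            "harm_cost": {
                o: {
                    a.name: kb.decision_model.harm_cost[(o, a)]
                    for a in ACTIONS
                    if (o, a) in kb.decision_model.harm_cost
                }
                for o in kb.decision_model.outcomes
            },
            "action_cost": {
                a.name: kb.decision_model.action_cost[a]
                for a in ACTIONS
                if a in kb.decision_model.action_cost
            },
        },
        "display_policy": {
            "modes": {m: list(t) for m, t in sorted(kb.display_policy.modes.items())}
        },
    }


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, Mapping):
        raise SchemaError("$", "knowledge-base file must contain a mapping at top level")
    return kb_from_dict(raw)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the canonical JSON serialization (deterministic byte-for-byte)."""
    Path(path).write_text(
        json.dumps(kb_to_dict(kb), indent=2, sort_keys=True) + "\n"
    )
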