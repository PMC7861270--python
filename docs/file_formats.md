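# File formats

## Knowledge base (JSON canonical, YAML accepted on input)

Top-level keys: `meta`, `nodes`, `families`, `disease_attributes`,
`triage_rules`, `decision_model`, `display_policy`.  A committed example is
`examples/data/example_kb.json`.

```json
{
  "meta": {"schema_version": 1},
  "nodes": [
    {"id": "rf_00", "name": "age 65+", "layer": "risk_factor",
     "demographic": {"kind": "age", "min": 65}},
    {"id": "d_00", "name": "some disease", "layer": "disease"},
    {"id": "s_00", "name": "some symptom", "layer": "symptom",
     "group": null}
  ],
  "families": [
    {"child_id": "rf_00", "leak": 0.25, "links": []},
    {"child_id": "d_00", "leak": 0.001,
     "links": [{"parent_id": "rf_00", "activation": 0.6}]},
    {"child_id": "s_00", "leak": 0.01,
     "links": [{"parent_id": "d_00", "activation": 0.85}]}
  ],
  "disease_attributes": [
    {"disease_id": "d_00", "severity_band": 3, "annual_incidence": 0.001,
     "outcome_distribution": {"outcome_0": 0.7, "outcome_1": 0.3}}
  ],
  "triage_rules": [
    {"rule_id": "redflag_0", "trigger": ["s_00"], "action": "ae"}
  ],
  "decision_model": {
    "outcomes": ["outcome_0", "outcome_1"],
    "harm_cost": {"outcome_0": {"self_care": 0.0, "...": 0.0},
                  "outcome_1": {"self_care": 8.0, "...": 0.4}},
    "action_cost": {"self_care": 0.0, "pharmacy": 0.02, "gp_nonurgent": 0.06,
                    "gp_urgent": 0.15, "ae": 0.45, "ambulance": 1.2}
  },
  "display_policy": {
    "modes": {"mode1": [0.05, 0.028, 0.016, 0.009, 0.005],
              "mode2": [0.15, 0.084, 0.047, 0.027, 0.015]}
  }
}
```

Semantics:

* every node id is unique; `layer` is one of `risk_factor`, `disease`,
  `symptom` and fixes which edges the node may take (risk factor → disease,
  disease → symptom only);
* each disease and symptom has exactly one noisy-OR `family`; a family's
  `leak` in `[0, 1)` is the probability of the child with all parents
  absent, each link's `activation` in `[0, 1]` the probability that the
  present parent alone activates the child.  Risk factors are parentless
  families whose leak is their prior; a disease's leak is its baseline
  prevalence with no modeled risk factor active;
* `outcome_distribution` sums to 1 (tolerance 1e-9);
* `action_cost` must be nondecreasing in urgency
  (`self_care < pharmacy < gp_nonurgent < gp_urgent < ae < ambulance`);
* display `modes` hold one probability threshold per severity band,
  indexed `band - 1`;
* ordinal concepts (e.g. duration bins) are encoded as mutually exclusive
  Boolean indicators sharing a `group` tag; at most one member of a group
  may be present in any evidence;
* `demographic` tags a risk factor as a deterministic function of age
  (`{"kind": "age", "min": a, "max": b}`, either bound optional) or sex
  (`{"kind": "sex", "value": "female"}`).

`save_kb` writes deterministically ordered JSON, so save → load → save is
byte-identical.

## Vignette (YAML, one per file)

A committed example is `examples/data/example_vignette.yaml`:

```yaml
id: v_d_01_5
age: 66              # >= 16
sex: male            # female | male
modeled_disease: d_01
presenting:          # volunteered at the start of the consultation
  s_04: present
open_facts:          # offered on the single open question
  s_03: present
direct_facts:        # revealed only when explicitly asked
  s_01: present
judge_range:         # acceptable triage actions, min <= max by urgency
  min: ambulance
  max: ambulance
annual_incidence: 0.00085   # weight for real-world-case-mix reweighting
```

The three fact tiers must be disjoint; states are `present`/`absent`.
Concepts not listed anywhere are answered `absent` when asked (configurable
to `unknown`).

## Agent results CSV

For scoring externally supplied differentials/triage (e.g. human doctors)
identically to the engine: UTF-8, comma-separated, header row, one row per
(agent, vignette):

```
agent_id,vignette_id,differential,triage_action
docA,v_d_01_5,d_01;d_02,gp_urgent
```

`differential` is a semicolon-separated ordered disease-id list (may be
empty); `triage_action` is optional.
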