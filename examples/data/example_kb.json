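{
  "decision_model": {
    "action_cost": {
      "ae": 0.45,
      "ambulance": 1.2,
      "gp_nonurgent": 0.06,
      "gp_urgent": 0.15,
      "pharmacy": 0.02,
      "self_care": 0.0
    },
    "harm_cost": {
      "outcome_0": {
        "ae": 0.0,
        "ambulance": 0.0,
        "gp_nonurgent": 0.0,
        "gp_urgent": 0.0,
        "pharmacy": 0.0,
        "self_care": 0.0
      },
      "outcome_1": {
        "ae": 0.3999999999999999,
        "ambulance": 0.10000000000000009,
        "gp_nonurgent": 1.3,
        "gp_urgent": 0.8,
        "pharmacy": 1.7,
        "self_care": 2.0
      },
      "outcome_2": {
        "ae": 1.5999999999999996,
        "ambulance": 0.40000000000000036,
        "gp_nonurgent": 5.2,
        "gp_urgent": 3.2,
        "pharmacy": 6.8,
        "self_care": 8.0
      },
      "outcome_3": {
        "ae": 6.399999999999999,
        "ambulance": 1.6000000000000014,
        "gp_nonurgent": 20.8,
        "gp_urgent": 12.8,
        "pharmacy": 27.2,
        "self_care": 32.0
      }
    },
    "outcomes": [
      "outcome_0",
      "outcome_1",
      "outcome_2",
      "outcome_3"
    ]
  },
  "disease_attributes": [
    {
      "annual_incidence": 0.0022813552366256107,
      "disease_id": "d_00",
      "outcome_distribution": {
        "outcome_0": 0.016995208696,
        "outcome_1": 0.205549279437,
        "outcome_2": 0.36838434846,
        "outcome_3": 0.409071163407
      },
      "severity_band": 4
    },
    {
      "annual_incidence": 0.0008542704033115318,
      "disease_id": "d_01",
      "outcome_distribution": {
        "outcome_0": 0.06850507878599991,
        "outcome_1": 0.164233849857,
        "outcome_2": 0.549679009284,
        "outcome_3": 0.217582062073
      },
      "severity_band": 3
    },
    {
      "annual_incidence": 1.554002697432925e-05,
      "disease_id": "d_02",
      "outcome_distribution": {
        "outcome_0": 0.078086951305,
        "outcome_1": 0.403597993383,
        "outcome_2": 0.450679865351,
        "outcome_3": 0.067635189961
      },
      "severity_band": 3
    }
  ],
  "display_policy": {
    "modes": {
      "mode1": [
        0.05,
        0.02811706625951745,
        0.015811388300841896,
        0.008891397050194613,
        0.005
      ],
      "mode2": [
        0.15000000000000002,
        0.08435119877855235,
        0.04743416490252569,
        0.026674191150583837,
        0.015
      ]
    }
  },
  "families": [
    {
      "child_id": "d_00",
      "leak": 0.0022813552366256107,
      "links": [
        {
          "activation": 0.9390300582365401,
          "parent_id": "rf_01"
        }
      ]
    },
    {
      "child_id": "d_01",
      "leak": 0.0008542704033115318,
      "links": [
        {
          "activation": 0.7026736720530051,
          "parent_id": "rf_00"
        }
      ]
    },
    {
      "child_id": "d_02",
      "leak": 1.554002697432925e-05,
      "links": [
        {
          "activation": 0.7495631541571256,
          "parent_id": "rf_02"
        }
      ]
    },
    {
      "child_id": "rf_00",
      "leak": 0.25,
      "links": []
    },
    {
      "child_id": "rf_01",
      "leak": 0.5,
      "links": []
    },
    {
      "child_id": "rf_02",
      "leak": 0.2367076935956697,
      "links": []
    },
    {
      "child_id": "s_00",
      "leak": 0.00019904592042223703,
      "links": []
    },
    {
      "child_id": "s_01",
      "leak": 0.000332755481576081,
      "links": [
        {
          "activation": 0.5567786946694504,
          "parent_id": "d_01"
        }
      ]
    },
    {
      "child_id": "s_02",
      "leak": 0.0034774596006348912,
      "links": []
    },
    {
      "child_id": "s_03",
      "leak": 0.00824171335653634,
      "links": [
        {
          "activation": 0.5278639391542481,
          "parent_id": "d_01"
        }
      ]
    },
    {
      "child_id": "s_04",
      "leak": 0.000523317202919728,
      "links": [
        {
          "activation": 0.7251988265016869,
          "parent_id": "d_01"
        }
      ]
    },
    {
      "child_id": "s_05",
      "leak": 0.0007791110659699146,
      "links": [
        {
          "activation": 0.8241948510464008,
          "parent_id": "d_00"
        },
        {
          "activation": 0.8035732681226013,
          "parent_id": "d_02"
        }
      ]
    }
  ],
  "meta": {
    "generator": "synthetic",
    "schema_version": 1,
    "seed": 42
  },
  "nodes": [
    {
      "id": "d_00",
      "layer": "disease",
      "name": "d 00"
    },
    {
      "id": "d_01",
      "layer": "disease",
      "name": "d 01"
    },
    {
      "id": "d_02",
      "layer": "disease",
      "name": "d 02"
    },
    {
      "demographic": {
        "kind": "age",
        "min": 65
      },
      "id": "rf_00",
      "layer": "risk_factor",
      "name": "rf 00"
    },
    {
      "demographic": {
        "kind": "sex",
        "value": "female"
      },
      "id": "rf_01",
      "layer": "risk_factor",
      "name": "rf 01"
    },
    {
      "id": "rf_02",
      "layer": "risk_factor",
      "name": "rf 02"
    },
    {
      "id": "s_00",
      "layer": "symptom",
      "name": "s 00"
    },
    {
      "id": "s_01",
      "layer": "symptom",
      "name": "s 01"
    },
    {
      "id": "s_02",
      "layer": "symptom",
      "name": "s 02"
    },
    {
      "id": "s_03",
      "layer": "symptom",
      "name": "s 03"
    },
    {
      "id": "s_04",
      "layer": "symptom",
      "name": "s 04"
    },
    {
      "id": "s_05",
      "layer": "symptom",
      "name": "s 05"
    }
  ],
  "triage_rules": []
}
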