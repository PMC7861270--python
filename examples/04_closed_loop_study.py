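"""A miniature closed-loop vignette study.

Generates a synthetic knowledge base, samples 30 vignettes from its own
generative model, runs a simulated consultation for each with and without
directed questioning, and prints the aggregate diagnostic and triage
metrics for both settings.
"""

from bayestriage import (
    QuestionPolicy,
    SynthConfig,
    aggregate,
    cases_from_records,
    generate_kb,
    generate_vignettes,
    run_consultation,
)

kb = generate_kb(SynthConfig(seed=0))
vignettes = generate_vignettes(kb, 30, seed=7)
vmap = {v.id: v for v in vignettes}

reports = {}
for budget in (0, 20):
    records = [
        run_consultation(kb, v, QuestionPolicy(max_questions=budget))
        for v in vignettes
    ]
    cases = cases_from_records(records, vmap)
    reports[budget] = aggregate(cases, agent_id=f"budget{budget}")

print(f"{'':>12s} {'recall':>8s} {'precision':>10s} {'F1':>6s} "
      f"{'top-3':>6s} {'safety':>7s} {'appropriate':>11s}")
for budget, rep in reports.items():
    print(
        f"budget {budget:>4d} {rep.recall:8.1f} {rep.precision:10.1f} "
        f"{rep.f1:6.1f} {rep.top3_recall:6.1f} {rep.safety:7.1f} "
        f"{rep.appropriateness:11.1f}"
    )

print(
    "\nAll values are percentages over 30 vignettes. Directed questioning "
    "(budget 20) recovers the direct-questioning-only facts, lifting top-3 "
    "recall and precision over the no-questions baseline; safety is the "
    "share of triage decisions at or above the synthetic judge's minimum "
    "urgency."
)
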