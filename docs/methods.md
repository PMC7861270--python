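# Methods

## The model

The diagnostic engine is a three-layer Bayesian network over Boolean
medical concepts: risk factors at the top, diseases in the middle, symptoms
at the bottom, with edges only from risk factors to diseases and diseases
to symptoms.  Every child variable has a noisy-OR conditional distribution

    P(child = 1 | parents) = 1 − (1 − leak) · ∏_{present parents p} (1 − λ_p)

so each present parent independently fails to activate the child with
probability 1 − λ_p, and the leak is the background cause.  The parameter
count grows linearly in the number of edges, which is what makes networks
of this family elicitable and tractable at clinical scale.  This is the
classic two-layer disease–finding diagnostic architecture (QMR-DT style)
extended upward with a risk-factor layer: risk factors are parentless
families whose leak is their prior probability, and a disease's leak is its
baseline prevalence when no modeled risk factor is active.  Age and sex are
ordinary risk-factor nodes tagged as deterministic functions of
demographics rather than strata baked into the priors; the alternative
(age/sex-stratified priors) would be expressible by swapping knowledge-base
files per stratum.

A small number of intrinsically ordinal concepts (e.g. symptom duration)
are represented as mutually exclusive Boolean indicator symptoms, one noisy-OR
family per bin, with evidence validation enforcing at most one present
member per group.  This keeps the entire inference core Boolean; no ordinal
CPT form is introduced.

Evidence is a partial assignment of present/absent to risk factors and
symptoms.  Anything unobserved is marginalized, never imputed absent — the
consultation layer, not the inference layer, decides what gets asserted.
Diseases are latent; clamping one (to probe explaining-away) requires an
explicit override flag and is marked in the result.

## Inference backends

*Enumeration* sums the joint over all configurations of unobserved risk
factors and diseases (cap: 20 such variables).  It is exponential and
trivially correct, and serves as the oracle for everything else.  It works
in log space throughout.

*Quickscore* exploits the noisy-OR factorization: negative findings fold
into per-disease multiplicative factors, positive findings are handled by
inclusion–exclusion over their subsets, and unobserved risk factors by an
outer exact enumeration.  Cost is O(2^|positive findings| · 2^|unobserved
risk factors| · #diseases); caps of 20 positive findings and 20 unobserved
risk factors apply.

Numerics of the inclusion–exclusion sum deserve a note.  Its terms
alternate in sign and can cancel many orders of magnitude (the empty subset
contributes O(1) while the total equals the evidence probability, which may
be tiny), and a log-space formulation does not help: the error that
cancellation amplifies is the representation error of the individual terms,
which log/exp round-trips make *worse*.  The implementation therefore
builds all subset products by exact recursive doubling in linear
arithmetic, accumulates in 80-bit extended precision, and estimates the
cancellation (machine epsilon × Σ|terms| against the computed total).  If
the estimate threatens the 1e-9 agreement bound with enumeration, the same
sums are re-evaluated in 50-digit decimal arithmetic; this fallback
triggers only on pathologically unlikely evidence and costs nothing on the
fast path.  Observed worst-case disagreement with enumeration across the
random-network suite is below 1e-13.  Activations and leaks of exactly 0
or 1 are legal everywhere; degenerate branches avoid division by zero.

*Likelihood weighting* samples unobserved nodes forward from the model,
clamps observed ones and multiplies their conditional probability into the
sample weight; estimates are weighted means with a ratio-estimator standard
error.  It is the fallback beyond the exact caps (default 100,000 samples)
and is reproducible for a fixed seed.  Evidence with zero probability under
the model (every sample weight zero) is reported as an error naming the
contradictory assignments.

## Question selection

The next question maximizes a one-step value-of-information score

    gain(c) = H(now) − Σ_{a ∈ {present, absent}} P(c = a | E) · H(E ∪ {c = a})

where H is the *sum of binary entropies* of the k highest-posterior disease
marginals (k = 10 by default), the top-k set is frozen at the current
evidence, and the predictive probability of each answer is the likelihood
ratio of the extended evidence — one extra exact inference per branch.
Summing marginal entropies instead of using the joint entropy is a
deliberate approximation: it is tractable, matches the marginal-based
display, and makes gain exactly zero for candidates d-separated from the
top-k diseases.  The production criterion this stands in for is not
published; this formula is one defensible instantiation and should be read
as such.  Questioning stops when the best gain falls below `min_gain`
(10⁻³ bits) or the budget (default 30) is exhausted.  Ties break to the
lexicographically smallest concept id so the whole consultation is a
deterministic function of its inputs.

## Differential display

Disease d is displayed iff P(d | E) ≥ τ_mode(severity_band(d)) — per-band
probability floors, lower for more severe bands so dangerous conditions
surface at lower probability.  The semantics "a combination of probability
and severity" admits other readings (e.g. multiplicative probability ×
severity scores); banded floors are the simplest faithful one and other
policies are expressible through the same threshold-vector interface.  The
boundary is inclusive.  If one mode's thresholds dominate another's
coordinatewise, its differential is provably a subset on any posterior
vector — which is what makes a threshold sweep trade recall for precision
monotonically.

## Triage

For each of the six ordered actions (self-care, pharmacy, non-urgent GP,
urgent GP, A&E, ambulance) the expected harm is Σ_d P(d|E) Σ_o P(o|d) ·
harm(o, action), with P(o|d) the disease's clinical-outcome distribution.
The chosen action minimizes expected harm plus an action-only cost that is
nondecreasing in urgency (the over-triage penalty).  Ties break toward the
*less* urgent action, consistent with penalizing over-triage.  Red-flag
rules have conjunctive triggers (all listed symptoms present); every fired
rule imposes a minimum urgency and the final action is the maximum of the
utility action and all fired floors, so escalation never lowers urgency.
Rules are implemented as minimum-urgency floors rather than hard overrides;
a hard "exactly this action" rule would differ only when the utility action
is already *more* urgent than the rule demands, where a floor keeps the
safer decision.  A decision is *safe* against a judge range [min, max] if
its urgency is ≥ min, *appropriate* if within the range; appropriate
implies safe by construction.

Outcome and action costs in the synthetic generator are hand-set (harm
growing geometrically with outcome badness, mitigation increasing with
urgency); fitting costs from case outcomes is out of scope.

## Simulated consultations

A vignette scripts a single-condition patient with tiered disclosure:
presenting facts seeded up front, one bulk open-questioning disclosure
(standing in for the free-text phase of a real consultation — no language
layer is modeled), then directed questions answered from the script.
Concepts the script does not mention are answered "absent", mirroring
role-players instructed with a complete case card; a config flag switches
to "unknown" (leave unobserved).  Evidence only grows during a
consultation.  The consultation ends with the displayed differential and
the triage decision on the final evidence.

## Synthetic data

`generate_kb` samples a structured network: disease baseline priors
log-uniform on [1e-5, 1e-2] per person-year (the scale of real annual
incidences — posteriors then behave like a diagnostic network's rather
than a toy's), risk-factor priors uniform on [0.02, 0.3], disease→symptom
activations uniform on [0.2, 0.95] with edge density 0.25 (each disease
keeps at least one symptom child), symptom leaks log-uniform on
[1e-4, 0.02], five severity bands, four outcomes with severity-correlated
outcome distributions, two red-flag rules on strongly linked symptoms of
the most severe diseases, and two display modes with mode-2 floors 3×
mode-1.  All sampling is deterministic under the config seed and the
output is byte-identical across runs.

`generate_vignette` samples from the KB's own generative model: risk
factors from priors (demographics from a sampled age 16–90 and sex),
the modeled disease forced present, incidental co-diseases suppressed by
default (the single-condition study design; a flag re-enables them),
symptoms from their CPTs.  Present symptoms are split into
presenting/open/direct tiers with probabilities (0.3, 0.4, 0.3) — a
one-time choice, configurable; present non-demographic risk factors go to
the open or direct tier.  The judge range is synthetic: the triage decision
under full disclosure with the true disease's posterior clamped to 1,
widened one urgency step upward.  It stands in for human judges only for
closed-loop testing; nothing about it models clinical judgement.

What passing closed-loop tests shows — and does not.  Vignettes drawn from
the model itself contain no model misspecification, no reporting noise, no
language ambiguity and no inter-judge disagreement, so closed-loop metrics
are an upper bound on behavior against real cases.  They do establish that
the pipeline is internally coherent: questioning recovers withheld facts
and measurably lifts top-3 recall, display modes trade recall for
precision in the predicted direction, and triage beats trivial baselines
against its own judge.

## Study sizes and evaluation conventions

The pinned closed-loop study uses the default KB (6 risk factors of which
2 demographic, 10 diseases, 24 symptoms), 200 vignettes with uniform
disease coverage (a vignette study's deliberate mix of common and rare
conditions; incidence reweighting undoes it when a real-world case mix is
wanted), and a 20-question budget.  Aggregate recall/precision are
(weighted) means of per-case values in percent; aggregate F1 is the
harmonic mean 2PR/(P+R) of the *aggregate* precision and recall, while
pooled multi-agent rows are unweighted arithmetic means of per-agent cells
(including their F1 cells) — both conventions verified against the
published table arithmetic they mirror.  An empty differential scores
precision 0 (the source convention leaves it undefined).  Display rounding
is one decimal, half away from zero; internal arithmetic is full
precision.  Confidence intervals are not reproduced: the published
interval method is unstated, so only a normal-approximation helper would
be honest, and none is claimed.

## Known limitations

* Joint disease posteriors are never computed; everything downstream
  consumes marginals.
* The value-of-information criterion is myopic (one step) and
  marginal-entropy based.
* Quickscore's exact caps make worst-case cost exponential in positive
  findings; beyond them only the sampling backend is available.
* The synthetic judge and cost parameters are constructs for closed-loop
  testing, not clinically calibrated quantities.
* Vignettes model one underlying condition; multi-morbidity inference
  works (the network is generative) but is unexercised by the study
  harness.
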