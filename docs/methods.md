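# Methods

## The screening model

`lifescreen` implements a first-level (rapid) healthy-lifestyle screening
instrument as a deterministic rule engine. A respondent answers a short
questionnaire spanning eight components: (1) anthropometric and
cardiometabolic parameters, (2) physical activity and exercise,
(3) well-being, social cohesion and functional independence, (4) nutrition,
(5) mental health, (6) smoking, drinking and illicit substances,
(7) sleep habits and quality, (8) health and disease. Every scored answer is
mapped to an ordinal traffic-light risk — low (green) < moderate (yellow) <
relevant (orange) — and each component aggregates its items with the
maximum rule:

- **low** if every scored answer is green;
- **moderate** if at least one answer is yellow and none is orange;
- **relevant** if at least one answer is orange.

Missing answers, "prefer not to answer", the "unknown" lab category, and the
two risk-free items (weekly exercise days once the respondent exercises, and
the 0–100 health visual-analogue scale) carry a fourth sentinel value,
`not_scored`, which is excluded from aggregation. A component with no scored
answer at all is itself `not_scored`; absence of information is deliberately
not treated as risk anywhere in the pipeline.

### Numeric rules

The on-site measurements use WHO-style cut-offs, applied to unrounded values
with no epsilon tolerance (140.0 mmHg is relevant; 139.999 is moderate):

| measure | low | moderate | relevant |
|---|---|---|---|
| BMI (kg/m²) | [18.5, 25) | (0, 18.5) ∪ [25, 30) | ≥ 30 |
| waist, men (cm) | < 94 | [94, 102] | > 102 |
| waist, women (cm) | < 80 | [80, 88] | > 88 |
| blood pressure (mmHg) | SBP < 130 and DBP < 85 | SBP ∈ [130, 140) or DBP ∈ [85, 90) | SBP ≥ 140 **or** DBP ≥ 90 |
| glycemia (mg/dl) | < 110 | [110, 126) | ≥ 126 |
| total cholesterol (mg/dl) | < 190 | [190, 240) | ≥ 240 |

Three reading choices here were genuinely open and are fixed as follows. The
BMI low band is half-open at 25 so no value falls between the printed
"24.99" and "25" bands. The waist moderate bands are inclusive at both ends
("94–102" read literally), making relevant strictly `> 102` / `> 88`. The
blood-pressure relevant rule is disjunctive (either elevation suffices),
which is both the scoring table's wording and the clinically standard
hypertension definition; the message catalog's "and" header is treated as a
label, not a rule.

Glycemia and cholesterol accept either a numeric value or a self-reported
category. A number always wins when both are present. The categorical
fallback maps normal → low, high → moderate, unknown → not scored: a
self-reported "high" cannot be split into the numeric moderate/relevant
bands, so the engine assigns the lower one and relies on referral routing to
trigger an actual measurement.

### Rule variants

The categorical rule table is shipped as declarative data
(`data/rules.json`) in two named, auditable editions:

- **`as_printed`** — the table verbatim, kept for auditability.
- **`narrative_corrected`** (default) — two patches that reconcile the table
  with the instrument's stated intent: (a) never using illicit substances is
  low risk rather than moderate; (b) for an ex-smoker the cessation-time
  answer supersedes the blanket moderate for having ever smoked, so a
  quitter of more than ten years scores a low smoking sub-block. Without
  (b), the stated "low risk for those who stopped smoking more than 10 years
  ago" is unreachable.

The two editions differ on no input other than these two points (a property
test enumerates all (item, answer) pairs). One known consequence of the
verbatim edition: it can produce an illicit-substances *moderate* sub-block,
a key for which no recommendation message cell exists; `check_catalog` and
message selection raise a configuration error naming the key. This is an
inconsistency of the source instrument, and one more reason the corrected
edition is the default.

### Nutrition grid

The weekly food-frequency item covers seven groups — five "healthy"
(vegetables/fruit; milk products; fish/meat/eggs; bread/pasta/cereal;
legumes/grains) and two "indulgent" (fried/salty; sweets). Low requires all
five healthy groups at ≥ 4 times/week and both indulgent groups at < 1
time/week; relevant fires when *any* healthy group is never consumed or
*any* indulgent group reaches ≥ 4 times/week (the conservative screening
reading of an ambiguous rule); everything else is moderate. A
dietary-exemption flag (religious or vegetarian/vegan habits) neutralizes
the relevant trigger for "never" on the two animal-product groups; it
deliberately does not relax the low rule, so an exempt vegan plateaus at
moderate rather than being misread as either extreme.

### Skip logic and validation

Validation is total: a raw record either yields a fully validated
`ResponseSet` or a non-empty list of issues, each naming the field and the
printed item number. Enforced constraints: closed answer domains;
physiological ranges (weight 20–400 kg, height 0.5–2.6 m, waist 40–250 cm,
SBP 50–300, DBP 30–200, DBP < SBP); and skip logic — the cessation-time item
only for ex-smokers, weekly exercise days only for exercisers, and the four
functional-independence items only for respondents *strictly older than 65*
(the printed "> 65" is followed literally; a 65-year-old is not gated in,
which is flagged for maintainers as an open reading). Height is accepted in
metres only; a value that looks like centimetres is rejected with an
explicit unit hint rather than silently converted, because silent inference
risks 100× BMI errors. An explicit "no" on a checklist item is an empty set,
distinct from a missing answer.

## Messages and referral

Recommendation messages live in an external UTF-8 catalog
(`data/messages.json`) keyed by (component, sub-block, risk), so a locale
swap needs no code change. Component 1 reports four sub-blocks (BMI/waist —
keyed by the worse of the two —, blood pressure, glycemia, cholesterol) and
component 6 three (smoking, drinking, illicit); all other components report
one message keyed by their aggregate. Unscored dimensions get a "not
assessed" placeholder, never a risk message.

Respondents with at least one moderate or relevant component are routed to
second-level instruments: body-composition bio-impedance and a detailed
nutrition questionnaire (components 1 and 4), a physical test battery
(handgrip, balance, sit-and-reach, reaction time, HRV; component 2), RSES /
SPS / SF-12 per well-being sub-question (component 3, item-level routing to
avoid over-referral), condition-specific questionnaires for component 5
(HADS for depression plus GDS-30 above age 65, PSS for anxiety/stress, MMSE
for memory complaints, MIDAS for migraine/nausea/dizziness, optional RSES
otherwise), a detailed substances questionnaire (component 6), ESS and PSQI
(component 7), and SF-12 plus spirometry/oximetry for reported respiratory
disease (component 8). Any trigger adds the generic EQ-5D-5L. Soundness
invariants, enforced by tests: the plan is empty iff no component is
moderate/relevant, and EQ-5D-5L presence exactly tracks that condition.
Neurological conditions without a dedicated instrument (stroke, Parkinson,
epilepsy) trigger only the component message and EQ-5D-5L; no instrument is
invented. The NEO-FFI carries an "optional, academic purposes only" flag.

## Synthetic cohorts

The generator (`cohort.py`) draws skip-logic-consistent records from
configurable marginals: truncated normals for the continuous vitals
(truncation kept strictly inside the validator ranges, so generator output
always validates — a property test sweeps seeds and missingness rates),
probability vectors for categorical answers, and none-probability +
per-condition weights for checklists. Sampling uses `numpy`'s PCG64
generator; truncated normals go through the inverse CDF
(`scipy.special.ndtr`/`ndtri`) for speed and exact seeded determinism.
Missingness is applied last, after skip logic, and dropping a parent answer
drops its gated children, so structurally absent items are never
double-counted as missing. Diastolic pressure is clamped below systolic.

Default marginals are plausibility-oriented values for an adult European
public-event population (e.g. 18% current smokers, 30% ex-smokers, 35%
sedentary, mean BMI ≈ 26.5, mean BP ≈ 128/78, 2% per-item missingness);
they make every rule band reachable at desk scale and claim no
epidemiological calibration. Factors are sampled independently — there is no
correlation structure between, say, BMI and blood pressure — so the cohort
exercises rule plumbing, message selection and referral routing, not
population risk structure. Passing tests therefore demonstrate correctness
of the engine, not realism of any simulated prevalence. A degenerate
`CohortSpec.lowest_risk()` spec pins every marginal in its green band and
yields, by construction, a zero referral rate.

## Numerical and testing choices

- Boundary behavior is pinned by triplet tests (threshold − 0.01, threshold,
  threshold + 0.01) for every numeric rule.
- Component aggregation is verified exhaustively against an independent
  restatement of the verbal rule (three mutually exclusive clauses) over all
  level combinations up to eight items, plus a seeded property test for
  monotonicity under single-item escalation.
- Reports are byte-stable: serialization excludes the timestamp unless one
  is attached explicitly, and referral ordering follows a fixed canonical
  instrument order.
- Problem sizes used by the test suite and the acceptance script: grid scans
  of ≤ 3001 points per threshold, exhaustive aggregation over ≤ 4^6
  combinations, cohorts of 25–80 for property checks and 10 000 for
  prevalence recovery (binomial 3-SE band). The whole suite runs in well
  under a minute on one CPU.

## Known limitations

- English message catalog only (the catalog file is the localization point).
- The second-level instruments are referral records only; their
  administration and scoring are out of scope by design.
- The generator's independence assumption makes joint prevalences
  (e.g. smoking × hypertension) unrealistic; a correlation hook is a natural
  extension point.
- The `as_printed` variant cannot render a complete report for every
  scorable input (see the catalog gap above); it is intended for rule
  audits, not production reporting.
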