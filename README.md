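# lifescreen

A deterministic scoring engine for a rapid, eight-component healthy-lifestyle
screening questionnaire, built for public-health teams running informal
screening events and for developers embedding first-level triage in health
platforms.

Respondents answer a short questionnaire (about 10 minutes) covering:

1. anthropometric and cardiometabolic parameters (BMI, waist circumference,
   blood pressure, glycemia, cholesterol),
2. physical activity and exercise,
3. well-being, social cohesion and functional independence,
4. nutrition,
5. mental health,
6. smoking, drinking and illicit substances,
7. sleep habits and quality,
8. health and disease.

Every scored answer receives a traffic-light risk — **low** (green) <
**moderate** (yellow) < **relevant** (orange) — from a versioned declarative
rule table. A component's risk is the maximum over its scored items: low iff
all answers are green, relevant as soon as one is orange, moderate in
between; unanswered items are excluded rather than penalized. Numeric
measures use WHO-style cut-offs, e.g. BMI low on [18.5, 25) kg/m², obesity
relevant at ≥ 30; blood pressure relevant when SBP ≥ 140 **or** DBP ≥ 90
mmHg; glycemia relevant at ≥ 126 mg/dl. The engine then emits a
recommendation report (one catalog message per scored dimension) and a
referral plan routing anyone with a moderate/relevant component to
second-level instruments (EQ-5D-5L plus component-specific questionnaires
and device tests). A seeded synthetic-cohort generator lets the whole
pipeline run end-to-end with no external data.

See `docs/methods.md` for the full rule model, the two auditable rule-set
editions (`narrative_corrected`, the default, vs `as_printed`), and the
generator's assumptions.

## Worked example

```python
import json
from importlib import resources
from lifescreen import assess

record = json.loads(
    (resources.files("lifescreen") / "data" / "example_response.json").read_text()
)
record["sbp"] = 143          # hypertensive systolic reading
record["sleep_hours"] = "lt5h"  # under five hours of sleep

report = assess(record)
for comp in report.to_dict()["components"]:
    print(comp["id"], comp["aggregate"], comp["color"])
print([i["name"] for i in report.to_dict()["referral"]["instruments"]])
```

prints

```
1 relevant orange
2 low green
3 low green
4 low green
5 low green
6 low green
7 relevant orange
8 low green
['EQ-5D-5L', 'Bio-impedance body composition', 'Detailed nutrition questionnaire',
 'Epworth Sleepiness Scale (ESS)', 'Pittsburgh Sleep Quality Index (PSQI)']
```

The systolic reading of 143 mmHg turns component 1 orange (SBP ≥ 140), the
short sleep turns component 7 orange (< 5 h is relevant), and the referral
plan routes the respondent to the cardiometabolic follow-ups, both sleep
questionnaires, and the generic EQ-5D-5L. The blood-pressure message in
`report.to_dict()["messages"]` begins "Your blood pressure is high. …".

## Command line

```bash
lifescreen score response.json --format both --out report.json
lifescreen simulate --n 500 --seed 7 --out cohort.csv
lifescreen batch cohort.csv --out results/       # reports.jsonl + summaries
lifescreen summarize results/reports.jsonl
lifescreen schema                                # JSON schema export for UIs
```

Batch CSV uses one column per answer slot (empty cell = missing answer,
checklists as `;`-joined tokens); the formats carry no personal identifiers
by construction. Invalid rows are reported per respondent with the violated
item number and skipped; the rest of the batch proceeds.

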