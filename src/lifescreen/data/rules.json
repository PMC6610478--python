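{
  "version": "1.0",
  "numeric": {
    "bmi": {"low_min": 18.5, "moderate_min": 25.0, "relevant_min": 30.0},
    "waist": {
      "male": {"moderate_min": 94.0, "relevant_gt": 102.0},
      "female": {"moderate_min": 80.0, "relevant_gt": 88.0}
    },
    "blood_pressure": {
      "sbp_moderate_min": 130.0, "sbp_relevant_min": 140.0,
      "dbp_moderate_min": 85.0, "dbp_relevant_min": 90.0
    },
    "glycemia": {"moderate_min": 110.0, "relevant_min": 126.0},
    "cholesterol": {"moderate_min": 190.0, "relevant_min": 240.0}
  },
  "lab_category_fallback": {"normal": "low", "high": "moderate", "unknown": "not_scored"},
  "categorical": {
    "2.1": {"no": "low", "yes": "relevant"},
    "2.2": {"gt60": "low", "30to60": "moderate", "lt30": "relevant"},
    "2.3": {"yes": "low", "no": "relevant"},
    "2.4": {"one_or_two": "low", "three_or_more": "low"},
    "3.1": {"strongly_agree": "low", "agree": "low", "neutral": "moderate",
            "disagree": "relevant", "strongly_disagree": "relevant",
            "prefer_not_to_answer": "not_scored"},
    "3.2": {"none": "relevant", "one_or_two": "moderate",
            "three_to_five": "low", "six_or_more": "low"},
    "3.3.1": {"yes": "low", "no": "moderate"},
    "3.3.2": {"yes": "low", "no": "moderate"},
    "3.3.3": {"yes": "low", "no": "moderate", "not_applicable": "not_scored"},
    "3.3.4": {"yes": "low", "no": "low", "not_applicable": "not_scored"},
    "4.1": {"yes": "low", "no": "moderate"},
    "5.1": {"no": "low", "yes": "relevant"},
    "5.2": {"no": "low", "yes": "relevant"},
    "6.1": {"no": "low", "yes": "relevant"},
    "6.2": {"no": "low", "yes": "moderate"},
    "6.3": {"lt_1y": "relevant", "1_to_5y": "moderate", "5_to_10y": "moderate",
            "gt_10y": "low"},
    "6.4": {"no": "low", "yes": "moderate"},
    "6.5": {"no": "low", "yes": "moderate"},
    "6.6": {"no": "moderate", "yes": "relevant"},
    "6.7": {"no": "low", "yes": "relevant"},
    "7.1": {"yes": "low", "no": "moderate"},
    "7.2": {"lt5h": "relevant", "5to7h": "moderate", "ge7h": "low"},
    "7.3": {"never_or_once": "low", "2_3_times": "moderate", "4_or_more": "relevant"},
    "7.4": {"yes": "relevant", "no": "low"},
    "7.5": {"yes": "relevant", "no": "low"},
    "8.1": {"no": "low", "yes": "moderate"},
    "8.2": {"none_or_one": "low", "two_to_five": "moderate", "more_than_five": "relevant"},
    "8.3": {"yes": "moderate", "no": "low"},
    "8.4": {"very_good": "low", "good": "low", "reasonable": "moderate",
            "bad": "relevant", "very_bad": "relevant"}
  },
  "variants": {
    "as_printed": {
      "overrides": {},
      "ex_smoker_supersession": false
    },
    "narrative_corrected": {
      "overrides": {"6.6": {"no": "low"}},
      "ex_smoker_supersession": true
    }
  }
}
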