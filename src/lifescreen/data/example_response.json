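{
  "age": 45,
  "sex": "male",
  "education": "higher",
  "employment": "employed",
  "weight": 67,
  "height": 1.75,
  "waist": 85,
  "sbp": 118,
  "dbp": 76,
  "glycemia": 90,
  "cholesterol": 170,
  "sedentary": "no",
  "walking": "gt60",
  "exercise": "yes",
  "exercise_types": "fitness_equipment",
  "exercise_days": "three_or_more",
  "life_satisfaction": "agree",
  "support_network": "six_or_more",
  "healthy_diet": "yes",
  "food_vegetables_fruit": "once_or_more_per_day",
  "food_milk_products": "once_or_more_per_day",
  "food_fish_meat_eggs": "times_4_6_per_week",
  "food_bread_pasta_cereal": "once_or_more_per_day",
  "food_legumes_grains": "times_4_6_per_week",
  "food_fried_salty": "lt_once_per_week",
  "food_sweets": "never",
  "mental_conditions": "no",
  "neuro_conditions": "no",
  "smokes": "no",
  "smoked_before": "no",
  "alcohol": "no",
  "alcohol_before": "no",
  "drugs": "no",
  "drugs_before": "no",
  "sleeps_well": "yes",
  "sleep_hours": "ge7h",
  "night_wakings": "never_or_once",
  "wakes_tired": "no",
  "sleeping_pills": "no",
  "chronic_conditions": "no",
  "daily_medications": "none_or_one",
  "natural_products": "no",
  "health_perception": "good",
  "health_vas": 85
}
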