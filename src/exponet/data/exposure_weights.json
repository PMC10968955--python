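{
  "version": "1.0",
  "description": "Meta-analytic odds ratios for the ten binarized exposome-score components, with the published two-decimal log-odds used as a fidelity check against ln(OR).",
  "components": [
    {"id": "winter_birth", "odds_ratio": 1.05, "printed_log_odds": 0.05},
    {"id": "obstetric_complications", "odds_ratio": 2.00, "printed_log_odds": 0.69},
    {"id": "advanced_paternal_age", "odds_ratio": 1.28, "printed_log_odds": 0.25},
    {"id": "non_right_handedness", "odds_ratio": 1.65, "printed_log_odds": 0.50},
    {"id": "emotional_neglect", "odds_ratio": 2.90, "printed_log_odds": 1.06},
    {"id": "emotional_abuse", "odds_ratio": 3.40, "printed_log_odds": 1.22},
    {"id": "bullying", "odds_ratio": 2.39, "printed_log_odds": 0.87},
    {"id": "sexual_abuse", "odds_ratio": 2.38, "printed_log_odds": 0.87},
    {"id": "cannabis_use", "odds_ratio": 1.75, "printed_log_odds": 0.56},
    {"id": "urban_upbringing", "odds_ratio": 1.72, "printed_log_odds": 0.54}
  ],
  "paternal_age_tiers": [
    {"tier": "35-54", "odds_ratio": 1.28, "printed_log_odds": 0.25},
    {"tier": ">=55", "odds_ratio": 2.22, "printed_log_odds": 0.80}
  ]
}
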