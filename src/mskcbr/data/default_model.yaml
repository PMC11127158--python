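# Default 29-attribute patient-similarity schema for primary-care
# musculoskeletal pain. Weights are integers 1-8 (higher = more prognostic
# relevance); plateau widths follow the attribute's minimal clinically
# important difference where one is established. Five attributes (mental
# distress, expectations, pain sites, sleep problems, work ability) carry
# the published worked-example weights and local profiles; the remaining
# attributes, weights and tables are editable defaults chosen by the same
# MCID-plus-consensus logic, since the full published attribute list is not
# publicly deposited.
name: msk-default
version: "1.0"
attributes:
  # --- sociodemographic -------------------------------------------------
  - name: age
    kind: numeric
    domain: [18, 100]
    weight: 2
    local: {plateau_width: 5, anchors: [[15, 0.8], [30, 0.5], [60, 0.2], [82, 0.0]]}
  - name: sex
    kind: categorical
    domain: [female, male]
    weight: 1
    local: {table: [[female, male, 0.5]]}
  - name: education
    kind: categorical
    domain: [higher, lower]
    weight: 1
    local: {table: [[higher, lower, 0.5]]}
  - name: bmi
    kind: numeric
    domain: [15, 60]
    weight: 2
    local: {plateau_width: 2, anchors: [[5, 0.8], [10, 0.4], [20, 0.1], [45, 0.0]]}
  - name: work_status
    kind: categorical
    domain: [working, sick_leave, not_working]
    weight: 3
    local:
      table:
        - [working, sick_leave, 0.3]
        - [working, not_working, 0.2]
        - [sick_leave, not_working, 0.6]
  # --- pain and function ------------------------------------------------
  - name: pain_intensity      # NRS 0-10, MCID 2 points
    kind: numeric
    domain: [0, 10]
    weight: 5
    local: {plateau_width: 2, anchors: [[4, 0.6], [6, 0.3], [10, 0.0]]}
  - name: pain_sites
    kind: numeric
    domain: [0, 10]
    weight: 2
    local: {plateau_width: 0, anchors: [[1, 0.8], [2, 0.6], [5, 0.2], [10, 0.0]]}
  - name: pain_duration
    kind: ordinal
    domain: [acute, subacute, chronic]   # <1 month, 1-3 months, >3 months
    weight: 5
    local:
      table:
        - [acute, subacute, 0.6]
        - [subacute, chronic, 0.5]
        - [acute, chronic, 0.2]
  - name: psfs                # Patient Specific Functional Scale, higher = better
    kind: numeric
    domain: [0, 10]
    weight: 4
    local: {plateau_width: 2, anchors: [[4, 0.6], [6, 0.3], [10, 0.0]]}
  - name: workability
    kind: numeric
    domain: [0, 10]
    weight: 4
    local: {plateau_width: 1, anchors: [[2, 0.8], [3, 0.6], [6, 0.2], [10, 0.0]]}
  - name: expectations        # expectation of recovery, 0-10
    kind: numeric
    domain: [0, 10]
    weight: 4
    local: {plateau_width: 1, anchors: [[2, 0.8], [4, 0.3], [10, 0.0]]}
  - name: previous_episodes
    kind: categorical
    domain: [yes_prev, no_prev]
    weight: 2
    local: {table: [[yes_prev, no_prev, 0.3]]}
  - name: comorbidity_count
    kind: numeric
    domain: [0, 10]
    weight: 2
    local: {plateau_width: 1, anchors: [[3, 0.5], [6, 0.2], [10, 0.0]]}
  - name: activity_limitation
    kind: numeric
    domain: [0, 10]
    weight: 3
    local: {plateau_width: 2, anchors: [[4, 0.6], [7, 0.2], [10, 0.0]]}
  - name: pain_worst          # worst pain last 2 weeks, NRS
    kind: numeric
    domain: [0, 10]
    weight: 2
    local: {plateau_width: 2, anchors: [[4, 0.6], [6, 0.3], [10, 0.0]]}
  # --- psychological ----------------------------------------------------
  - name: mental_distress     # HSCL-10 mean score, highest weight
    kind: numeric
    domain: [1, 4]
    weight: 8
    local: {plateau_width: 0, anchors: [[0.2, 0.8], [0.5, 0.6], [1.0, 0.3], [3.0, 0.0]]}
  - name: sleep_problems
    kind: ordinal
    domain: [Normal, Slight, Moderate, Great]
    weight: 4
    local:
      table:
        - [Normal, Slight, 0.8]
        - [Normal, Moderate, 0.4]
        - [Normal, Great, 0.2]
        - [Slight, Moderate, 0.8]
        - [Slight, Great, 0.4]
        - [Moderate, Great, 0.6]
  - name: fear_avoidance
    kind: numeric
    domain: [0, 10]
    weight: 4
    local: {plateau_width: 2, anchors: [[4, 0.6], [7, 0.2], [10, 0.0]]}
  - name: catastrophizing
    kind: numeric
    domain: [0, 10]
    weight: 4
    local: {plateau_width: 2, anchors: [[4, 0.6], [7, 0.2], [10, 0.0]]}
  - name: self_efficacy
    kind: numeric
    domain: [0, 10]
    weight: 3
    local: {plateau_width: 2, anchors: [[4, 0.6], [7, 0.2], [10, 0.0]]}
  - name: stress
    kind: numeric
    domain: [0, 10]
    weight: 3
    local: {plateau_width: 2, anchors: [[4, 0.6], [7, 0.2], [10, 0.0]]}
  - name: mood
    kind: numeric
    domain: [0, 10]
    weight: 3
    local: {plateau_width: 2, anchors: [[4, 0.6], [7, 0.2], [10, 0.0]]}
  - name: risk_group          # musculoskeletal risk stratification
    kind: ordinal
    domain: [low, medium, high]
    weight: 4
    local:
      table:
        - [low, medium, 0.5]
        - [medium, high, 0.5]
        - [low, high, 0.1]
  # --- health behaviour -------------------------------------------------
  - name: physical_activity   # days/week; position-dependent similarity:
    kind: ordinal             # 0 vs 1 day differs more than 5 vs 6-7 days
    domain: ["0", "1", "2", "3", "4", "5", "6-7"]
    weight: 3
    local:
      table:
        - ["0", "1", 0.4]
        - ["0", "2", 0.2]
        - ["0", "3", 0.1]
        - ["0", "4", 0.0]
        - ["0", "5", 0.0]
        - ["0", "6-7", 0.0]
        - ["1", "2", 0.6]
        - ["1", "3", 0.4]
        - ["1", "4", 0.2]
        - ["1", "5", 0.1]
        - ["1", "6-7", 0.0]
        - ["2", "3", 0.8]
        - ["2", "4", 0.5]
        - ["2", "5", 0.3]
        - ["2", "6-7", 0.2]
        - ["3", "4", 0.9]
        - ["3", "5", 0.7]
        - ["3", "6-7", 0.5]
        - ["4", "5", 0.9]
        - ["4", "6-7", 0.8]
        - ["5", "6-7", 1.0]
  - name: smoking
    kind: categorical
    domain: [smoker, non_smoker]
    weight: 1
    local: {table: [[smoker, non_smoker, 0.4]]}
  - name: alcohol_risk
    kind: categorical
    domain: [at_risk, not_at_risk]
    weight: 1
    local: {table: [[at_risk, not_at_risk, 0.5]]}
  - name: sleep_hours
    kind: numeric
    domain: [3, 12]
    weight: 2
    local: {plateau_width: 1, anchors: [[2, 0.6], [4, 0.2], [9, 0.0]]}
  - name: medication_use
    kind: categorical
    domain: [none, occasional, regular]
    weight: 2
    local:
      table:
        - [none, occasional, 0.6]
        - [occasional, regular, 0.6]
        - [none, regular, 0.2]
  - name: social_support
    kind: categorical
    domain: [good, moderate, poor]
    weight: 2
    local:
      table:
        - [good, moderate, 0.6]
        - [moderate, poor, 0.6]
        - [good, poor, 0.2]
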