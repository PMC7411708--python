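# Default CHEM21-style SH&E scoring rules.
#
# These band tables are an editable reconstruction of the CHEM21 rubric
# (safety from flammability, health from H3xx statements, environment from
# boiling point / H4xx / REACH status).  Edit a copy of this file and pass it
# to `Chem21Scorer(rules=...)` or `sussol score --rules ...` to change any
# threshold.  All scores are clamped to the 1-10 scale.

safety:
  # First matching band wins.  Conditions: fp_min (flash point >= x),
  # fp_below (flash point < x), bp_below (boiling point < x).
  bands:
    - {fp_below: -20, bp_below: 45, score: 8}   # cryogenic flash point AND highly volatile
    - {fp_min: 60, score: 1}
    - {fp_min: 24, score: 3}
    - {fp_min: 0, score: 5}
    - {fp_min: -20, score: 6}
    - {score: 7}                                # flash point below -20 degC
  missing_flash_point_score: 7                  # most conservative ordinary band
  low_autoignition_threshold: 200.0             # degC; below this adds one penalty point
  penalty: 1                                    # points per triggered penalty flag
  high_energy_decomposition_score: 10

health:
  # Worst (maximum) mapped H3xx statement sets the base score.  Codes are
  # matched on their 4-character stem, so H360FD matches H360.
  h3_scores:
    H300: 9
    H301: 7
    H302: 4
    H304: 4
    H310: 9
    H311: 7
    H312: 4
    H314: 5
    H315: 2
    H317: 4
    H318: 5
    H319: 2
    H330: 9
    H331: 7
    H332: 4
    H334: 6
    H335: 3
    H336: 3
    H340: 10
    H341: 7
    H350: 10
    H351: 7
    H360: 9
    H361: 6
    H362: 6
    H370: 8
    H371: 6
    H372: 8
    H373: 6
  no_statement_score: 1
  unknown_score: 5            # incomplete toxicological data
  low_bp_threshold: 85.0      # degC; boiling below this adds one penalty point
  low_bp_penalty: 1

environment:
  # First matching boiling-point band wins (min <= bp <= max).
  bp_bands:
    - {min: 70, max: 139, score: 3}   # ideal boiling range
    - {min: 50, max: 200, score: 5}   # just outside the ideal window
    - {score: 7}                      # very low boilers (emissions) / very high boilers (recycling)
  h4_scores:
    H400: 7
    H401: 5
    H402: 4
    H410: 7
    H411: 6
    H412: 5
    H413: 4
    H420: 10
  h420_score: 10              # ozone-layer hazard dominates everything
  unknown_score: 5            # incomplete environmental-toxicity data
  reach_adjustment:
    full: 0
    intermediate-only: 0
    unregistered: 1
    restricted: 2

ranking:
  # Overall Recommended / Problematic / Hazardous rule.  Approximate by
  # construction: no single threshold rule reproduces every published table.
  hazardous:
    safety_ge: 8
    health_ge: 9
    environment_ge: 10
    health_and_environment_ge: [7, 7]
  recommended_all_le: 3
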