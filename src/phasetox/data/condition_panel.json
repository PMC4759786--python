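[
  {"condition_id": "control", "substrates": [], "agonists": [], "blockers": [],
   "observed_significance": "ns", "observed_pct_id": 66.17, "observed_sem": 5.50,
   "n_cult": 16, "n_cell": 461},
  {"condition_id": "APV", "blockers": ["APV"],
   "observed_significance": "***", "observed_pct_id": 24.65, "observed_sem": 9.43,
   "n_cult": 8, "n_cell": 223},
  {"condition_id": "MK801", "blockers": ["MK801"],
   "observed_significance": "***", "observed_pct_id": 5.85, "observed_sem": 2.07,
   "n_cult": 8, "n_cell": 228},
  {"condition_id": "L-Lactate", "substrates": ["L-Lactate"],
   "observed_significance": "**", "observed_pct_id": 32.08, "observed_sem": 8.44,
   "n_cult": 15, "n_cell": 411},
  {"condition_id": "Pyruvate", "substrates": ["Pyruvate"],
   "observed_significance": "**", "observed_pct_id": 30.64, "observed_sem": 8.14,
   "n_cult": 10, "n_cell": 265},
  {"condition_id": "D-Lactate", "substrates": ["D-Lactate"],
   "observed_significance": "ns", "observed_pct_id": 60.76, "observed_sem": 9.52,
   "n_cult": 11, "n_cell": 305},
  {"condition_id": "D-Glucose", "substrates": ["D-Glucose"],
   "observed_significance": "ns", "observed_pct_id": 51.90, "observed_sem": 9.16,
   "n_cult": 10, "n_cell": 286},
  {"condition_id": "L-Lactate+UK5099", "substrates": ["L-Lactate"], "blockers": ["UK5099"],
   "observed_significance": "ns", "observed_pct_id": 60.71, "observed_sem": 9.70,
   "n_cult": 9, "n_cell": 248},
  {"condition_id": "ATPgS", "agonists": ["ATPgS"],
   "observed_significance": "**", "observed_pct_id": 32.68, "observed_sem": 8.51,
   "n_cult": 10, "n_cell": 271},
  {"condition_id": "Adenosine", "agonists": ["Adenosine"],
   "observed_significance": "ns", "observed_pct_id": 65.33, "observed_sem": 8.97,
   "n_cult": 10, "n_cell": 261},
  {"condition_id": "L-Lactate+Apyrase", "substrates": ["L-Lactate"], "blockers": ["Apyrase"],
   "observed_significance": "ns", "observed_pct_id": 67.40, "observed_sem": 8.89,
   "n_cult": 9, "n_cell": 210},
  {"condition_id": "L-Lactate+Apyrase+ATPgS", "substrates": ["L-Lactate"],
   "agonists": ["ATPgS"], "blockers": ["Apyrase"],
   "observed_significance": "**", "observed_pct_id": 33.74, "observed_sem": 8.71,
   "n_cult": 9, "n_cell": 219},
  {"condition_id": "L-Lactate+PPADS", "substrates": ["L-Lactate"], "blockers": ["PPADS"],
   "observed_significance": "ns", "observed_pct_id": 57.94, "observed_sem": 9.12,
   "n_cult": 10, "n_cell": 277},
  {"condition_id": "2MeSADP", "agonists": ["2MeSADP"],
   "observed_significance": "ns", "observed_pct_id": 45.62, "observed_sem": 5.86,
   "n_cult": 10, "n_cell": 280},
  {"condition_id": "L-Lactate+MRS2179", "substrates": ["L-Lactate"], "blockers": ["MRS2179"],
   "observed_significance": "*", "observed_pct_id": 33.08, "observed_sem": 8.70,
   "n_cult": 10, "n_cell": 273},
  {"condition_id": "UTPgS", "agonists": ["UTPgS"],
   "observed_significance": "*", "observed_pct_id": 34.19, "observed_sem": 9.46,
   "n_cult": 10, "n_cell": 276},
  {"condition_id": "L-Lactate+Probenecid", "substrates": ["L-Lactate"], "blockers": ["Probenecid"],
   "observed_significance": "ns", "observed_pct_id": 62.46, "observed_sem": 5.68,
   "n_cult": 10, "n_cell": 287},
  {"condition_id": "L-Lactate+Carbenoxolone", "substrates": ["L-Lactate"], "blockers": ["Carbenoxolone"],
   "observed_significance": "ns", "observed_pct_id": 57.15, "observed_sem": 7.45,
   "n_cult": 10, "n_cell": 285},
  {"condition_id": "L-Lactate+SQ22536", "substrates": ["L-Lactate"], "blockers": ["SQ22536"],
   "observed_significance": "***", "observed_pct_id": 34.63, "observed_sem": 7.60,
   "n_cult": 10, "n_cell": 248},
  {"condition_id": "L-Lactate+U0126", "substrates": ["L-Lactate"], "blockers": ["U0126"],
   "observed_significance": "***", "observed_pct_id": 35.69, "observed_sem": 7.91,
   "n_cult": 10, "n_cell": 273},
  {"condition_id": "L-Lactate+LY294002", "substrates": ["L-Lactate"], "blockers": ["LY294002"],
   "observed_significance": "ns", "observed_pct_id": 57.44, "observed_sem": 5.17,
   "n_cult": 10, "n_cell": 283},
  {"condition_id": "UTPgS+LY294002", "agonists": ["UTPgS"], "blockers": ["LY294002"],
   "observed_significance": "ns", "observed_pct_id": 56.06, "observed_sem": 5.03,
   "n_cult": 11, "n_cell": 312},
  {"condition_id": "L-Lactate+Glibenclamide", "substrates": ["L-Lactate"], "blockers": ["Glibenclamide"],
   "observed_significance": "ns", "observed_pct_id": 62.39, "observed_sem": 5.47,
   "n_cult": 10, "n_cell": 283},
  {"condition_id": "UTPgS+Glibenclamide", "agonists": ["UTPgS"], "blockers": ["Glibenclamide"],
   "observed_significance": "ns", "observed_pct_id": 60.30, "observed_sem": 4.41,
   "n_cult": 10, "n_cell": 296}
]
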