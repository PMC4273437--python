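{
  "description": "Per-compartment counts of anterior-medial-cluster (PAM) dopaminergic neurons, from split-GAL4 line labeling and from photoactivated-GFP tracing of each medial-lobe compartment. Mixture lines are counted once per compartment they label, so the totals over-count DAN types that innervate two compartments.",
  "compartments": ["g1", "g2", "g3", "g4", "g5", "bp1", "bp2", "b1", "b2"],
  "split_gal4": {
    "g1": 13, "g2": 13, "g3": 9, "g4": 13, "g5": 8,
    "bp1": 14, "bp2": 35, "b1": 5, "b2": 11
  },
  "pa_gfp": {
    "g1": 3.8, "g2": 7.8, "g3": 23.6, "g4": 17.3, "g5": 21.5,
    "bp1": 12.8, "bp2": 41.3, "b1": 6.6, "b2": 18.8
  }
}
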