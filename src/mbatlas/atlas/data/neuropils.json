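{
  "description": "Catalog of the 38 named adult central-brain regions used for projection quantification (standard insect-brain nomenclature), plus the five discrete neuropils onto which MBON axon terminals converge. Phantom volumes give geometry only to the MB lobes and the five convergence zones; the remaining regions may be empty.",
  "regions": [
    "AL", "AME", "AOTU", "ATL", "AVLP", "BU", "CAN", "CRE", "EB", "EPA",
    "FB", "FLA", "GA", "GNG", "GOR", "IB", "ICL", "IPS", "LAL", "LH",
    "MB-CA", "MB-ML", "MB-PED", "MB-VL", "NO", "PB", "PLP", "PRW", "PVLP",
    "ROB", "SAD", "SCL", "SIP", "SLP", "SMP", "SPS", "VES", "WED"
  ],
  "mb_regions": ["MB-ML", "MB-VL", "MB-PED", "MB-CA"],
  "mbon_projection_zones": ["CRE", "SMP", "SIP", "SLP", "LH"]
}
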