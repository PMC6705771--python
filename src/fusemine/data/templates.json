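{
  "default": {
    "positive": [
      "The {fusion} {keyword} was detected in bone marrow samples.",
      "Expression of the {fusion} {keyword} was confirmed by sequencing.",
      "We identified the {fusion} {keyword} in a cohort of patients.",
      "The {fusion} {keyword} encodes a constitutively active kinase."
    ],
    "interaction": [
      "{partner} {verb_3sg} the {fusion} {keyword}.",
      "{partner} was found to {verb} the {fusion} {keyword} in vitro.",
      "The adapter protein {partner} {verb_3sg} {fusion}.",
      "{partner} has been shown to {verb} {fusion}."
    ],
    "interaction_coordinated": [
      "{partner} has been shown to {verb} {fusion} and {fusion2}."
    ],
    "disease": [
      "The {fusion} {keyword} causes {disease}.",
      "The {fusion} {keyword} induces {disease} in mouse models."
    ],
    "distractor": [
      "Samples from {year1}-{year2} were analyzed retrospectively.",
      "Treatment with all-trans-retinoic acid improved outcomes.",
      "A dose-dependent response was observed across the cohort.",
      "Long-term follow-up confirmed a time-dependent effect.",
      "Patients received high-dose chemotherapy after enrollment."
    ],
    "negative": [
      "The {gene} gene was sequenced in all patients.",
      "Expression of {gene} was measured by quantitative PCR.",
      "We observed no aberration affecting {gene} in this cohort.",
      "Mutations in {gene} were rare among the screened samples."
    ]
  }
}
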