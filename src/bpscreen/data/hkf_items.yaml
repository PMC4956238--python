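# Item manifest of the HKF-R 10 (27 items; item 5 = average pain intensity of
# the last week on a 0-100 VAS, recorded but excluded from scoring).
# Completeness of a record is defined by this manifest.
items:
  - {id: 1,  scale_min: 0, scale_max: 1,   scored: true}    # gender
  - {id: 2,  scale_min: 0, scale_max: 4,   scored: true}    # graduation
  - {id: 3,  scale_min: 0, scale_max: 10,  scored: true}    # pain intensity
  - {id: 4,  scale_min: 0, scale_max: 10,  scored: true}    # pain intensity
  - {id: 5,  scale_min: 0, scale_max: 100, scored: false}   # last-week pain VAS, follow-up documentation only
  - {id: 6,  scale_min: 0, scale_max: 10,  scored: true}    # pain duration
  - {id: 7,  scale_min: 0, scale_max: 10,  scored: true}    # pain duration
  - {id: 8,  scale_min: 0, scale_max: 10,  scored: true}    # efficacy of massage
  - {id: 9,  scale_min: 0, scale_max: 10,  scored: true}    # depression scale (9-13)
  - {id: 10, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 11, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 12, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 13, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 14, scale_min: 0, scale_max: 10,  scored: true}    # catastrophising (14-18)
  - {id: 15, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 16, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 17, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 18, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 19, scale_min: 0, scale_max: 10,  scored: true}    # helpless-/hopelessness (19-27)
  - {id: 20, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 21, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 22, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 23, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 24, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 25, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 26, scale_min: 0, scale_max: 10,  scored: true}
  - {id: 27, scale_min: 0, scale_max: 10,  scored: true}
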