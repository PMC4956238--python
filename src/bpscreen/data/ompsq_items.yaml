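# Scored-item table of the German OMPSQ translation (21 scored items, IDs 5-25;
# sociodemographic items 1-4 are excluded from scoring).
#
# Which two items besides the pain-sites item use a 1-10 scale is a data
# choice, not a code path: this default assigns items 6 (sick-leave days,
# categorical) and 7 (pain duration, categorical) as a documented placeholder.
# Swap the table to score the original Swedish 4-210 variant.
max_substitutions: 3
risk_bands:           # total < low_below -> low; <= high_upto -> medium; else high
  low_below: 91
  high_upto: 106
items:
  - {id: 5,  scale_min: 1, scale_max: 6,  inverted: false, doubled: true,  checkbox: false}   # number of pain sites, six categories, counted twice
  - {id: 6,  scale_min: 1, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 7,  scale_min: 1, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 8,  scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: true}    # work item, "not working" box
  - {id: 9,  scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 10, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 11, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 12, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: false}
  - {id: 13, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 14, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 15, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 16, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: true}    # work item, inverted
  - {id: 17, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: true}    # work item, inverted
  - {id: 18, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 19, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 20, scale_min: 0, scale_max: 10, inverted: false, doubled: false, checkbox: false}
  - {id: 21, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: false}   # function items 21-25, inverted
  - {id: 22, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: false}
  - {id: 23, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: false}
  - {id: 24, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: false}
  - {id: 25, scale_min: 0, scale_max: 10, inverted: true,  doubled: false, checkbox: false}
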