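{
  "sets": {
    "WholeCellsNT-293T": 97,
    "MitoNT-293T": 65,
    "CytoNT-293T": 55,
    "MitoT-293T": 18,
    "CytoT-293T": 22,
    "MitoT-SH-SY5Y": 54,
    "CytoT-SH-SY5Y": 53,
    "ParkinTAP candidates": 203,
    "Mito": 99,
    "Cyto": 94,
    "MonogenicPD": 9,
    "Pink1TAP": 17,
    "ParkinIP": 77,
    "MonogenicPDIP": 668,
    "PINK1IP": 44,
    "RelatedPD": 80
  },
  "unions": {
    "Mito": ["MitoNT-293T", "MitoT-293T", "MitoT-SH-SY5Y"],
    "Cyto": ["CytoNT-293T", "CytoT-293T", "CytoT-SH-SY5Y"],
    "ParkinTAP candidates": [
      "WholeCellsNT-293T", "MitoNT-293T", "CytoNT-293T", "MitoT-293T",
      "CytoT-293T", "MitoT-SH-SY5Y", "CytoT-SH-SY5Y"
    ],
    "RelatedPD": ["ParkinIP", "MonogenicPD"]
  },
  "overlaps": {
    "ParkinTAP candidates|ParkinIP": [4, 3],
    "ParkinTAP candidates|MonogenicPD": [1, 0],
    "ParkinTAP candidates|MonogenicPDIP": [40, 39],
    "ParkinTAP candidates|Pink1TAP": [15, 15],
    "ParkinIP|MonogenicPD": [6, 5],
    "Mito|Cyto": [49, 49]
  },
  "bait_id": "5071"
}
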