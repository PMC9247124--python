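{
  "cholestasis": [
    [
      "BHLHE40",
      "down"
    ],
    [
      "CSRP1",
      "down"
    ],
    [
      "NQO1",
      "up"
    ],
    [
      "SLC16A10",
      "up"
    ],
    [
      "AGT",
      "down"
    ]
  ],
  "cirrhosis": [
    [
      "CSF1R",
      "down"
    ],
    [
      "EGR1",
      "up"
    ],
    [
      "GPNMB",
      "up"
    ],
    [
      "LPL",
      "up"
    ],
    [
      "HSD11B2",
      "down"
    ],
    [
      "MGAT2",
      "up"
    ],
    [
      "NR1D1",
      "up"
    ],
    [
      "S100A9",
      "up"
    ]
  ],
  "hepatitis": [
    [
      "SLC6A6",
      "down"
    ],
    [
      "CSRP1",
      "down"
    ],
    [
      "RAB30",
      "up"
    ],
    [
      "APOM",
      "up"
    ],
    [
      "PPP2R1B",
      "up"
    ],
    [
      "HMOX1",
      "up"
    ],
    [
      "TSR1",
      "down"
    ],
    [
      "EBNA1BP2",
      "unspecified"
    ],
    [
      "WDR77",
      "up"
    ]
  ],
  "steatosis": [
    [
      "CCL2",
      "up"
    ],
    [
      "ICAM1",
      "up"
    ],
    [
      "ME1",
      "up"
    ],
    [
      "SGK1",
      "up"
    ]
  ]
}
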