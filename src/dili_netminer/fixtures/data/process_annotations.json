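{
  "AGT": [
    "glucose homeostasis",
    "oxidative stress"
  ],
  "APOM": [
    "viral replication"
  ],
  "BHLHE40": [
    "general stress response"
  ],
  "CCL2": [
    "immune cell recruitment",
    "inflammation"
  ],
  "CSF1R": [
    "macrophage differentiation"
  ],
  "CSRP1": [
    "hepatic differentiation"
  ],
  "EBNA1BP2": [
    "viral replication"
  ],
  "EGR1": [
    "apoptosis",
    "oxidative stress"
  ],
  "GPNMB": [
    "Kupffer cell activation"
  ],
  "HMOX1": [
    "cytoprotection",
    "oxidative stress"
  ],
  "HSD11B2": [
    "NF-kB pathway activation"
  ],
  "ICAM1": [
    "apoptosis"
  ],
  "LPL": [
    "hepatic stellate cell activation"
  ],
  "ME1": [
    "fatty acid biosynthesis"
  ],
  "MGAT2": [
    "hepatic fibrosis"
  ],
  "NQO1": [
    "NRF2 activation",
    "oxidative stress",
    "detoxification",
    "cytoprotection"
  ],
  "NR1D1": [
    "macrophage response"
  ],
  "PPP2R1B": [
    "cell cycle arrest"
  ],
  "RAB30": [
    "autophagy"
  ],
  "S100A9": [
    "inflammation"
  ],
  "SGK1": [
    "general stress response",
    "oxidative stress"
  ],
  "SLC16A10": [
    "amino acid transport",
    "detoxification"
  ],
  "SLC6A6": [
    "mitochondrial dysfunction"
  ],
  "TSR1": [
    "DNA damage"
  ],
  "WDR77": [
    "viral replication"
  ]
}
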