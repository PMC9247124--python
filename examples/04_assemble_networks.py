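"""Assemble and merge the four curated disease networks.

Seeds are the packaged refined gene lists for cholestasis, steatosis,
hepatitis and cirrhosis; merging exposes the biological processes the
diseases share.
"""

from dili_netminer import datasets

for disease in datasets.DISEASES:
    net = datasets.disease_network(disease)
    print(f"{disease}: {len(net.seed_genes)} seeds, "
          f"{len(net.connector_genes)} connectors, {len(net.edges)} edges")

merged = datasets.merged_disease_network()
print("\nshared by all four diseases:", sorted(merged.processes_shared_by_all()))
print("cholestasis & hepatitis:",
      sorted(merged.processes_shared_by(["cholestasis", "hepatitis"])))
print("steatosis & cirrhosis:",
      sorted(merged.processes_shared_by(["steatosis", "cirrhosis"])))
# Oxidative stress appears in every disease network; cholestasis and
# hepatitis additionally share cytoprotection and hepatic differentiation,
# steatosis and cirrhosis share apoptosis.
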