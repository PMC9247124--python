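"""Select positive/negative reference chemicals from an evidence table.

Positives need literature evidence + expression data + a DILI knowledge-base
listing + post-market corroboration; negatives need expression data and no
literature association.
"""

from dili_netminer import select_reference_chemicals, summarize_overlap
from dili_netminer.simulate import SimulationConfig, gen_labels

cfg = SimulationConfig(disease_id="cholestasis")
labels = gen_labels(cfg)
refs = select_reference_chemicals(labels, "cholestasis", min_set_size=4)
print(f"cholestasis: {len(refs.positives)} positives, {len(refs.negatives)} negatives")
print("  positives:", ", ".join(sorted(refs.positives)))

cfg2 = SimulationConfig(disease_id="steatosis", n_chemicals_pos=4)
refs2 = select_reference_chemicals(gen_labels(cfg2), "steatosis", min_set_size=4)
overlap = summarize_overlap([refs, refs2])
print(overlap.to_string(index=False))
# Each Venn cell counts chemicals in exactly that disease subset; here the
# synthetic positives share 4 chemicals (POS01..POS04 exist in both tables).
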