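"""Molecular networking on a synthetic PEFA experiment.

Generates a seeded synthetic dataset (40 PEFA features, 20 decoys),
builds the modified-cosine network with the standard thresholds
(cosine > 0.7, >= 6 matched peaks, mutual top-10, family cap 100) and
prints the family structure.  PEFA analogs connect through shifted
peak matches; unstructured decoys stay singletons.
"""

from pefanet import GeneratorConfig, build_network, generate_dataset

dataset = generate_dataset(GeneratorConfig(seed=1))
network = build_network(dataset.spectra)

print(f"spectra    : {len(dataset.spectra)}")
print(f"edges      : {len(network.edges)}")
print(f"families   : {len(network.families)}")
print(f"singletons : {len(network.singletons)}")
for family in network.families:
    members = sorted(family.node_ids)
    kinds = {dataset.manifest["features"][m]["kind"] for m in members}
    print(f"  family {family.family_id}: {len(members)} nodes ({', '.join(sorted(kinds))})")
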