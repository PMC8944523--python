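"""Physicochemical properties of family proteins.

Molecular weight is the sum of average residue masses plus one water, in
kDa; pI is the pH where the Henderson-Hasselbalch net charge crosses zero
(bisection over an EMBOSS-style pKa table).
"""

from genefamkit.identify import DEFAULT_DOMAIN_CONSENSUS, DomainModel, identify_family
from genefamkit.properties import protein_properties
from genefamkit.synthetic import SyntheticConfig, generate_bundle

species = generate_bundle(SyntheticConfig(seed=1)).to_species_bundle()
model = DomainModel.from_consensus(DEFAULT_DOMAIN_CONSENSUS)
members = identify_family(species, model, "Gso", "GPX")

print(f"{'name':<12} {'aa':>4} {'MW (kDa)':>9} {'pI':>6}")
for m in members:
    p = protein_properties(m.protein)
    print(f"{m.name:<12} {p.length:>4} {p.mw_kda:>9.2f} {p.pi:>6.2f}")
# Lengths near 180 aa and weights near 20 kDa reflect the simulated family;
# pI above/below 7 indicates a basic/acidic protein.
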