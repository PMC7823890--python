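"""Exact monoisotopic masses and adduct m/z of PEFA glycolipids.

Builds the neutral formula of a mannitol-triacetyl 3-acetoxy-C16 ester
from its parts and prints its sodiated m/z under both charge-carrier
conventions.  The ~0.55 mDa gap between them is one electron mass —
visible at the fourth decimal of a high-resolution measurement.
"""

from pefanet import AdductSpec, ElementalFormula, PefaSpecies, adduct_mz, species_formula

species = PefaSpecies("mannitol", 3, 16, "acetoxy")
formula = species_formula(species)
print(f"species : {species.label()}")
print(f"formula : {formula} (neutral monoisotopic {formula.mass:.6f} Da)")

for convention in ("ion-mass", "atom-mass"):
    mz = adduct_mz(formula, AdductSpec("M+Na", convention))
    print(f"[M+Na]+ {convention:9s}: {mz:.4f}")

# assembling the same formula by hand: polyol + 3 acetyl increments
# + 3-acetoxyhexadecanoic acid - water for the ester bond
total = (
    ElementalFormula.parse("C6H14O6")
    + 3 * ElementalFormula.parse("C2H2O")
    + ElementalFormula.parse("C18H34O4")
    - ElementalFormula.parse("H2O")
)
print(f"assembled from parts: {total} (same: {total == formula})")
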