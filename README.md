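# pefanet

Molecular networking, bioactivity scoring and rule-based annotation of
**polyol esters of fatty acids (PEFAs)** from untargeted LC-MS/MS
metabolomics data.

PEFAs are glycolipid biosurfactants produced by *Rhodotorula* and related
basidiomycete yeasts: a sugar-alcohol head group (mannitol or arabitol,
carrying 0–5 O-acetyl groups) esterified to a 3-hydroxy or 3-acetoxy fatty
acid (C10–C20, even chains). Dozens of near-isobaric members co-elute in a
single extract, which makes them tedious to identify one by one — but their
MS/MS chemistry is so regular that identification can be reduced to
arithmetic. This package is for natural-product and metabolomics researchers
who want that arithmetic as a tested, scriptable pipeline.

## The method

Three diagnostic rules identify a PEFA from its positive-mode spectrum
([M+Na]⁺ precursor):

1. **Exact precursor mass.** Every theoretical species has formula
   `polyol + n·C2H2O + fatty acid − H2O`; its sodiated m/z is
   `M + m(Na) − m(e⁻)`. The default library enumerates 132 species
   (2 polyols × allowed acetylation × 6 chains × 2 C-3 substituents).
2. **Acetyl ladder.** Each acetyloxy group is lost as acetic acid,
   60.0211 Da. The number of sequential −60.0211 steps descending from the
   precursor counts the acetyl groups.
3. **Residual-polyol ion.** Loss of the intact fatty acid leaves the
   sodiated acetylated polyol (e.g. mannitol-triacetate at m/z 313.09),
   pinning down the head group and its acetylation degree.

A feature is annotated with the unique library species consistent with all
three, at 0.02 Da tolerances. Around the annotation engine sit the standard
stages of feature-based molecular networking: spectrum cleaning (±17 Da
precursor exclusion, top-6 peaks per ±50 Da window), **modified cosine**
similarity (√intensity weights, peak pairs matched directly or shifted by
the precursor mass difference, exact maximum one-to-one assignment), edge
thresholds (cosine > 0.7, ≥ 6 matched peaks, mutual top-10), molecular
families capped at 100 nodes, **bioactive molecular networking**
(TIC normalization, per-feature Pearson *r* against fraction bioactivity,
flag at *r* > 0.5), and group-origin analysis across culture conditions.

A seeded synthetic-data generator emulates the whole experiment — PEFA
spectra with jitter and noise, decoys, fraction abundance profiles, planted
bioactive features, blanks — with a ground-truth manifest, so every stage is
testable end to end.

## Worked example

```python
import numpy as np
from pefanet import FragmentSpectrum, annotate_feature, enumerate_library

spectrum = FragmentSpectrum(
    "feature_1", precursor_mz=627.3346,
    mz=np.array([313.0904, 447.2723, 507.2916, 567.3137]),
    intensity=np.array([1.0, 0.4, 0.6, 0.9]),
)
a = annotate_feature(spectrum, enumerate_library())
print(a.matched_species.label(), a.ladder_count, a.confidence)
```

prints

```
mannitol-3Ac-C16-3acetoxy 3 full
```

— the precursor matches the mannitol-triacetyl 3-acetoxy-C16 ester at
−0.8 ppm, the three fragments 567.31/507.29/447.27 form a three-step acetyl
ladder, and 313.0904 is the mannitol-triacetate residual ion, so the call is
made with full fragment-level confidence. More narrative scripts live in
`examples/` (exact masses, spectrum annotation, networking, bioactivity
scoring, the full file-based pipeline); the `pefanet` command
exposes the same stages as `net`, `annotate`, `bmn`, `compare`, `simulate`
and `libgen` subcommands.

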