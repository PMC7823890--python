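"""Rule-based annotation of one observed PEFA spectrum.

Feeds the annotation engine an observed sodiated precursor with four
fragments: a three-step 60.0211 Da acetic-acid-loss ladder plus the
residual mannitol-triacetate ion at m/z 313.09.  The engine counts the
ladder, identifies the head group from the residual ion, and picks the
unique library species consistent with both.
"""

import numpy as np

from pefanet import FragmentSpectrum, annotate_feature, enumerate_library

spectrum = FragmentSpectrum(
    "feature_1",
    precursor_mz=627.3346,
    mz=np.array([313.0904, 447.2723, 507.2916, 567.3137]),
    intensity=np.array([1.0, 0.4, 0.6, 0.9]),
)

annotation = annotate_feature(spectrum, enumerate_library())
print(f"feature        : {annotation.feature_id}")
print(f"annotation     : {annotation.matched_species.label()}")
print(f"precursor error: {annotation.precursor_error_ppm:+.1f} ppm")
print(f"acetyl ladder  : {annotation.ladder_count} sequential 60.0211 Da losses")
r = annotation.residual_ion_match
print(f"residual ion   : {r.polyol} with {r.acetyl_count} acetyls "
      f"(obs {r.observed_mz:.4f}, pred {r.predicted_mz:.4f})")
print(f"confidence     : {annotation.confidence}")
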