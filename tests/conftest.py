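import numpy as np
import pytest

from pefanet import (
    FragmentSpectrum,
    LibraryConfig,
    enumerate_library,
)


@pytest.fixture(scope="session")
def default_library():
    return enumerate_library(LibraryConfig())


@pytest.fixture(scope="session")
def compound_spectra():
    """Published high-resolution spectra of the three ladder-bearing isolates.

    Observed precursor and fragment m/z values of the mannitol
    triacetyl C16 acetoxy ester (3 acetyl losses + residual ion), the
    mannitol monoacetyl C16 acetoxy ester (2 losses) and the mannitol
    tetraacetyl C18 acetoxy ester (4 losses), as read from the
    experimental HR-MS/MS fragment lists.
    """
    return {
        "compound1": {
            "precursor": 627.3346,
            "fragments": [567.3137, 507.2916, 447.2723, 313.0904],
            "ladder": 3,
            "species": ("mannitol", 3, 16, "acetoxy"),
        },
        "compound2": {
            "precursor": 543.3141,
            "fragments": [483.2929, 423.27, 229.0757],
            "ladder": 2,
            "species": ("mannitol", 1, 16, "acetoxy"),
        },
        "compound3": {
            "precursor": 697.3789,
            "fragments": [637.3586, 577.3372, 517.3150, 457.2921, 355.1011, 295.0796],
            "ladder": 4,
            "species": ("mannitol", 4, 18, "acetoxy"),
        },
    }


def random_spectrum(rng, n_peaks, feature_id="q", precursor=None):
    """Small random spectrum for property tests."""
    if precursor is None:
        precursor = float(rng.uniform(300, 800))
    mz = np.sort(rng.uniform(80, precursor - 20, size=n_peaks))
    intensity = rng.uniform(0.05, 1.0, size=n_peaks)
    return FragmentSpectrum(feature_id, precursor, mz=mz, intensity=intensity)
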