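import numpy as np
import pandas as pd
import pytest

from dichroma.spectra_io import DEFAULT_WL, SpectrumSet
from dichroma.visual_model import VisualSystem


def make_set(wl, refl, sexes=None, region="Abdomen", individuals=None):
    """Assemble a SpectrumSet with minimal metadata."""
    refl = np.atleast_2d(np.asarray(refl, float))
    if refl.shape[0] != len(wl):
        refl = refl.T
    n = refl.shape[1]
    sexes = ["M"] * n if sexes is None else list(sexes)
    individuals = [f"ind{i}" for i in range(n)] if individuals is None else list(individuals)
    meta = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(n)],
        "individual_id": individuals,
        "sex": sexes,
        "region": region,
        "patch_index": range(n),
    })
    return SpectrumSet(np.asarray(wl, float), refl, meta)


@pytest.fixture(scope="session")
def wl():
    return DEFAULT_WL


@pytest.fixture(scope="session")
def ideal_vs(wl):
    """Equal cone abundances under a flat illuminant: the analytic case."""
    return VisualSystem.build(wl=wl, scheme="equal", illuminant="ideal")


@pytest.fixture(scope="session")
def default_vs(wl):
    """The reporting default: LWS-emphasis ratios, blue-sky illuminant."""
    return VisualSystem.build(wl=wl)
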