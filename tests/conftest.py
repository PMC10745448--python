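import numpy as np
import pandas as pd
import pytest

from nirerr.spectra import DesignTable, SpectraSet, WavelengthGrid


def make_set(x, wavelengths=None, design=None, **design_cols):
    """Build a SpectraSet from a raw matrix with minimal boilerplate."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float) + 1000.0
    if design is None:
        if not design_cols:
            design_cols = {"sample": ["S1"] * n}
        design = pd.DataFrame(design_cols)
    return SpectraSet(
        x=x, grid=WavelengthGrid(np.asarray(wavelengths, float)),
        design=DesignTable(design),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def balanced_session_set(rng):
    """45 spectra: 3 sessions x 15 replicates of one sample, 6 channels."""
    n, p = 45, 6
    design = pd.DataFrame({
        "sample": ["S1"] * n,
        "session": [str(1 + i // 15) for i in range(n)],
        "replicate_order": [str(1 + i % 15) for i in range(n)],
    })
    x = 0.5 + 0.01 * rng.standard_normal((n, p))
    return make_set(x, design=design)
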