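import logging

import numpy as np
import pytest

from mobiseg.preprocess import FilterSpec, lowpass_filter

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def fspec() -> FilterSpec:
    return FilterSpec()


@pytest.fixture(scope="session")
def filt(fspec):
    """Filter a recording channel's resultant the way the detectors do."""

    def _filt(rec, kind: str, location: str) -> np.ndarray:
        x = rec.gyr_magnitude(location) if kind == "gyr" else rec.acc_magnitude(location)
        return lowpass_filter(x, fspec, rec.fs)

    return _filt


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240402)
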