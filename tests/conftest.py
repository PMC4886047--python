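import numpy as np
import pandas as pd
import pytest

from msiclassify.io import MSIDataset, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(intensity, mz=None, x=1, y=1, patient_id="p1"):
    intensity = np.asarray(intensity, dtype=float)
    if mz is None:
        mz = 3000.0 + np.arange(intensity.size, dtype=float)
    return Spectrum(np.asarray(mz, dtype=float), intensity, x, y, patient_id)


def make_dataset(spectra, classes=None):
    pids = sorted({s.patient_id for s in spectra})
    classes = classes or {}
    md = pd.DataFrame(
        [
            {
                "patient_id": p,
                "cytological_class": classes.get(p, ("THY2", None))[0],
                "histological_class": classes.get(p, (None, None))[1],
            }
            for p in pids
        ]
    )
    return MSIDataset(spectra, md)


@pytest.fixture
def gaussian_spectrum():
    """One clean Gaussian peak of apex 10 on a flat zero background."""
    mz = 9000.0 + np.arange(401.0)
    intensity = 10.0 * np.exp(-0.5 * ((mz - 9200.0) / 6.0) ** 2)
    return Spectrum(mz, intensity, 1, 1, "p1")
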