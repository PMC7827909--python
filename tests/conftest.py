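"""Shared fixtures: small deterministic datasets and simulated studies."""

import numpy as np
import pytest

import smearmsi as sm


@pytest.fixture(scope="session")
def tiny_dataset() -> sm.MSIDataset:
    """A handmade 3x3 continuous-mode dataset with two peaks.

    Peak A at 250.000 everywhere; peak B at 400.010 only in the center
    pixel (1, 1).  Intensities are simple integers so expectations can be
    written by hand.
    """
    axis = np.array([249.99, 250.0, 250.01, 400.0, 400.01, 400.02])
    spectra = []
    for j in range(3):
        for i in range(3):
            inten = np.array([1.0, 4.0, 1.0, 0.0, 0.0, 0.0])
            if (i, j) == (1, 1):
                inten[3:] = [2.0, 8.0, 2.0]
            spectra.append(sm.Spectrum(axis, inten))
    return sm.MSIDataset(
        n_x=3, n_y=3, pitch_x=8.0, pitch_y=7.0, polarity=-1,
        matrix_label="9AA", setting_label="D0", mz_range=(200.0, 600.0),
        spectra=spectra, uniform_axis=axis, dataset_id="tiny",
    )


@pytest.fixture(scope="session")
def small_smear():
    """One simulated 24x24 smear (negative mode, default enrichment)."""
    cfg = sm.SmearSimConfig(n_x=24, n_y=24, seed=11)
    return sm.generate_smear(cfg)


@pytest.fixture(scope="session")
def small_study():
    """A 6-donor simulated study on the 200-600 Da window."""
    cfg = sm.SmearSimConfig(n_x=24, n_y=24, seed=5)
    return sm.generate_study(cfg, n_donors=6)


@pytest.fixture(scope="session")
def bundled_db():
    return sm.bundled_metabolite_table()
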