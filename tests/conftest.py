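import numpy as np
import pytest
from hypothesis import settings

import pollensig as ps
from pollensig.datamodel import EmissionSpectrum, PollenLoadSpectra, grid_length

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_record(load_id="load-1", species="sp", fill=None):
    """A well-formed spectroscopy record; fill maps excitation -> constant value."""
    fill = fill or {}
    spectra = {
        exc: EmissionSpectrum(exc, np.full(grid_length(exc), float(fill.get(exc, 1.0))))
        for exc in ps.EXCITATION_WAVELENGTHS
    }
    return PollenLoadSpectra(load_id=load_id, species=species, spectra=spectra)


@pytest.fixture(scope="session")
def sim_small():
    """A small labelled campaign: 4 species x 8 loads, 1 spectroscopy drop."""
    cfg = ps.SimConfig(seed=11, n_species=4, loads_per_species=8, n_dropped=1)
    return cfg, ps.make_dataset(cfg)


@pytest.fixture(scope="session")
def default_campaign():
    """The default-scale campaign: 14 species x 24 loads, 3 drops."""
    cfg = ps.SimConfig(seed=1)
    return cfg, ps.make_dataset(cfg)
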