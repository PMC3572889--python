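import numpy as np
import pytest

from filmdose import (ChannelMap, DoseMap, FilmRenderSpec, SourceModel,
                      ebt_reference_model, line_source_dose_field)


@pytest.fixture(scope="session")
def ebt_model():
    """Reference EBT red-channel calibration curve on NOD in [0.1, 1.2]."""
    return ebt_reference_model()


@pytest.fixture(scope="session")
def line_source():
    """Source delivering 5 Gy at 2 cm axial / 2 cm lateral over 671.3 s."""
    return SourceModel.calibrated(dose_gy=5.0, at_mm=(20.0, 20.0))


@pytest.fixture(scope="session")
def phantom_field(line_source):
    """In-phantom film-plane dose field, all doses inside the calibrated
    dose range of the reference curve."""
    return line_source_dose_field(line_source, ((-50.0, 50.0), (12.0, 52.0)),
                                  spacing_mm=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def constant_map(value, shape=(10, 12), spacing=0.254):
    return ChannelMap(values=np.full(shape, float(value)),
                      pixel_spacing_mm=spacing)


@pytest.fixture
def radial_dose_map():
    """D(r) = 4 / r^2 Gy (r in cm) sampled on a 12x12 cm grid at 0.5 mm."""
    s = 0.5
    n = 240
    x = (np.arange(n) + 0.5) * s - 60.0
    xx, yy = np.meshgrid(x, x, indexing="ij")
    r_cm = np.hypot(xx, yy) / 10.0
    return DoseMap(values=4.0 / r_cm ** 2, pixel_spacing_mm=s,
                   origin_mm=(-60.0, -60.0))
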