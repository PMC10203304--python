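import numpy as np
import pytest

from photogranule import DepthProfile, GranuleGeometry


@pytest.fixture
def geometry() -> GranuleGeometry:
    return GranuleGeometry(1800.0)


def uniform_consumption_profile(
    depths_um,
    radius_um: float = 1800.0,
    q_umol_per_l_per_s: float = 0.5,
    d_um2_per_s: float = 2000.0,
    bulk_umol_per_l: float = 250.0,
) -> DepthProfile:
    """Closed-form steady profile for uniform zero-order consumption.

    C(r) = C_R − q (R² − r²) / (6 D): exactly quadratic in r, so the
    shell inversion must recover −q in every shell.
    """
    z = np.asarray(depths_um, dtype=float)
    r = radius_um - z
    conc = bulk_umol_per_l - q_umol_per_l_per_s * (radius_um**2 - r**2) / (6 * d_um2_per_s)
    return DepthProfile(analyte="oxygen", depths_um=z, conc_umol_per_l=conc)
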