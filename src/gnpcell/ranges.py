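"""Electron range-energy relation in water, shared by source and transport.

R(E) = k·E^p with E in keV, fitted to published electron range
tabulations in water: R(1 keV) ≈ 0.05 µm, R(10 keV) ≈ 2.5 µm.
"""

from __future__ import annotations

import numpy as np

DEFAULT_RANGE_COEFF_UM = 0.05
DEFAULT_RANGE_EXPONENT = 1.7


def electron_range_um(
    energy_kev,
    coeff: float = DEFAULT_RANGE_COEFF_UM,
    exponent: float = DEFAULT_RANGE_EXPONENT,
):
    """Continuous-slowing-down range in water, µm."""
    return coeff * np.asarray(energy_kev) ** exponent
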