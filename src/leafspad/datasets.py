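"""Packaged worked-example data.

The reference case is one rice blade under light nitrogen deficiency
(150 kg N ha^-1) at panicle initiation: the ten per-part SPAD values
(base to tip) and the fitted quadratic chlorophyll profile

    SPAD(L) = -0.0452 L^2 + 1.1289 L + 33.763   (L in cm from the base).

The arithmetic mean of the ten parts is 38.42; entering it into the profile
gives the conventional representative positions 5.21 and 19.76 cm from the
base (about 1/5 and 4/5 of the blade).
"""

from __future__ import annotations

import numpy as np

from .containers import ChlorophyllProfile

__all__ = ["REFERENCE_SPAD_PARTS", "REFERENCE_LENGTH_CM", "reference_profile"]

#: Mean SPAD of the ten equal-length parts, base to tip.
REFERENCE_SPAD_PARTS = np.array(
    [35.8, 36.5, 39.2, 40.3, 40.6, 39.8, 41.2, 39.4, 37.1, 34.3]
)

#: Representative blade length (cm); the profile's vertex then sits at
#: ~50 % of the blade, matching the observed 50-60 % peak position.
REFERENCE_LENGTH_CM = 25.2


def reference_profile(length_cm: float = REFERENCE_LENGTH_CM) -> ChlorophyllProfile:
    """The reference quadratic chlorophyll profile (see module docstring)."""
    return ChlorophyllProfile(a2=-0.0452, a1=1.1289, a0=33.763,
                              length_cm=length_cm)
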