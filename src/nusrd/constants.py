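"""Magnetic-field / frequency conversion constants.

The proton base frequency is calibrated so that an 18.8 T magnet corresponds to
an 800.13 MHz spectrometer, matching the common vendor labelling of that field
class; other nuclei follow from their frequency ratios relative to 1H.
"""

from __future__ import annotations

#: 1H Larmor frequency per tesla, MHz/T (18.8 T -> 800.13 MHz).
PROTON_MHZ_PER_TESLA = 800.13 / 18.8

#: Larmor frequency ratios Xi = nu(X) / nu(1H).
GAMMA_RATIO = {
    "1H": 1.0,
    "15N": 0.101329118,
    "13C": 0.251449530,
    # carbonyl carbon is plain 13C for frequency purposes
    "13CO": 0.251449530,
}

DEFAULT_FIELD_TESLA = 18.8


def larmor_mhz(field_tesla: float, nucleus: str) -> float:
    """Larmor frequency (MHz) of *nucleus* at the given static field."""
    try:
        ratio = GAMMA_RATIO[nucleus]
    except KeyError:
        raise ValueError(f"unknown nucleus {nucleus!r}; known: {sorted(GAMMA_RATIO)}")
    return PROTON_MHZ_PER_TESLA * field_tesla * ratio
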