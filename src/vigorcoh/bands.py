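"""Beta sub-band definitions.

"Beta" is not treated as a unitary rhythm: low and high sub-bands can show
opposite behavioral correlations, so every spectral/connectivity operation
is parameterized by an explicit band.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name!r}: need f_lo < f_hi, got "
                             f"({self.f_lo}, {self.f_hi})")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: The three beta sub-bands used throughout: low (8-15 Hz), standard
#: (15-25 Hz, centered on the ~20 Hz range most targeted by neurostimulation),
#: and high (25-35 Hz).
BAND_PRESETS: dict[str, Band] = {
    "low": Band("low", 8.0, 15.0),
    "standard": Band("standard", 15.0, 25.0),
    "high": Band("high", 25.0, 35.0),
}


def get_band(band: "str | Band") -> Band:
    """Resolve a band name or pass a Band through."""
    if isinstance(band, Band):
        return band
    try:
        return BAND_PRESETS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; presets: {sorted(BAND_PRESETS)}"
        ) from None
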