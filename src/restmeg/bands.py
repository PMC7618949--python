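"""Canonical frequency band definitions.

The six bands used throughout the pipeline: delta 1-4 Hz, theta 4-7 Hz,
alpha 7-13 Hz, beta 13-30 Hz, low-gamma 30-48 Hz and high-gamma 52-80 Hz.
The 48-52 Hz gap between the gamma bands is the line-noise notch region and
is deliberately left uncovered. Bands are half-open intervals [lo, hi) so
adjacent bands never share a frequency bin.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """Half-open frequency interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, f: float) -> bool:
        return self.lo <= f < self.hi


DELTA = Band("delta", 1.0, 4.0)
THETA = Band("theta", 4.0, 7.0)
ALPHA = Band("alpha", 7.0, 13.0)
BETA = Band("beta", 13.0, 30.0)
LOW_GAMMA = Band("low_gamma", 30.0, 48.0)
HIGH_GAMMA = Band("high_gamma", 52.0, 80.0)

CANONICAL_BANDS: tuple[Band, ...] = (DELTA, THETA, ALPHA, BETA, LOW_GAMMA, HIGH_GAMMA)
BANDS: dict[str, Band] = {b.name: b for b in CANONICAL_BANDS}

#: Bands searched for oscillatory peaks in the spectral-shape analysis.
PEAK_BANDS: dict[str, Band] = {"alpha": ALPHA, "beta": BETA}


def get_band(band) -> Band:
    """Coerce a band name, (lo, hi) pair or Band instance to a Band."""
    if isinstance(band, Band):
        return band
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    lo, hi = band
    return Band(f"{lo:g}-{hi:g}Hz", float(lo), float(hi))
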