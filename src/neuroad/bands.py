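"""EEG frequency-band definitions.

Two presets are shipped because consumer single-electrode devices and the
clinical EEG literature draw the band edges differently:

``device``
    The ThinkGear-style edges reported by the acquisition chipset
    (overlapping Alpha/Beta boundaries, Gamma extending to Nyquist).
``classic``
    A traditional clinical partition (Delta 1-3 Hz ... Gamma II 41-50 Hz).
    Note the printed clinical list leaves gaps between some bands; it is
    provided verbatim rather than silently regularized.

All bands are half-open intervals ``[low, high)`` in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinitions:
    """Ordered band-name -> (low, high) map, ascending in low edge."""

    bands: tuple[tuple[str, tuple[float, float]], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        lows = []
        for name, (low, high) in self.bands:
            if not low < high:
                raise ValueError(f"band {name!r}: low {low} must be < high {high}")
            lows.append(low)
        if any(b <= a for a, b in zip(lows, lows[1:])):
            raise ValueError("bands must be listed in ascending low-edge order")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for band, lims in self.bands:
            if band == name:
                return lims
        raise KeyError(name)

    def items(self):
        return iter(self.bands)

    def capped(self, nyquist: float) -> "BandDefinitions":
        """Clip band highs at the Nyquist frequency, dropping empty bands."""
        kept = []
        for name, (low, high) in self.bands:
            if low >= nyquist:
                continue
            kept.append((name, (low, min(high, nyquist))))
        if not kept:
            raise ValueError(f"no band lies below the Nyquist frequency {nyquist} Hz")
        return BandDefinitions(tuple(kept))


DEVICE_BANDS = BandDefinitions(
    (
        ("Delta", (0.5, 4.0)),
        ("Theta", (4.0, 8.0)),
        ("LowAlpha", (7.5, 9.0)),
        ("HighAlpha", (9.5, 12.5)),
        ("LowBeta", (12.0, 15.0)),
        ("HighBeta", (15.0, 18.0)),
        ("LowGamma", (30.0, 80.0)),
        ("HighGamma", (80.0, math.inf)),
    )
)

CLASSIC_BANDS = BandDefinitions(
    (
        ("Delta", (1.0, 3.0)),
        ("Theta", (4.0, 7.0)),
        ("LowAlpha", (8.0, 9.0)),
        ("HighAlpha", (10.0, 12.0)),
        ("LowBeta", (13.0, 17.0)),
        ("HighBeta", (18.0, 30.0)),
        ("LowGamma", (31.0, 40.0)),
        ("HighGamma", (41.0, 50.0)),
    )
)

BAND_PRESETS: dict[str, BandDefinitions] = {
    "device": DEVICE_BANDS,
    "classic": CLASSIC_BANDS,
}
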