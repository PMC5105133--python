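"""Time-frequency grid: four analysis periods x four frequency bands.

The epoch (-0.3 s to +1.3 s around stimulus onset) is divided into four
contiguous periods -- pre-stimulus (1#), pre-processing (2#), P300
processing (3#) and post-response (4#) -- and the spectrum into the four
classical EEG bands delta/theta/alpha/beta.  Every divisional coherence
map, statistical matrix and network is indexed by this 4x4 grid.

Interval convention: all intervals are left-closed, right-open, so a
boundary sample/frequency belongs to the later period / higher band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_PERIODS: dict[str, tuple[float, float]] = {
    "1#": (-0.300, 0.000),
    "2#": (0.000, 0.250),
    "3#": (0.250, 0.600),
    "4#": (0.600, 1.300),
}

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta")
PERIOD_ORDER = ("1#", "2#", "3#", "4#")


@dataclass(frozen=True)
class TFGrid:
    """The divisional grid of analysis periods and frequency bands."""

    periods: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PERIODS)
    )
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        pv = list(self.periods.values())
        for (a, b) in pv:
            if not b > a:
                raise ValueError(f"degenerate period ({a}, {b})")
        for (lo, hi), (lo2, _) in zip(pv, pv[1:]):
            if not np.isclose(hi, lo2):
                raise ValueError("periods must be contiguous and non-overlapping")
        bv = list(self.bands.values())
        for (lo, hi) in bv:
            if not hi > lo >= 0:
                raise ValueError(f"degenerate band ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(bv, bv[1:]):
            if lo2 < hi:
                raise ValueError("bands must be non-overlapping and ordered")

    @property
    def epoch_window(self) -> tuple[float, float]:
        pv = list(self.periods.values())
        return pv[0][0], pv[-1][1]

    def period_mask(self, name: str, time_axis: np.ndarray) -> np.ndarray:
        lo, hi = self.periods[name]
        # boundary sample belongs to the later period; the final period is
        # closed on the right so the last epoch sample is not orphaned
        last = name == list(self.periods)[-1]
        m = (time_axis >= lo - 1e-12) & (time_axis < hi - 1e-12)
        if last:
            m |= np.isclose(time_axis, hi)
        return m

    def band_mask(self, name: str, freq_axis: np.ndarray) -> np.ndarray:
        lo, hi = self.bands[name]
        return (freq_axis >= lo) & (freq_axis < hi)
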