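"""Canonical frequency-band definitions for relative band power.

The five-band scheme used throughout the package: δ (1–4 Hz), θ (4–8 Hz),
α (8–13 Hz), β (13–30 Hz) and γ (30–77.5 Hz).  The γ band carries two
excluded sub-intervals, 47.5–52.5 Hz and 57.5–62.5 Hz, so that power-line
noise at either 50 or 60 Hz never contributes, and is capped at 77.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with optional excluded sub-intervals.

    Parameters
    ----------
    name : str
        Band name ("delta", "theta", ...).
    low, high : float
        Band edges in Hz.  Integration uses the half-open interval
        ``[low, high)`` on frequency-bin centres, so a shared edge
        (e.g. 4 Hz) belongs to the upper band only.
    exclusions : tuple of (float, float)
        Sub-intervals excluded from the band, same half-open rule.
    """

    name: str
    low: float
    high: float
    exclusions: Tuple[Tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low must be < high")
        for lo, hi in self.exclusions:
            if not (self.low <= lo < hi <= self.high):
                raise ValueError(
                    f"band {self.name!r}: exclusion ({lo}, {hi}) not nested "
                    f"within [{self.low}, {self.high}]"
                )

    @property
    def effective_width(self) -> float:
        """Band width in Hz after removing excluded sub-intervals."""
        return (self.high - self.low) - sum(hi - lo for lo, hi in self.exclusions)


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 77.5, ((47.5, 52.5), (57.5, 62.5)))

#: The standard five-band scheme, in canonical order.
STANDARD_BANDS: Tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

#: Canonical band names, in order.
BAND_NAMES: Tuple[str, ...] = tuple(b.name for b in STANDARD_BANDS)


def get_band(name: str, bands: Sequence[BandDefinition] = STANDARD_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")
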