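"""Spectral-channel intensities and normalized autofluorescence fractions.

The relative autofluorescence intensity of channels 1-3 (372 nm excitation)
is expressed as a fraction of their summed signal, F_n = I_n / (I1+I2+I3).
Channel 4 (438 nm excitation) uses a separate laser and fibre path, so it is
recorded but never enters the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import DecayHistogram

__all__ = ["ChannelIntensities", "integrate_histogram", "normalized_fractions"]


@dataclass
class ChannelIntensities:
    """Background-corrected total counts per detection channel."""

    i1: float
    i2: float
    i3: float
    i4: float = 0.0
    acquisition_time: float = 1.0  # seconds

    def __post_init__(self) -> None:
        if min(self.i1, self.i2, self.i3, self.i4) < 0:
            raise ValueError("channel intensities must be non-negative")

    def fractions(self) -> tuple[float, float, float]:
        return normalized_fractions(self.i1, self.i2, self.i3)


def integrate_histogram(hist: DecayHistogram, offset_C: float = 0.0) -> float:
    """Total counts with the constant background offset removed.

    ``offset_C`` is the fitted per-bin dark/ambient offset; the result is
    clipped at zero.
    """
    if offset_C < 0:
        raise ValueError("offset_C must be non-negative")
    return max(hist.total - offset_C * hist.n_bins, 0.0)


def normalized_fractions(i1: float, i2: float, i3: float) -> tuple[float, float, float]:
    """Channel fractions F_n = I_n / (I1 + I2 + I3); they sum to one."""
    if min(i1, i2, i3) < 0:
        raise ValueError("intensities must be non-negative")
    total = i1 + i2 + i3
    if total <= 0:
        raise ValueError("zero total intensity: unusable measurement")
    return (i1 / total, i2 / total, i3 / total)
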