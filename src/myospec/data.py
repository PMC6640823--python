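"""Core data containers.

All time-resolved quantities live on a single uniform time grid: ``n_bins``
bins of width ``bin_width`` picoseconds spanning (up to one bin short of) one
laser repetition period ``rep_period`` nanoseconds.  At the 20 MHz repetition
rate used throughout, the period is 50 ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

SPECTRUM_KINDS = ("raw", "reference", "absorbance", "normalized_absorbance")


@dataclass
class DecayHistogram:
    """Binned photon counts for one measurement in one detection channel.

    Parameters
    ----------
    counts : array of shape (n_bins,)
        Photon counts per time bin.  Non-negative; integral for measured
        data (float values are permitted so noiseless simulator output can
        be carried in the same container).
    bin_width : float
        Bin width in picoseconds.
    rep_period : float
        Laser repetition period in nanoseconds (50 ns at 20 MHz).
    channel : int
        Detection channel 1-4 (410/455/525 nm bands at 372 nm excitation;
        channel 4 is the 525 nm band at 438 nm excitation).
    meta : dict
        Free-form provenance (animal, ROI, position, repeat, ...).
    """

    counts: np.ndarray
    bin_width: float
    rep_period: float
    channel: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.n_bins < 64:
            raise ValueError(f"need at least 64 bins, got {self.n_bins}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            bad = int(np.argmax(self.counts < 0))
            raise ValueError(f"negative count at bin {bad}")
        if self.channel not in (1, 2, 3, 4):
            raise ValueError(f"channel must be 1-4, got {self.channel}")
        if self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("bin_width and rep_period must be positive")
        # window may not exceed the repetition period (one-bin tolerance)
        window_ns = self.n_bins * self.bin_width / 1000.0
        if window_ns > self.rep_period + self.bin_width / 1000.0:
            raise ValueError(
                f"time window {window_ns:.3f} ns exceeds repetition period "
                f"{self.rep_period:.3f} ns"
            )

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def times_ns(self) -> np.ndarray:
        """Left bin edges in nanoseconds."""
        return np.arange(self.n_bins) * (self.bin_width / 1000.0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class InstrumentResponse:
    """Reference-dye histogram used as the instrument response function.

    The IRF is measured with a short-lifetime (~200 ps) reference dye, so the
    raw histogram is the instrument temporal response slightly broadened by
    the dye decay.  :meth:`kernel` returns the background-subtracted,
    unit-area copy used for reconvolution.
    """

    counts: np.ndarray
    bin_width: float
    rep_period: float
    reference_lifetime: float = 200.0  # ps, nominal dye lifetime
    channel: int | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 64:
            raise ValueError("IRF requires a 1-d histogram with >= 64 bins")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("IRF counts must be finite and non-negative")
        if self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("bin_width and rep_period must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def background(self, pre_rise_frac: float = 0.05) -> float:
        """Background level estimated from the earliest (pre-rise) bins."""
        k = max(1, int(round(pre_rise_frac * self.n_bins)))
        return float(self.counts[:k].mean())

    def kernel(self, pre_rise_frac: float = 0.05) -> np.ndarray:
        """Background-subtracted, unit-area IRF for reconvolution."""
        c = np.clip(self.counts - self.background(pre_rise_frac), 0.0, None)
        s = c.sum()
        if s <= 0:
            raise ValueError("IRF has no signal above background")
        return c / s


@dataclass
class Spectrum:
    """Wavelength-indexed intensity or absorbance spectrum."""

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray
    kind: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-d arrays")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if self.kind in ("raw", "reference"):
            finite = self.values[np.isfinite(self.values)]
            if np.any(finite < 0):
                raise ValueError(f"{self.kind} spectrum has negative values")

    def band(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting wavelengths in [lo, hi]."""
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)
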