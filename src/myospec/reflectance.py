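"""Diffuse-reflectance calibration and absorbance spectra.

Tissue reflectance I(lambda) is calibrated against a white-reference lamp
spectrum I0(lambda) measured on the same day; tissue absorbance is
A(lambda) = -log10(I / I0).  In the 500-600 nm band the absorbance carries
the haemoglobin/myoglobin oxygenation features (~542 and ~577 nm when
oxygenated) and the reduced cytochrome c peak (~550 nm, shoulder ~520 nm),
so spectra are typically normalized to their in-band maximum before
comparison across animals.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .data import Spectrum

__all__ = ["absorbance", "normalize_band", "band_peaks"]


def absorbance(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Absorbance A = -log10(I/I0) of a sample against the white reference.

    The reference is linearly interpolated onto the sample grid if the two
    grids differ.  Non-positive reference values are an error; non-positive
    sample values yield NaN bins (flagged missing, never fabricated).
    """
    wl = sample.wavelengths
    if (
        reference.wavelengths.size == wl.size
        and np.allclose(reference.wavelengths, wl)
    ):
        i0 = reference.values
    else:
        if wl[0] < reference.wavelengths[0] or wl[-1] > reference.wavelengths[-1]:
            raise ValueError("sample wavelengths extend beyond the reference range")
        i0 = np.interp(wl, reference.wavelengths, reference.values)
    if np.any(i0 <= 0):
        bad = float(wl[np.argmax(i0 <= 0)])
        raise ValueError(f"non-positive reference intensity at {bad:g} nm")
    vals = np.where(sample.values > 0, sample.values, np.nan)
    a = -np.log10(vals / i0)
    return Spectrum(wl, a, kind="absorbance", meta=dict(sample.meta))


def normalize_band(a: Spectrum, band: tuple[float, float] = (500.0, 600.0)) -> Spectrum:
    """Divide a spectrum by its maximum inside ``band`` (default 500-600 nm)."""
    mask = a.band(*band)
    if not mask.any():
        raise ValueError(f"no wavelengths in band {band}")
    peak = np.nanmax(a.values[mask])
    if not peak > 0:
        raise ValueError("in-band maximum must be positive")
    return Spectrum(
        a.wavelengths, a.values / peak, kind="normalized_absorbance", meta=dict(a.meta)
    )


def band_peaks(
    a: Spectrum, band: tuple[float, float], min_prominence: float = 0.05
) -> list[tuple[float, float]]:
    """Local maxima within a wavelength band.

    Peaks are 3-point local maxima with prominence at least
    ``min_prominence`` times the in-band value range, returned as
    (wavelength_nm, value) sorted by wavelength.  An empty list is a valid
    result (e.g. for a monotone spectrum).
    """
    mask = a.band(*band)
    if mask.sum() < 5:
        raise ValueError("need at least 5 points in the band")
    wl = a.wavelengths[mask]
    v = a.values[mask]
    rng = np.nanmax(v) - np.nanmin(v)
    if not rng > 0:
        return []
    idx, _ = find_peaks(v, prominence=min_prominence * rng)
    return [(float(wl[i]), float(v[i])) for i in idx]
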