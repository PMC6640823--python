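"""Readers and writers for the plain-text fixture dialects.

TCSPC histograms use the "tcspc-csv" dialect::

    # bin_width_ps=48.8
    # rep_period_ns=50.0
    # channel=4
    bin_index,counts
    0,12
    ...

IRF files add ``# reference_lifetime_ps=200``.  An equivalent JSON envelope
with a ``meta`` object is also supported (extension ``.json``).  Spectra are
two-column CSV ``wavelength_nm,value`` with a ``# kind=`` header.  Unknown
``# key=value`` headers are preserved in ``meta``.  CRLF and LF line
endings parse identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import DecayHistogram, InstrumentResponse, Spectrum

__all__ = [
    "read_histogram",
    "write_histogram",
    "read_irf",
    "write_irf",
    "read_spectrum",
    "write_spectrum",
]


def _parse_headers(lines: list[str]) -> tuple[dict[str, str], int]:
    headers: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s.startswith("#"):
            break
        body = s.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            headers[key.strip()] = val.strip()
    return headers, i


def _require(headers: dict[str, str], key: str, path) -> str:
    if key not in headers:
        raise ValueError(f"{path}: missing required header key {key!r}")
    return headers[key]


def _read_counts_csv(path) -> tuple[dict[str, str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    headers, start = _parse_headers(lines)
    body = [ln.strip() for ln in lines[start:] if ln.strip()]
    if body and body[0].lower().replace(" ", "") == "bin_index,counts":
        body = body[1:]
    counts = {}
    for ln in body:
        try:
            idx_s, cnt_s = ln.split(",")
            idx, cnt = int(idx_s), float(cnt_s)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row {ln!r}") from exc
        if cnt < 0:
            raise ValueError(f"{path}: negative count at bin {idx}")
        if cnt != np.floor(cnt):
            raise ValueError(f"{path}: non-integral count at bin {idx}")
        counts[idx] = cnt
    n = max(counts) + 1 if counts else 0
    arr = np.zeros(n)
    for idx, cnt in counts.items():
        arr[idx] = cnt
    return headers, arr


def _histogram_fields(headers: dict[str, str], path) -> tuple[float, float, int, dict]:
    bin_width = float(_require(headers, "bin_width_ps", path))
    rep_period = float(_require(headers, "rep_period_ns", path))
    channel = int(_require(headers, "channel", path))
    known = {"bin_width_ps", "rep_period_ns", "channel", "reference_lifetime_ps"}
    meta = {k: v for k, v in headers.items() if k not in known}
    return bin_width, rep_period, channel, meta


def read_histogram(path) -> DecayHistogram:
    """Read a decay histogram from tcspc-csv or its JSON envelope."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        for key in ("bin_width_ps", "rep_period_ns", "channel", "counts"):
            if key not in doc:
                raise ValueError(f"{path}: missing required key {key!r}")
        counts = np.asarray(doc["counts"], dtype=float)
        if np.any(counts < 0):
            raise ValueError(
                f"{path}: negative count at bin {int(np.argmax(counts < 0))}"
            )
        return DecayHistogram(
            counts=counts,
            bin_width=float(doc["bin_width_ps"]),
            rep_period=float(doc["rep_period_ns"]),
            channel=int(doc["channel"]),
            meta=dict(doc.get("meta", {})),
        )
    headers, counts = _read_counts_csv(path)
    bin_width, rep_period, channel, meta = _histogram_fields(headers, path)
    return DecayHistogram(
        counts=counts, bin_width=bin_width, rep_period=rep_period,
        channel=channel, meta=meta,
    )


def write_histogram(hist: DecayHistogram, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "bin_width_ps": hist.bin_width,
            "rep_period_ns": hist.rep_period,
            "channel": hist.channel,
            "meta": {k: v for k, v in hist.meta.items() if _jsonable(v)},
            "counts": [int(c) for c in hist.counts],
        }
        path.write_text(json.dumps(doc) + "\n")
        return
    lines = [
        f"# bin_width_ps={hist.bin_width:g}",
        f"# rep_period_ns={hist.rep_period:g}",
        f"# channel={hist.channel}",
    ]
    lines += [
        f"# {k}={v}" for k, v in hist.meta.items()
        if isinstance(v, (str, int, float)) and "=" not in str(v)
    ]
    lines.append("bin_index,counts")
    lines += [f"{i},{int(c)}" for i, c in enumerate(hist.counts)]
    path.write_text("\n".join(lines) + "\n")


def read_irf(path) -> InstrumentResponse:
    """Read an instrument-response histogram (tcspc-csv plus dye lifetime)."""
    headers, counts = _read_counts_csv(path)
    bin_width, rep_period, channel, meta = _histogram_fields(headers, path)
    ref = float(headers.get("reference_lifetime_ps", 200.0))
    return InstrumentResponse(
        counts=counts, bin_width=bin_width, rep_period=rep_period,
        reference_lifetime=ref, channel=channel, meta=meta,
    )


def write_irf(irf: InstrumentResponse, path) -> None:
    lines = [
        f"# bin_width_ps={irf.bin_width:g}",
        f"# rep_period_ns={irf.rep_period:g}",
        f"# channel={irf.channel if irf.channel is not None else 1}",
        f"# reference_lifetime_ps={irf.reference_lifetime:g}",
        "bin_index,counts",
    ]
    lines += [f"{i},{int(c)}" for i, c in enumerate(irf.counts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV with a # kind= header."""
    path = Path(path)
    lines = path.read_text().splitlines()
    headers, start = _parse_headers(lines)
    kind = headers.get("kind", "raw")
    body = [ln.strip() for ln in lines[start:] if ln.strip()]
    if body and body[0].lower().replace(" ", "") == "wavelength_nm,value":
        body = body[1:]
    wl, vals = [], []
    for ln in body:
        try:
            w_s, v_s = ln.split(",")
            wl.append(float(w_s))
            vals.append(float(v_s))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row {ln!r}") from exc
    known = {"kind"}
    meta = {k: v for k, v in headers.items() if k not in known}
    return Spectrum(np.asarray(wl), np.asarray(vals), kind=kind, meta=meta)


def write_spectrum(spec: Spectrum, path) -> None:
    lines = [f"# kind={spec.kind}", "wavelength_nm,value"]
    lines += [
        f"{w:.6g},{v:.10g}" for w, v in zip(spec.wavelengths, spec.values)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
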