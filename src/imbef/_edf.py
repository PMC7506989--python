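"""Minimal EDF/EDF+ writer used for synthetic fixtures.

Only writing lives here; reading goes through MNE.  The writer covers the
subset of the format the package needs: one 16-bit signal channel, an
optional EDF+ annotation channel carrying one stage event per data record,
and a fixed (dateless) header so that rewriting the same data produces a
byte-identical file.
"""

from __future__ import annotations

import io

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767


def _field(value, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field {value!r} exceeds {width} bytes")
    return b + b" " * (width - len(b))


def _bound(x: float, rounder) -> tuple[str, float]:
    """Outward-rounded value representable in an 8-char header field."""
    import math

    for decimals in range(7, -1, -1):
        v = rounder(x * 10 ** decimals) / 10 ** decimals
        s = f"{v:.{decimals}f}".rstrip("0").rstrip(".") if decimals else str(
            int(v))
        if len(s) <= 8:
            return s, float(s)
    raise ValueError(f"value {x} not representable in an EDF header field")


def _phys_range(samples: np.ndarray) -> tuple[str, str, float, float]:
    import math

    pmin, pmax = float(samples.min()), float(samples.max())
    if pmax <= pmin:  # flat signal: open the physical range artificially
        pmax = pmin + 1.0
    smin, fmin = _bound(pmin, math.floor)
    smax, fmax = _bound(pmax, math.ceil)
    if fmax <= fmin:
        fmax = fmin + 1.0
        smax = _bound(fmax, math.ceil)[0]
    return smin, smax, fmin, fmax


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    channel: str = "EEG synth",
    physical_unit: str = "uV",
    annotations: list[tuple[float, float, str]] | None = None,
    record_duration: float = 1.0,
) -> None:
    """Write ``samples`` as a single-channel EDF (EDF+C when annotations given).

    ``annotations`` is a list of ``(onset_s, duration_s, text)``; each event
    is stored in the data record containing its onset.  The sample count must
    be an integer multiple of samples-per-record (``fs * record_duration``).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size == 0:
        raise ValueError("samples must be a non-empty 1-D array")
    spr = fs * record_duration
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("fs * record_duration must be an integer")
    spr = int(round(spr))
    if samples.size % spr != 0:
        raise ValueError(
            f"signal length {samples.size} is not a multiple of "
            f"{spr} samples per record"
        )
    n_records = samples.size // spr

    smin, smax, pmin_d, pmax_d = _phys_range(samples)

    has_ann = annotations is not None
    tals: list[bytes] = []
    ann_spr = 0
    if has_ann:
        for r in range(n_records):
            t0, t1 = r * record_duration, (r + 1) * record_duration
            tal = f"+{r * record_duration:g}\x14\x14\x00".encode("ascii")
            for onset, dur, text in annotations:
                if t0 <= onset < t1:
                    tal += f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00".encode("utf-8")
            tals.append(tal)
        ann_spr = (max(len(t) for t in tals) + 1) // 2 + 2

    n_sig = 2 if has_ann else 1
    labels = [channel] + (["EDF Annotations"] if has_ann else [])

    hdr = io.BytesIO()
    hdr.write(_field("0", 8))
    hdr.write(_field("X X X X", 80))
    hdr.write(_field("Startdate 01-JAN-2000 X X X", 80))
    hdr.write(_field("01.01.00", 8))
    hdr.write(_field("00.00.00", 8))
    hdr.write(_field(256 * (1 + n_sig), 8))
    hdr.write(_field("EDF+C" if has_ann else "", 44))
    hdr.write(_field(n_records, 8))
    hdr.write(_field(f"{record_duration:g}", 8))
    hdr.write(_field(n_sig, 4))

    for lab in labels:
        hdr.write(_field(lab, 16))
    for _ in labels:
        hdr.write(_field("", 80))  # transducer
    hdr.write(_field(physical_unit, 8))
    if has_ann:
        hdr.write(_field("", 8))
    hdr.write(_field(smin, 8))
    if has_ann:
        hdr.write(_field(-1, 8))
    hdr.write(_field(smax, 8))
    if has_ann:
        hdr.write(_field(1, 8))
    hdr.write(_field(DIG_MIN, 8))
    if has_ann:
        hdr.write(_field(DIG_MIN, 8))
    hdr.write(_field(DIG_MAX, 8))
    if has_ann:
        hdr.write(_field(DIG_MAX, 8))
    for _ in labels:
        hdr.write(_field("", 80))  # prefiltering
    hdr.write(_field(spr, 8))
    if has_ann:
        hdr.write(_field(ann_spr, 8))
    for _ in labels:
        hdr.write(_field("", 32))  # reserved

    # physical -> 16-bit digital over the declared (enclosing) range
    scale = (pmax_d - pmin_d) / (DIG_MAX - DIG_MIN)
    dig = np.clip(
        np.round((samples - pmin_d) / scale + DIG_MIN), DIG_MIN, DIG_MAX
    ).astype("<i2")

    out = bytearray(hdr.getvalue())
    for r in range(n_records):
        out += dig[r * spr : (r + 1) * spr].tobytes()
        if has_ann:
            tal = tals[r]
            out += tal + b"\x00" * (2 * ann_spr - len(tal))
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def quantization_step(samples: np.ndarray) -> float:
    """Physical value of one digital unit for the range write_edf would use."""
    samples = np.asarray(samples, dtype=float)
    _, _, pmin_d, pmax_d = _phys_range(samples)
    return (pmax_d - pmin_d) / (DIG_MAX - DIG_MIN)
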