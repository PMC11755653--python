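"""Minimal EDF writer (16-bit European Data Format).

Writing support only: no EDF writer is shipped with the scientific stack
this package builds on, and the format's fixed-width ASCII header plus
little-endian int16 records are simple enough to emit directly.  Reading
goes through MNE (see :mod:`wbsync.recordings`).

Limitations (adequate for surrogate recordings): one data-record per
second, integer sampling rates, whole-second durations, a single physical
dimension for all channels, no annotations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> str:
    """Format a physical min/max into <= 8 ASCII chars."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g"):
        s = format(v, fmt)
        if len(s) <= 8:
            return s
    raise ValidationError(f"cannot format {v} into an EDF header field")


def write_edf(path, signals: np.ndarray, fs: float, labels,
              phys_dim: str = "uV", patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write ``signals`` (shape [n_channels, n_samples], physical units) to EDF.

    The physical range of each channel is auto-scaled to its extreme value
    (with 2% headroom) over the digital range -32767..32767, giving a
    quantization step of about 6e-5 of the channel's peak amplitude.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValidationError("signals must be 2-D [n_channels, n_samples]")
    n_ch, n_samp = signals.shape
    labels = list(labels)
    if len(labels) != n_ch:
        raise ValidationError("one label per channel is required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires a positive integer sampling rate")
    spr = int(round(fs))
    if n_samp % spr != 0:
        raise ValidationError("EDF writer requires a whole number of seconds")
    n_rec = n_samp // spr
    if not np.all(np.isfinite(signals)):
        raise ValidationError("signals must be finite")

    dig_max, dig_min = 32767, -32767
    phys_max_strs, gains = [], []
    for ch in range(n_ch):
        amax = float(np.max(np.abs(signals[ch])))
        amax = 1.02 * amax if amax > 0 else 1.0
        s = _fmt_phys(amax)
        pm = float(s)  # use the value as written, so scaling is exact
        phys_max_strs.append(s)
        gains.append(dig_max / pm)

    header = bytearray()
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)
    header += _field(str(n_ch), 4)

    def sig_fields(values, width):
        out = bytearray()
        for v in values:
            out += _field(v, width)
        return out

    header += sig_fields(labels, 16)
    header += sig_fields([""] * n_ch, 80)  # transducer
    header += sig_fields([phys_dim] * n_ch, 8)
    header += sig_fields(["-" + s for s in phys_max_strs], 8)
    header += sig_fields(phys_max_strs, 8)
    header += sig_fields([str(dig_min)] * n_ch, 8)
    header += sig_fields([str(dig_max)] * n_ch, 8)
    header += sig_fields([""] * n_ch, 80)  # prefiltering
    header += sig_fields([str(spr)] * n_ch, 8)
    header += sig_fields([""] * n_ch, 32)

    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for ch in range(n_ch):
        digital[ch] = np.clip(np.rint(signals[ch] * gains[ch]), dig_min, dig_max)

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records: per second, channels sequentially
        rec = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())
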