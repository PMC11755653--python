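"""Recordings, cohort manifests, and matrix file I/O.

EDF/EDF+ recordings are read through MNE; a small header scan validates
channel presence and per-channel sampling rates *before* the data are
loaded, so montage and sampling problems surface as specific errors
rather than silent resampling.  Channel matching is case-insensitive and
alias-aware (modern temporal names T7/T8/P7/P8 map onto T3/T4/T5/T6).

All downstream objects index channels in one canonical order -- the
19-channel International 10-20 montage listed in ``CANONICAL_CHANNELS``
-- which prevents silent transposition between matrices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MontageError, SamplingError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_CHANNELS",
    "Recording",
    "read_recording",
    "read_manifest",
    "write_matrix",
    "read_matrix",
    "AHI_GROUP_THRESHOLD",
    "group_from_ahi",
]

#: Canonical order of the 19 analysis channels (10-20 montage, ear reference).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Modern 10-10 temporal labels mapped onto their classical equivalents.
_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: AHI at or below this value assigns a subject to the control group.
AHI_GROUP_THRESHOLD = 15.0


def group_from_ahi(ahi: float) -> str:
    """Group rule: control iff 0 <= AHI <= 15 events/hour, else main."""
    if ahi < 0:
        raise ValidationError(f"negative AHI: {ahi}")
    return "control" if ahi <= AHI_GROUP_THRESHOLD else "main"


def normalize_label(label: str) -> str:
    """Reduce an EDF channel label to a canonical 10-20 name (uppercased)."""
    s = label.strip()
    s = re.sub(r"^EEG[\s_:]*", "", s, flags=re.IGNORECASE)
    s = re.sub(r"[-\s_](A1|A2|REF|LE|AVG|M1|M2)$", "", s, flags=re.IGNORECASE)
    s = s.strip().upper()
    return _ALIASES.get(s.capitalize(), s.capitalize()).upper()


@dataclass
class Recording:
    """A multichannel EEG recording in physical units (microvolts).

    ``mask``, when present, flags valid samples per channel; missing data
    are represented by the mask, never by sentinel values.
    """

    subject_id: str
    signals: np.ndarray  # [n_channels, n_samples]
    fs: float
    channel_labels: tuple[str, ...]
    mask: np.ndarray | None = None  # bool, True = valid

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValidationError("signals must be 2-D [n_channels, n_samples]")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValidationError("one label per signal row is required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signals.shape:
                raise ValidationError("mask shape must match signals")
            check = np.where(self.mask, self.signals, 0.0)
        else:
            check = self.signals
        if not np.all(np.isfinite(check)):
            raise ValidationError("signals contain non-finite values outside the mask")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------

def _read_edf_header(path: Path) -> dict:
    """Parse the fixed-width ASCII EDF header (labels, rates, dimensions)."""
    try:
        with open(path, "rb") as fh:
            fixed = fh.read(256)
            if len(fixed) < 256:
                raise FormatError(f"{path}: truncated EDF header")
            try:
                n_rec = int(fixed[236:244].decode("ascii").strip())
                rec_dur = float(fixed[244:252].decode("ascii").strip())
                n_sig = int(fixed[252:256].decode("ascii").strip())
            except (UnicodeDecodeError, ValueError) as exc:
                raise FormatError(f"{path}: malformed EDF header") from exc
            sig_hdr = fh.read(256 * n_sig)
            if len(sig_hdr) < 256 * n_sig:
                raise FormatError(f"{path}: truncated EDF signal header")
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc

    def col(offset, width):
        base = offset * n_sig
        return [sig_hdr[base + i * width: base + (i + 1) * width].decode(
            "ascii", "replace").strip() for i in range(n_sig)]

    labels = col(0, 16)
    dims_off = 16 + 80
    dims = [sig_hdr[(dims_off) * n_sig + i * 8: (dims_off) * n_sig + (i + 1) * 8]
            .decode("ascii", "replace").strip() for i in range(n_sig)]
    spr_off = 16 + 80 + 8 + 8 + 8 + 8 + 8 + 80
    try:
        spr = [int(sig_hdr[spr_off * n_sig + i * 8: spr_off * n_sig + (i + 1) * 8]
                   .decode("ascii").strip()) for i in range(n_sig)]
    except (UnicodeDecodeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed samples-per-record fields") from exc
    if rec_dur <= 0:
        raise FormatError(f"{path}: non-positive data record duration")
    return {
        "labels": labels,
        "dims": dims,
        "fs": [s / rec_dur for s in spr],
        "n_records": n_rec,
        "record_duration": rec_dur,
    }


def read_recording(path, required_channels=CANONICAL_CHANNELS,
                   subject_id: str | None = None) -> Recording:
    """Read an EDF/EDF+ file and return the requested channels, canonically ordered.

    Extra polysomnography channels (ECG, respiration, ...) present in the
    file are dropped.  The sampling rate is taken from the file header;
    disagreement between the selected channels is an error, never a silent
    resample.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    header = _read_edf_header(path)

    norm_to_orig: dict[str, str] = {}
    norm_to_idx: dict[str, int] = {}
    for i, lab in enumerate(header["labels"]):
        norm = normalize_label(lab)
        norm_to_orig.setdefault(norm, lab)
        norm_to_idx.setdefault(norm, i)

    required = tuple(required_channels)
    missing = [ch for ch in required if normalize_label(ch) not in norm_to_orig]
    if missing:
        raise MontageError(missing)

    sel_idx = [norm_to_idx[normalize_label(ch)] for ch in required]
    rates = {header["fs"][i] for i in sel_idx}
    if len(rates) != 1:
        raise SamplingError(
            f"{path}: selected channels have differing sampling rates {sorted(rates)}")
    fs = rates.pop()

    dims = {header["dims"][i] for i in sel_idx}
    unexpected = {d for d in dims if d.lower() not in ("uv", "µv")}
    if unexpected:
        logger.warning("%s: physical dimension(s) %s are not microvolts; "
                       "amplitudes pass through unscaled (the synchronization "
                       "measure is amplitude-invariant)", path, sorted(unexpected))

    include = [norm_to_orig[normalize_label(ch)] for ch in required]
    try:
        raw = mne.io.read_raw_edf(path, include=include, preload=True,
                                  verbose="error")
    except Exception as exc:  # mne raises a mixture of types on corrupt input
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc

    order = [raw.ch_names.index(norm_to_orig[normalize_label(ch)]) for ch in required]
    data = raw.get_data()[order]
    # MNE scales recognized dimensions to SI units (volts); restore microvolts.
    units = raw._orig_units if hasattr(raw, "_orig_units") else {}
    scale = np.ones(len(required))
    for k, ch in enumerate(required):
        unit = units.get(norm_to_orig[normalize_label(ch)], "")
        if unit in ("V", "uV", "µV", "mV"):
            scale[k] = 1e6
    data = data * scale[:, None]

    return Recording(
        subject_id=subject_id or path.stem,
        signals=data,
        fs=fs,
        channel_labels=required,
    )


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Read a delimited cohort manifest with columns subject_id, path, ahi[, group].

    The group label is derived from the AHI rule (control iff AHI <= 15)
    when absent; an explicit column that disagrees with the rule is kept
    but logged as a warning.  Subjects sitting exactly on the boundary are
    noted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse manifest ({exc})") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    needed = {"subject_id", "path", "ahi"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"{path}: manifest must have columns {sorted(needed)}; "
            f"found {list(df.columns)}")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{path}: duplicate subject_id(s): {dups}")
    df["ahi"] = df["ahi"].astype(float)
    if (df["ahi"] < 0).any():
        bad = df.loc[df["ahi"] < 0, "subject_id"].tolist()
        raise ValidationError(f"{path}: negative AHI for subject(s): {bad}")

    derived = df["ahi"].map(group_from_ahi)
    if "group" in df.columns:
        given = df["group"].astype(str).str.strip().str.lower()
        mismatch = given != derived
        if mismatch.any():
            logger.warning("%s: group column disagrees with the AHI rule for %s; "
                           "keeping the explicit labels", path,
                           df.loc[mismatch, "subject_id"].tolist())
        df["group"] = given
    else:
        df["group"] = derived
    on_boundary = df["ahi"] == AHI_GROUP_THRESHOLD
    if on_boundary.any():
        logger.info("%s: subject(s) %s sit exactly on the AHI=%g boundary "
                    "(assigned to control)", path,
                    df.loc[on_boundary, "subject_id"].tolist(), AHI_GROUP_THRESHOLD)
    return df[["subject_id", "path", "ahi", "group"]]


# ---------------------------------------------------------------------------
# Matrix files
# ---------------------------------------------------------------------------

def write_matrix(matrix, path) -> None:
    """Write a connectivity matrix as labeled CSV with ``# key: value`` metadata.

    Masked cells are serialized as ``NA``; values keep full precision so a
    read/write round trip is exact.
    """
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.channels, columns=matrix.channels)
    meta = [f"# band: {matrix.band}", f"# level: {matrix.level}"]
    if matrix.n_subjects is not None:
        meta.append(f"# n_subjects: {matrix.n_subjects}")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(meta) + "\n")
            df.to_csv(fh, na_rep="NA")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc


def read_matrix(path):
    """Inverse of :func:`write_matrix`."""
    from .spatial import ConnectivityMatrix

    import io

    path = Path(path)
    meta = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition(":")
        meta[key.strip()] = value.strip()
        body_start += 1
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])),
                     index_col=0, na_values=["NA"])
    values = df.to_numpy(dtype=float)
    n_subjects = int(meta["n_subjects"]) if "n_subjects" in meta else None
    return ConnectivityMatrix(
        band=meta.get("band", ""),
        level=meta.get("level", "subject"),
        values=values,
        channels=tuple(df.index),
        n_subjects=n_subjects,
    )
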