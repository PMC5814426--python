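"""EDF (European Data Format) round-trip for recordings.

Writing is implemented directly against the EDF layout (256-byte ASCII
header, 256 bytes of signal headers per channel, 16-bit little-endian
samples in 1-second records); reading goes through MNE's EDF reader, so
the round-trip is checked by two independent code paths.  The physical
range is fixed at +/-500 microvolt, which bounds the quantization error
at 1000/65535 ~ 0.015 microvolt per sample.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, MontageError
from .montage import default_montage
from .simulate import Recording

PHYS_MIN = -500.0
PHYS_MAX = 500.0
DIG_MIN = -32768
DIG_MAX = 32767
_CAL = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)
_OFFSET = PHYS_MIN - DIG_MIN * _CAL


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} ({width})")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | os.PathLike) -> None:
    """Write ``rec`` as a 16-bit EDF file with 1-second data records.

    The subject id and sex label are stored in the local-patient field
    (``"<id> M"`` / ``"<id> F"``).  Samples beyond the last whole second
    are dropped (EDF stores whole records only).
    """
    if not float(rec.fs).is_integer():
        raise ConfigurationError(
            f"EDF export uses 1-s records; fs={rec.fs} must be an integer")
    if not np.all(np.isfinite(rec.signal)):
        raise ConfigurationError("signal contains non-finite values")
    if np.abs(rec.signal).max(initial=0.0) > PHYS_MAX:
        raise ConfigurationError(
            f"signal exceeds the +/-{PHYS_MAX} uV physical range")
    fs = int(rec.fs)
    n_ch = rec.montage.n_channels
    n_records = rec.n_samples // fs

    header = b"".join([
        _field("0", 8),
        _field(f"{rec.subject_id} {'M' if rec.sex == 1 else 'F'}", 80),
        _field("Startdate 02-JAN-2001 synthetic eegsex cohort", 80),
        _field("02.01.01", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    names = rec.montage.channel_names
    sig_header = b"".join([
        b"".join(_field(f"EEG {ch}", 16) for ch in names),
        b"".join(_field("AgAgCl electrode", 80) for _ in names),
        b"".join(_field("uV", 8) for _ in names),
        b"".join(_field(str(int(PHYS_MIN)), 8) for _ in names),
        b"".join(_field(str(int(PHYS_MAX)), 8) for _ in names),
        b"".join(_field(str(DIG_MIN), 8) for _ in names),
        b"".join(_field(str(DIG_MAX), 8) for _ in names),
        b"".join(_field("", 80) for _ in names),
        b"".join(_field(str(fs), 8) for _ in names),
        b"".join(_field("", 32) for _ in names),
    ])

    digital = np.round((rec.signal[:, :n_records * fs] - _OFFSET) / _CAL)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")
    # record-major layout: for each second, all channels consecutively
    data = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(np.ascontiguousarray(data).tobytes())


def _check_edf_size(path: Path) -> None:
    size = path.stat().st_size
    if size < 256:
        raise FormatError(f"{path}: too short for an EDF header ({size} bytes)")
    with open(path, "rb") as fh:
        head = fh.read(256)
    try:
        header_bytes = int(head[184:192].decode("ascii").strip())
        n_records = int(head[236:244].decode("ascii").strip())
        n_sig = int(head[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header") from exc
    if size < header_bytes:
        raise FormatError(f"{path}: truncated header")
    with open(path, "rb") as fh:
        fh.seek(256)
        sig = fh.read(header_bytes - 256)
    if len(sig) != 256 * n_sig:
        raise FormatError(f"{path}: truncated signal headers")
    spr = [int(sig[216 * n_sig + 8 * i: 216 * n_sig + 8 * (i + 1)].decode().strip())
           for i in range(n_sig)]
    expected = header_bytes + 2 * n_records * sum(spr)
    if size < expected:
        raise FormatError(
            f"{path}: truncated data ({size} bytes, expected {expected})")


def read_edf(path: str | os.PathLike) -> Recording:
    """Read an EDF file back into a :class:`Recording`.

    Channel labels must form a subset of the default 26-channel montage;
    the returned montage preserves the file's channel order.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    _check_edf_size(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    montage = default_montage()
    unknown = [lab for lab in labels if lab not in montage.channel_names]
    if unknown:
        raise MontageError(f"unknown channel labels in {path}: {unknown}")
    sub = montage.subset(labels)

    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii").strip()
    parts = patient.split()
    subject_id = parts[0] if parts else path.stem
    sex = 1 if (len(parts) > 1 and parts[1].upper().startswith("M")) else 0

    signal = raw.get_data() * 1e6  # MNE returns volt
    return Recording(subject_id=subject_id, sex=sex, fs=float(raw.info["sfreq"]),
                     signal=signal, montage=sub)


def write_cohort_edf(recordings, directory: str | os.PathLike) -> pd.DataFrame:
    """Write each recording as EDF plus a cohort manifest CSV.

    Returns the manifest (subject_id, sex, path, seed); also written to
    ``directory/manifest.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        p = directory / f"{rec.subject_id}.edf"
        write_edf(rec, p)
        rows.append({"subject_id": rec.subject_id, "sex": rec.sex,
                     "path": str(p), "seed": rec.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
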