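"""Recording file I/O: delimited text and 16-bit EDF.

Two interchange formats are supported:

* delimited text — one row per channel, a header line of channel labels,
  and a JSON sidecar (`<stem>.json`) holding sampling rate and study
  metadata; lossless and diff-friendly.
* EDF — the standard electrophysiology interchange format. Reading uses
  :func:`mne.io.read_raw_edf`; writing uses a self-contained EDF writer
  (16-bit samples, one data record per second), so round-trips are exact
  up to the format's integer quantization step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import Condition, Recording, Segment, Side

# ---------------------------------------------------------------------------
# delimited text


def write_text(rec: Recording, path: str | Path, delimiter: str = "\t") -> Path:
    """Write channels as rows with a label header plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(rec.labels) + "\n")
        # columns = channels in the file so standard column tools apply
        np.savetxt(fh, rec.data.T, fmt="%.9g", delimiter=delimiter)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "condition": rec.condition.value,
        "side": rec.side.value,
        "segment": rec.segment.value,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_text(path: str | Path, delimiter: str = "\t") -> Recording:
    path = Path(path)
    with open(path) as fh:
        labels = tuple(fh.readline().strip().split(delimiter))
        data = np.loadtxt(fh, delimiter=delimiter, ndmin=2).T
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        labels=labels,
        subject_id=meta.get("subject_id", "s00"),
        condition=Condition(meta.get("condition", "sham")),
        side=Side(meta.get("side", "left")),
        segment=Segment(meta.get("segment", "pre")),
    )


# ---------------------------------------------------------------------------
# EDF

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a plain EDF file with 16-bit samples, one 1-s data record per second.

    Physical range is set per channel to the signal's own min/max, so the
    quantization step is (max - min) / 65535.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per channel
    n_records = rec.n_samples // spr
    if n_records * spr != rec.n_samples:
        raise ValueError("recording length must be a whole number of seconds")
    nchan = rec.n_channels

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    # recording id field doubles as the metadata carrier for round-trips
    rec_id = (
        f"Startdate X {rec.subject_id} {rec.condition.value} "
        f"{rec.side.value} {rec.segment.value}"
    )
    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id, 80),
            _pad(rec_id, 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + nchan)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),  # record duration, seconds
            _pad(str(nchan), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_pad(lab, 16) for lab in rec.labels),
            b"".join(_pad("EEG", 80) for _ in range(nchan)),
            b"".join(_pad("uV", 8) for _ in range(nchan)),
            b"".join(_pad(f"{phys_min[i]:.6g}", 8) for i in range(nchan)),
            b"".join(_pad(f"{phys_max[i]:.6g}", 8) for i in range(nchan)),
            b"".join(_pad(str(_EDF_DIGITAL_MIN), 8) for _ in range(nchan)),
            b"".join(_pad(str(_EDF_DIGITAL_MAX), 8) for _ in range(nchan)),
            b"".join(_pad("", 80) for _ in range(nchan)),
            b"".join(_pad(str(spr), 8) for _ in range(nchan)),
            b"".join(_pad("", 32) for _ in range(nchan)),
        ]
    )

    gain = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (rec.data - phys_min[:, None]) * gain[:, None] + _EDF_DIGITAL_MIN
    )
    digital = np.clip(digital, _EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via MNE, recovering study metadata when present."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE works in volts
    labels = tuple(raw.ch_names)
    meta = _parse_recording_id(path)
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=labels,
        **meta,
    )


def _parse_recording_id(path: str | Path) -> dict:
    """Recover subject/condition/side/segment from the EDF recording-id field."""
    with open(path, "rb") as fh:
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", "replace").split()
    out: dict = {}
    # layout written by write_edf: Startdate X <subject> <condition> <side> <segment>
    if len(rec_id) >= 6 and rec_id[0] == "Startdate":
        try:
            out = {
                "subject_id": rec_id[2],
                "condition": Condition(rec_id[3]),
                "side": Side(rec_id[4]),
                "segment": Segment(rec_id[5]),
            }
        except ValueError:
            out = {"subject_id": rec_id[2]}
    return out


# ---------------------------------------------------------------------------
# dispatch


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _format_from_suffix(path)
    if fmt == "edf":
        return write_edf(rec, path)
    if fmt == "delimited":
        return write_text(rec, path)
    raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(
    path: str | Path,
    format: str | None = None,
    expected_labels: tuple[str, ...] | None = None,
) -> Recording:
    """Read a recording; optionally validate and normalize channel order.

    With ``expected_labels`` the file must contain every listed channel
    (missing ones are reported by name) and the rows are reordered to
    that label order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _format_from_suffix(path)
    if fmt == "edf":
        rec = read_edf(path)
    elif fmt == "delimited":
        rec = read_text(path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if expected_labels is not None:
        missing = [lab for lab in expected_labels if lab not in rec.labels]
        if missing:
            raise ValueError(
                f"{path.name}: missing montage channels {missing}"
            )
        order = [rec.labels.index(lab) for lab in expected_labels]
        rec = Recording(
            data=rec.data[order], fs=rec.fs, labels=tuple(expected_labels),
            subject_id=rec.subject_id, condition=rec.condition,
            side=rec.side, segment=rec.segment,
        )
    return rec


def _format_from_suffix(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".tsv", ".txt", ".csv"}:
        return "delimited"
    raise ValueError(f"cannot infer recording format from {path.name!r}")
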