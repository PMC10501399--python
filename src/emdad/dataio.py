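"""Readers and writers for the formats the pipeline touches.

Recordings travel as EDF (the standard clinical EEG container) or as a
plain tab-separated text dialect used for bit-exact test fixtures; cohorts
are described by a JSON manifest; feature matrices round-trip through CSV
at full double precision.

The EDF support here is deliberately minimal: plain EDF (not EDF+), one
signal per channel, identical sampling rate for all channels, no
annotations.  That is all the pipeline needs and keeps the container
auditable.  EDF stores samples as 16-bit integers scaled into a per-channel
physical range, so a write/read round trip is exact only up to one
quantization step of that range.
"""

from __future__ import annotations

import json
import math

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_LABELS = ("neurotypical", "mild_ad", "moderate_ad")

#: Default 20-site montage of the international 10-20 system.
MONTAGE_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)


class FormatError(ValueError):
    """A file did not satisfy the expected on-disk contract."""


@dataclass
class EEGRecording:
    """One subject's continuous multi-channel EEG signal.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    class_label : str
        One of ``neurotypical``, ``mild_ad``, ``moderate_ad``.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered electrode names (10-20 montage sites).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    class_label: str
    fs: float
    channel_labels: tuple
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"but {len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortManifest:
    """Index of a cohort written to disk: one entry per subject file."""

    entries: list  # of dict {subject_id, class_label, file, n_trials}
    fs: float
    epoch_seconds: float

    def __post_init__(self) -> None:
        ids = [e["subject_id"] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids in manifest must be unique")

    def save(self, path) -> None:
        payload = {
            "fs": self.fs,
            "epoch_seconds": self.epoch_seconds,
            "entries": self.entries,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "CohortManifest":
        payload = json.loads(Path(path).read_text())
        manifest = cls(
            entries=payload["entries"],
            fs=payload["fs"],
            epoch_seconds=payload["epoch_seconds"],
        )
        base = Path(path).parent
        for e in manifest.entries:
            if not (base / e["file"]).exists():
                raise FormatError(f"manifest references missing file: {e['file']}")
        return manifest


# ---------------------------------------------------------------------------
# EDF container
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _edf_float(value: float, width: int) -> bytes:
    # EDF headers are fixed-width ASCII; pick the densest representation
    # that fits the slot.
    for fmt in (f"{value:.{width - 2}g}", f"{value:.6g}", f"{value:.3g}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise FormatError(f"cannot encode {value} in {width} EDF header chars")


def write_edf(rec: EEGRecording, path, record_seconds: float = 8.0) -> None:
    """Write a recording as plain EDF with fixed-length data records.

    The physical range of each channel is set from its data min/max so the
    16-bit quantization step is as small as the data allows.  Trailing
    samples that do not fill a whole data record are zero-padded (the
    epoching step discards any trailing remainder anyway).
    """
    fs = rec.fs
    spr = fs * record_seconds
    if abs(spr - round(spr)) > 1e-9:
        raise FormatError("fs * record_seconds must be an integer sample count")
    spr = int(round(spr))
    n_records = math.ceil(rec.n_samples / spr)
    ns = rec.n_channels

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # Degenerate flat channels still need a nonzero physical span.
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"subject={rec.subject_id} class={rec.class_label}", 80),
        _edf_field("emdad synthetic cohort", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + 256 * ns, 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_float(record_seconds, 8),
        _edf_field(ns, 4),
    ])
    header += b"".join(_edf_field(lbl, 16) for lbl in rec.channel_labels)
    header += b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_edf_field("uV", 8) for _ in range(ns))
    header += b"".join(_edf_float(phys_min[c], 8) for c in range(ns))
    header += b"".join(_edf_float(phys_max[c], 8) for c in range(ns))
    header += b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(ns))
    header += b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))
    header += b"".join(_edf_field(spr, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 32) for _ in range(ns))

    # Re-read the ASCII-encoded ranges so scaling matches what a reader sees.
    pmin = np.array([float(_edf_float(phys_min[c], 8)) for c in range(ns)])
    pmax = np.array([float(_edf_float(phys_max[c], 8)) for c in range(ns)])
    pmax = np.where(pmax - pmin < 1e-12, pmin + 1.0, pmax)

    padded = np.zeros((ns, n_records * spr))
    padded[:, : rec.n_samples] = rec.data
    gain = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.rint((padded - pmin[:, None]) / gain[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within a record


def read_edf(path) -> tuple:
    """Read a plain EDF file; returns ``(data, fs, channel_labels, meta)``.

    ``meta`` carries the recording-id free text so callers can recover the
    subject id and class label written by :func:`write_edf`.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError("file too short to be EDF")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        record_seconds = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"unparseable EDF header: {exc}") from exc
    if ns <= 0:
        raise FormatError("EDF header reports no signals")
    hdr = raw[256 : 256 + 256 * ns]

    def _col(offset, width):
        base = offset * ns
        return [
            hdr[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    labels = _col(0, 16)
    # byte offsets of fixed-width fields within the per-signal header block
    pmin = np.array([float(v) for v in _col(16 + 80 + 8, 8)])
    pmax = np.array([float(v) for v in _col(16 + 80 + 8 + 8, 8)])
    dmin = np.array([float(v) for v in _col(16 + 80 + 8 + 16, 8)])
    dmax = np.array([float(v) for v in _col(16 + 80 + 8 + 24, 8)])
    spr_all = [int(v) for v in _col(16 + 80 + 8 + 32 + 80, 8)]
    if len(set(spr_all)) != 1:
        raise FormatError("mixed per-channel sampling rates are not supported")
    spr = spr_all[0]
    fs = spr / record_seconds

    body = raw[256 + 256 * ns :]
    expect = n_records * ns * spr * 2
    if len(body) < expect:
        raise FormatError("EDF body truncated")
    digital = np.frombuffer(body[:expect], dtype="<i2").reshape(n_records, ns, spr)
    digital = np.concatenate([digital[r] for r in range(n_records)], axis=1).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    meta = {"recording_id": raw[8:88].decode("ascii").strip()}
    return data, fs, labels, meta


# ---------------------------------------------------------------------------
# Text dialect (tab-separated, for bit-exact fixtures)
# ---------------------------------------------------------------------------


def write_text_recording(rec: EEGRecording, path) -> None:
    """TSV dialect: header row of channel labels, one sample per row,
    metadata in a JSON sidecar ``<path>.json``."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        for row in rec.data.T:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "subject_id": rec.subject_id,
        "class_label": rec.class_label,
        "fs": rec.fs,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_text_recording(path) -> EEGRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing metadata sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    with open(path, encoding="utf-8") as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        rows = [[float(v) for v in line.rstrip("\n").split("\t")] for line in fh if line.strip()]
    data = np.array(rows).T if rows else np.empty((len(labels), 0))
    return EEGRecording(
        subject_id=meta["subject_id"],
        class_label=meta["class_label"],
        fs=meta["fs"],
        channel_labels=labels,
        data=data,
    )


def write_recording(rec: EEGRecording, path, format: str = "edf") -> None:
    if format == "edf":
        write_edf(rec, path)
    elif format == "text":
        write_text_recording(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'edf' or 'text'")


def read_recording(path, expected_fs: float | None = None) -> EEGRecording:
    """Read an EDF or text-dialect recording, validating the sampling rate.

    The format is sniffed from the file: the text dialect has a JSON
    sidecar; anything else is treated as EDF.
    """
    path = Path(path)
    if path.with_suffix(path.suffix + ".json").exists():
        rec = read_text_recording(path)
    else:
        data, fs, labels, meta = read_edf(path)
        subject_id, class_label = path.stem, "neurotypical"
        for token in meta.get("recording_id", "").split():
            if token.startswith("subject="):
                subject_id = token[len("subject="):]
            elif token.startswith("class="):
                class_label = token[len("class="):]
        rec = EEGRecording(
            subject_id=subject_id,
            class_label=class_label,
            fs=fs,
            channel_labels=labels,
            data=data,
        )
    if expected_fs is not None and abs(rec.fs - expected_fs) > 1e-9:
        raise FormatError(
            f"sampling-rate mismatch: file header says fs={rec.fs} Hz, "
            f"expected {expected_fs} Hz"
        )
    return rec


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------


def write_feature_matrix(fm, path) -> None:
    """CSV with one column per <channel>_<component> plus label/subject_id.

    Doubles are printed with 17 significant digits so the round trip is
    bitwise lossless.
    """
    if fm.values.size == 0:
        raise ValueError("refusing to write an empty feature matrix")
    df = pd.DataFrame(fm.values, columns=list(fm.column_labels))
    df.insert(0, "subject_id", list(fm.subject_ids))
    df.insert(1, "label", list(fm.labels))
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path, feature_name: str = ""):
    from .features import FeatureMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["subject_id", "label"]:
        raise FormatError("feature CSV must start with subject_id,label columns")
    cols = list(df.columns[2:])
    if not cols:
        raise FormatError("feature CSV has no feature columns")
    return FeatureMatrix(
        values=df[cols].to_numpy(dtype=float),
        feature_name=feature_name,
        column_labels=tuple(cols),
        labels=tuple(df["label"]),
        subject_ids=tuple(df["subject_id"]),
    )
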