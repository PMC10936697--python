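"""Reading and writing waveform recordings.

Three interchange routes are supported:

* **native dialect** — a binary waveform file (little-endian float32,
  channel-interleaved, fixed magic + header) paired with an ASCII metafile
  holding setup key-value lines and one tab-separated line per annotation;
* **EDF** — the 16-bit European Data Format, written here directly against
  the standard's field layout and read back through :mod:`mne`;
* **CSV** — one time column plus one column per channel, with annotations in
  a tab-separated sidecar file.

Times are always seconds from record start; sample index 0 sits at t = 0.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np

from .records import Annotation, AnnotationKind, SignalRecord

__all__ = [
    "SignalRecord",
    "Annotation",
    "AnnotationKind",
    "FormatError",
    "write_record",
    "read_record",
    "export_edf",
    "export_csv",
]

log = logging.getLogger(__name__)

MAGIC = b"RHEOPULS"
VERSION = 1
# after the magic: version(u16), n_channels(u16), fs(f64), n_samples(u64)
_HEADER = struct.Struct("<HHdQ")


class FormatError(ValueError):
    """Raised when a file is not a valid recording in the declared format."""


# ---------------------------------------------------------------------------
# native dialect


def _native_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".rheo", ".meta"}:
        base = base.with_suffix("")
    return base.with_suffix(".rheo"), base.with_suffix(".meta")


def write_record(record: SignalRecord, path: str | Path) -> tuple[Path, Path]:
    """Write ``record`` in the native dialect.

    Produces ``<base>.rheo`` (binary waveform: magic, version, channel count,
    sampling rate, sample count, then float32 little-endian samples
    interleaved by channel at each time point) and ``<base>.meta`` (ASCII
    key-value lines, then one ``time_s<TAB>kind<TAB>label`` line per
    annotation). Returns the two paths written.
    """
    bin_path, meta_path = _native_paths(path)
    data = np.ascontiguousarray(record.samples.T, dtype="<f4")

    with open(bin_path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(_HEADER.pack(VERSION, record.n_channels, record.fs, record.n_samples))
        fh.write(data.tobytes())

    lines = [
        f"format\trheopulse-native",
        f"version\t{VERSION}",
        f"n_channels\t{record.n_channels}",
        f"fs\t{record.fs!r}",
        f"n_samples\t{record.n_samples}",
        f"start_time\t{record.start_time}",
        f"channel_labels\t{','.join(record.channel_labels)}",
        f"channel_units\t{','.join(record.channel_units)}",
    ]
    for key, value in record.metadata.items():
        lines.append(f"{key}\t{value}")
    for ann in record.annotations:
        lines.append(f"{ann.time_s!r}\t{ann.kind.value}\t{ann.label}")
    meta_path.write_text("\n".join(lines) + "\n", encoding="ascii")
    return bin_path, meta_path


_KNOWN_KEYS = {
    "format",
    "version",
    "n_channels",
    "fs",
    "n_samples",
    "start_time",
    "channel_labels",
    "channel_units",
}
_KINDS = {k.value for k in AnnotationKind}


def _read_native(path: str | Path) -> SignalRecord:
    bin_path, meta_path = _native_paths(path)
    raw = bin_path.read_bytes()
    if raw[: len(MAGIC)] != MAGIC:
        raise FormatError(f"{bin_path}: bad magic, not a rheopulse waveform file")
    header = raw[len(MAGIC) : len(MAGIC) + _HEADER.size]
    if len(header) < _HEADER.size:
        raise FormatError(f"{bin_path}: truncated header")
    version, n_channels, fs, n_samples = _HEADER.unpack(header)
    if version != VERSION:
        raise FormatError(f"{bin_path}: unsupported version {version}")
    payload = raw[len(MAGIC) + _HEADER.size :]
    expected = n_channels * n_samples
    found = len(payload) // 4
    if found != expected:
        raise FormatError(
            f"{bin_path}: truncated payload, expected {expected} samples "
            f"({n_channels} channels x {n_samples}), found {found}"
        )
    samples = (
        np.frombuffer(payload, dtype="<f4", count=expected)
        .reshape(n_samples, n_channels)
        .T.copy()
    )

    labels = [f"ch{i}" for i in range(n_channels)]
    units = ["V"] * n_channels
    start_time = ""
    metadata: dict[str, str] = {}
    annotations: list[Annotation] = []
    if meta_path.exists():
        for line in meta_path.read_text(encoding="ascii").splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) >= 3 and fields[1] in _KINDS:
                annotations.append(
                    Annotation(
                        time_s=float(fields[0]),
                        label="\t".join(fields[2:]),
                        kind=AnnotationKind(fields[1]),
                    )
                )
                continue
            key, _, value = line.partition("\t")
            if key == "channel_labels":
                labels = value.split(",")
            elif key == "channel_units":
                units = value.split(",")
            elif key == "start_time":
                start_time = value
            elif key not in _KNOWN_KEYS:
                metadata[key] = value  # unknown keys kept as opaque metadata
    return SignalRecord(
        samples=samples,
        fs=fs,
        channel_labels=labels,
        channel_units=units,
        start_time=start_time,
        annotations=annotations,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# EDF


def export_edf(record: SignalRecord, path: str | Path) -> Path:
    """Write ``record`` as a plain EDF file.

    Uses 1-second data records with the standard's 16-bit integer scaling;
    per-channel physical min/max are taken from the data range. If the
    sample count is not a whole number of records the final record is padded
    by repeating the last sample. Channel labels longer than the 16-byte
    header field are truncated with a logged warning. Annotations go to a
    ``<base>.annotations.tsv`` sidecar (plain EDF has no annotation stream).
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF export needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    n_records = int(np.ceil(record.n_samples / spr))
    n_sig = record.n_channels

    phys_min, phys_max = [], []
    dig_min, dig_max = -32768, 32767
    digital = np.empty((n_sig, n_records * spr), dtype="<i2")
    for c in range(n_sig):
        x = record.samples[c].astype(np.float64)
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        padded = np.concatenate([x, np.full(n_records * spr - x.size, x[-1])])
        scaled = (padded - lo) / (hi - lo) * (dig_max - dig_min) + dig_min
        digital[c] = np.clip(np.round(scaled), dig_min, dig_max).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)

    def field(text: str, width: int) -> bytes:
        out = text[:width].ljust(width)
        return out.encode("ascii")

    labels = []
    for lab in record.channel_labels:
        if len(lab) > 16:
            log.warning("EDF label %r truncated to 16 characters", lab)
        labels.append(lab[:16])

    header = b"".join(
        [
            field("0", 8),
            field("rheopulse export", 80),
            field(record.start_time or "recording", 80),
            field("01.01.00", 8),
            field("00.00.00", 8),
            field(str(256 * (1 + n_sig)), 8),
            field("", 44),
            field(str(n_records), 8),
            field("1", 8),
            field(str(n_sig), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(field(lab, 16) for lab in labels),
            b"".join(field("", 80) for _ in range(n_sig)),
            b"".join(field(u, 8) for u in record.channel_units),
            b"".join(field(f"{phys_min[c]:.8g}"[:8], 8) for c in range(n_sig)),
            b"".join(field(f"{phys_max[c]:.8g}"[:8], 8) for c in range(n_sig)),
            b"".join(field(str(dig_min), 8) for _ in range(n_sig)),
            b"".join(field(str(dig_max), 8) for _ in range(n_sig)),
            b"".join(field("", 80) for _ in range(n_sig)),
            b"".join(field(str(spr), 8) for _ in range(n_sig)),
            b"".join(field("", 32) for _ in range(n_sig)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for c in range(n_sig):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())

    if record.annotations:
        _write_annotation_sidecar(record.annotations, _sidecar_path(path))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".annotations.tsv")


def _write_annotation_sidecar(annotations: list[Annotation], path: Path) -> None:
    lines = ["time_s\tkind\tlabel"]
    for ann in annotations:
        lines.append(f"{ann.time_s!r}\t{ann.kind.value}\t{ann.label}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_annotation_sidecar(path: Path) -> list[Annotation]:
    annotations = []
    for line in path.read_text(encoding="utf-8").splitlines()[1:]:
        if not line.strip():
            continue
        t, kind, label = line.split("\t", 2)
        annotations.append(Annotation(float(t), label, AnnotationKind(kind)))
    return annotations


def _read_edf(path: str | Path) -> SignalRecord:
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne rescales channels it recognises to SI units; undo that so sample
    # values come back in the units declared in the EDF signal header.
    data = raw.get_data()
    orig_units = getattr(raw, "_orig_units", {}) or {}
    units = []
    for i, name in enumerate(raw.ch_names):
        unit = orig_units.get(name, "V")
        factor = _UNIT_FACTORS.get(unit.strip(), 1.0)
        data[i] = data[i] / factor
        units.append(unit.strip() or "V")
    annotations: list[Annotation] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        annotations = _read_annotation_sidecar(sidecar)
    return SignalRecord(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        channel_units=units,
        annotations=annotations,
    )


_UNIT_FACTORS = {"V": 1.0, "mV": 1e-3, "uV": 1e-6, "µV": 1e-6}


# ---------------------------------------------------------------------------
# CSV


def export_csv(record: SignalRecord, path: str | Path) -> Path:
    """Write one time column (seconds) plus one column per channel.

    Annotations go to a ``<base>.annotations.tsv`` sidecar with one row per
    annotation.
    """
    import pandas as pd

    path = Path(path)
    frame = pd.DataFrame(
        {"time_s": record.times(), **{
            lab: record.samples[i] for i, lab in enumerate(record.channel_labels)
        }}
    )
    frame.to_csv(path, index=False, float_format="%.9g")
    _write_annotation_sidecar(record.annotations, _sidecar_path(path))
    return path


def _read_csv(path: str | Path) -> SignalRecord:
    import pandas as pd

    path = Path(path)
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns or frame.shape[1] < 2:
        raise FormatError(f"{path}: expected a time_s column plus channel columns")
    t = frame["time_s"].to_numpy()
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples to infer fs")
    fs = 1.0 / float(np.median(np.diff(t)))
    labels = [c for c in frame.columns if c != "time_s"]
    annotations: list[Annotation] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        annotations = _read_annotation_sidecar(sidecar)
    return SignalRecord(
        samples=frame[labels].to_numpy().T,
        fs=fs,
        channel_labels=labels,
        annotations=annotations,
    )


def read_record(path: str | Path) -> SignalRecord:
    """Read a recording, dispatching on file extension.

    ``.rheo``/``.meta`` (or a bare basename) select the native dialect;
    ``.edf`` the European Data Format; ``.csv`` delimited text. Malformed
    native files raise :class:`FormatError` rather than returning a partial
    record.
    """
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return _read_edf(path)
    if suffix == ".csv":
        return _read_csv(path)
    return _read_native(path)
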