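"""Minimal WFDB reading for the optional real-record reproduction path.

Supports the subset of the WFDB standard the target ambulatory-ECG records
use: a ``.hea`` header naming the signal files, plus ``.dat`` signal files in
format 212 (two 12-bit samples packed in 3 bytes) or format 16 (little-endian
int16).  Multiple signals sharing one ``.dat`` are de-interleaved frame-wise.
Values are converted to physical units via ``(adc - baseline) / gain``.

This is not a general WFDB implementation — no multi-segment records, no
skew/byte offsets, no other packed formats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .synthetic import ECGSegment, LabeledDataset, _normalize

_GAIN_RE = re.compile(
    r"^(?P<gain>[-+0-9.eE]+)?(?:\((?P<baseline>[-+0-9]+)\))?(?:/(?P<units>\S+))?$"
)


@dataclass(frozen=True)
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int


@dataclass(frozen=True)
class WFDBRecord:
    name: str
    fs: float
    n_samples: int
    signals: np.ndarray  # (n_samples, n_sig), physical units


def _parse_header(path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        fields = ln.split()
        fmt = int(fields[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(fields) > 2:
            match = _GAIN_RE.match(fields[2])
            if match and match.group("gain"):
                gain = float(match.group("gain"))
            if match and match.group("baseline") is not None:
                baseline = int(match.group("baseline"))
        if gain == 0:
            gain = 200.0
        adc_zero = int(fields[4]) if len(fields) > 4 else 0
        specs.append(
            _SignalSpec(
                file_name=fields[0],
                fmt=fmt,
                gain=gain,
                baseline=adc_zero if baseline is None else baseline,
            )
        )
    return name, n_sig, fs, n_samples, specs


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int32)
    first = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    second = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    values = np.empty(raw.shape[0] * 2, dtype=np.int32)
    values[0::2] = first
    values[1::2] = second
    values[values > 2047] -= 4096
    return values[:n_values]


def read_record(header_path: str | Path) -> WFDBRecord:
    """Read one WFDB record (header + signal files) into physical units."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"WFDB header not found for record: {header_path}")
    name, n_sig, fs, n_samples, specs = _parse_header(header_path)

    columns: list[np.ndarray | None] = [None] * n_sig
    for file_name in dict.fromkeys(s.file_name for s in specs):
        members = [i for i, s in enumerate(specs) if s.file_name == file_name]
        dat_path = header_path.parent / file_name
        if not dat_path.exists():
            raise FileNotFoundError(
                f"WFDB signal file '{file_name}' missing for record {name}"
            )
        raw = np.fromfile(dat_path, dtype=np.uint8)
        fmt = specs[members[0]].fmt
        if fmt == 212:
            flat = _decode_212(raw, (len(raw) // 3) * 2)
        elif fmt == 16:
            flat = raw[: (len(raw) // 2) * 2].view("<i2").astype(np.int32)
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt} in record {name}")
        frames = len(flat) // len(members)
        flat = flat[: frames * len(members)].reshape(frames, len(members))
        for k, idx in enumerate(members):
            columns[idx] = flat[:, k]

    length = min(len(c) for c in columns)
    if n_samples:
        length = min(length, n_samples)
    physical = np.column_stack(
        [
            (columns[i][:length] - specs[i].baseline) / specs[i].gain
            for i in range(n_sig)
        ]
    )
    return WFDBRecord(name=name, fs=fs, n_samples=length, signals=physical)


def load_wfdb_segments(
    record_ids: list[str],
    segments_per_record: int,
    split: tuple[int, int],
    data_dir: str | Path = ".",
    channel: int = 0,
    target_fs: float = 250.0,
    n_samples: int = 250,
) -> LabeledDataset:
    """Window real records into a labeled dataset, one subject per record.

    Each record's chosen channel is resampled to ``target_fs`` if needed,
    cut into consecutive non-overlapping ``n_samples``-sample windows, and
    per-window amplitude-normalized; the first ``split[0]`` windows become
    the train split and the next ``split[1]`` the test split
    (``split[0] + split[1] == segments_per_record``).
    """
    if not record_ids:
        raise ValueError("record list is empty — no dataset to build")
    train_count, test_count = split
    if train_count + test_count != segments_per_record:
        raise ValueError("split counts must sum to segments_per_record")

    data_dir = Path(data_dir)
    segments: list[ECGSegment] = []
    splits: list[str] = []
    for label, record_id in enumerate(record_ids, start=1):
        record = read_record(data_dir / f"{record_id}.hea")
        signal = record.signals[:, channel]
        if record.fs != target_fs:
            ratio = Fraction(target_fs / record.fs).limit_denominator(1000)
            signal = resample_poly(signal, ratio.numerator, ratio.denominator)
        needed = segments_per_record * n_samples
        if len(signal) < needed:
            raise ValueError(
                f"record {record_id} holds {len(signal)} samples at {target_fs} Hz, "
                f"but {needed} are required for {segments_per_record} windows"
            )
        for w in range(segments_per_record):
            window = signal[w * n_samples : (w + 1) * n_samples]
            segments.append(ECGSegment(_normalize(window), label, None))
            splits.append("train" if w < train_count else "test")
    return LabeledDataset(
        segments,
        splits,
        seed=None,
        params={
            "records": list(record_ids),
            "segments_per_record": segments_per_record,
            "split": [train_count, test_count],
        },
    )
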