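"""Binary serialization of per-crystal calibration records (Mille-style files).

Layout (all little-endian): an 8-byte header — magic ``b"MILE"``, then uint16
format version (1) and the uint16 endianness tag 0x0102 — followed by records.
Each record is an int32 word count n, then n float32 values, then n int32
tags.  Per measurement the (value, tag) stream is:

    (0, 0)                          marker opening the measurement
    (d_local_j, j + 1)              local derivatives, 1-based local index
    (residual, 0)                   the measurement value
    (d_global_l, label_l + 1)       global derivatives, 1-based global label
    (sigma, 0)                      the measurement standard error

Zero derivatives are not written.  The layout is modeled on the Millepede-II
data-file concept; self round-tripping is guaranteed bit-exactly for float32
payloads, byte compatibility with other implementations is not.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .localfit import MilleRecord

__all__ = ["write_mille", "read_mille", "MilleFormatError"]

MAGIC = b"MILE"
VERSION = 1
ENDIAN_TAG = 0x0102


class MilleFormatError(ValueError):
    """Raised on malformed Mille files."""


def _encode_record(record: MilleRecord):
    values, tags = [], []
    A = record.local_derivs
    G = record.global_derivs
    labels = record.global_labels
    for i in range(record.n_measurements):
        values.append(0.0)
        tags.append(0)
        for j in range(A.shape[1]):
            if A[i, j] != 0.0:
                values.append(A[i, j])
                tags.append(j + 1)
        values.append(record.values[i])
        tags.append(0)
        for col, label in enumerate(labels):
            if G[i, col] != 0.0:
                values.append(G[i, col])
                tags.append(int(label) + 1)
        values.append(record.sigmas[i])
        tags.append(0)
    return np.asarray(values, dtype="<f4"), np.asarray(tags, dtype="<i4")


def write_mille(records, path) -> Path:
    """Write records to ``path``; returns the path."""
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(MAGIC + struct.pack("<HH", VERSION, ENDIAN_TAG))
        for record in records:
            values, tags = _encode_record(record)
            fh.write(struct.pack("<i", len(values)))
            fh.write(values.tobytes())
            fh.write(tags.tobytes())
    return path


def _decode_record(values: np.ndarray, tags: np.ndarray, index: int) -> MilleRecord:
    # split the stream at measurement boundaries: each measurement holds
    # exactly three 0-tagged words (marker, value, sigma)
    zero_pos = np.nonzero(tags == 0)[0]
    if len(zero_pos) % 3 != 0:
        raise MilleFormatError(f"record {index}: malformed tag sequence")
    meas_values, meas_sigmas, local_rows, global_rows = [], [], [], []
    n_local = 0
    global_labels: dict[int, int] = {}
    spans = []
    for m in range(len(zero_pos) // 3):
        marker, vpos, spos = zero_pos[3 * m:3 * m + 3]
        if values[marker] != 0.0:
            raise MilleFormatError(f"record {index}: measurement {m} marker not zero")
        local_span = (marker + 1, vpos)
        global_span = (vpos + 1, spos)
        for p in range(*local_span):
            n_local = max(n_local, int(tags[p]))
        for p in range(*global_span):
            global_labels.setdefault(int(tags[p]) - 1, len(global_labels))
        meas_values.append(float(values[vpos]))
        meas_sigmas.append(float(values[spos]))
        spans.append((local_span, global_span))
    labels_sorted = sorted(global_labels)
    col_of = {lab: i for i, lab in enumerate(labels_sorted)}
    n_meas = len(meas_values)
    A = np.zeros((n_meas, n_local), dtype=np.float32)
    G = np.zeros((n_meas, len(labels_sorted)), dtype=np.float32)
    for m, (local_span, global_span) in enumerate(spans):
        for p in range(*local_span):
            A[m, int(tags[p]) - 1] = values[p]
        for p in range(*global_span):
            G[m, col_of[int(tags[p]) - 1]] = values[p]
    return MilleRecord(
        values=np.asarray(meas_values, dtype=np.float32),
        sigmas=np.asarray(meas_sigmas, dtype=np.float32),
        local_derivs=A,
        global_labels=np.asarray(labels_sorted, dtype=int),
        global_derivs=G,
        crystal_id=index,
    )


def read_mille(path) -> list:
    """Read a Mille file written by :func:`write_mille`."""
    data = Path(path).read_bytes()
    if len(data) < 8 or data[:4] != MAGIC:
        raise MilleFormatError("not a Mille file (bad magic)")
    version, endian = struct.unpack("<HH", data[4:8])
    if version != VERSION or endian != ENDIAN_TAG:
        raise MilleFormatError(f"unsupported version/endianness: {version}/{endian:#x}")
    records = []
    offset = 8
    index = 0
    while offset < len(data):
        if offset + 4 > len(data):
            raise MilleFormatError(f"record {index}: truncated word count")
        (n,) = struct.unpack_from("<i", data, offset)
        offset += 4
        need = 8 * n
        if n < 0 or offset + need > len(data):
            raise MilleFormatError(f"record {index}: truncated payload")
        values = np.frombuffer(data, dtype="<f4", count=n, offset=offset)
        tags = np.frombuffer(data, dtype="<i4", count=n, offset=offset + 4 * n)
        records.append(_decode_record(values, tags, index))
        offset += need
        index += 1
    return records
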