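"""Minimal EDF (European Data Format) writing and reading for EEG recordings.

Writing implements the plain continuous EDF layout directly — an ASCII
header (256 bytes plus 256 per signal) followed by one-second data records
of little-endian 16-bit integers — which is all the pipeline needs for its
16-channel, uniformly sampled recordings.  Reading delegates to MNE's EDF
reader, which also serves as an independent check on files we write.

The header's start date/time are fixed (01.01.2000) so that re-running a
simulation with the same seed produces byte-identical files; real
timestamps belong in the run manifest.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .spectral import EegRecording

__all__ = ["write_edf", "read_edf"]


def _ascii(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF header field too long: {text!r} (max {width})")
    return text.ljust(width).encode("ascii")


def write_edf(rec: EegRecording, path: str | Path) -> Path:
    """Write an :class:`EegRecording` (microvolts) to ``path`` as EDF.

    The sampling rate must be a positive integer (samples per one-second
    record); the recording is truncated to whole seconds.  Each channel is
    scaled into the full 16-bit digital range against a shared symmetric
    physical range, so quantization error is below physical_max / 32767.
    """
    path = Path(path)
    rate = rec.rate
    if rate != int(rate) or rate <= 0:
        raise ValueError("EDF writing requires an integer sampling rate")
    spr = int(rate)  # samples per 1 s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_ch = rec.n_channels
    data = rec.data[:, : n_records * spr]

    phys_max = float(np.max(np.abs(data)))
    phys_max = math.ceil(phys_max) + 1.0 if phys_max > 0 else 1.0
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    header = bytearray()
    header += _ascii("0", 8)  # version
    header += _ascii("X X X X", 80)  # local patient identification
    header += _ascii("Startdate 01-JAN-2000 X fesloop synthetic", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)  # record duration, seconds
    header += _ascii(n_ch, 4)
    for label in rec.labels:
        header += _ascii(label, 16)
    header += b"".join(_ascii("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch))
    header += b"".join(_ascii(f"{-phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(_ascii(f"{phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(_ascii(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_ascii(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_ascii(spr, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within the record
    return path


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF file into an :class:`EegRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return EegRecording(data=data, rate=float(raw.info["sfreq"]), labels=raw.ch_names)
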