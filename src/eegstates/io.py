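"""EEG container and file I/O.

The in-memory container is :class:`EEGRecording`, a channels x samples
potential matrix in microvolts with a sampling rate and unique channel
labels.  Two on-disk formats are supported:

* plain EDF (16-bit), read through MNE-Python and written by a minimal
  single-rate writer;
* a delimited matrix: UTF-8 CSV, one column per channel, first row the
  channel labels, with the sampling rate in a ``# sampling_rate_hz=``
  header comment.

Cohort metadata travels as a CSV table with columns
``subject_id,group,hamd_baseline,hamd_post``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

_CSV_RATE_KEY = "# sampling_rate_hz="

METADATA_COLUMNS = ["subject_id", "group", "hamd_baseline", "hamd_post"]


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    potentials : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    sampling_rate : float
        Samples per second (Hz), > 0.
    ch_names : list of str
        Unique channel labels, one per row of ``potentials``.
    positions : ndarray, shape (n_channels, 2 or 3), optional
        Electrode coordinates; required only by operations that use
        geometry (interpolation, canonical map labeling).
    """

    potentials: np.ndarray
    sampling_rate: float
    ch_names: list[str]
    positions: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.potentials = np.atleast_2d(np.asarray(self.potentials, dtype=float))
        if self.potentials.ndim != 2:
            raise ValueError("potentials must be a 2-D channels x samples matrix")
        if not np.isfinite(self.potentials).all():
            raise ValueError("potentials contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.ch_names = [str(c) for c in self.ch_names]
        if len(self.ch_names) != self.potentials.shape[0]:
            raise ValueError("one channel label required per potentials row")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.n_channels:
                raise ValueError("one position required per channel")

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, potentials: np.ndarray) -> "EEGRecording":
        return replace(self, potentials=np.asarray(potentials, dtype=float))


def write_recording(rec: EEGRecording, path: str | os.PathLike, fmt: str | None = None) -> Path:
    """Write a recording as EDF or delimited CSV (format from extension if omitted)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported recording format: {fmt!r}")
    return path


def read_recording(path: str | os.PathLike, fmt: str | None = None) -> EEGRecording:
    """Read an EDF or delimited-CSV recording from disk."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported recording format: {fmt!r}")


def _write_csv(rec: EEGRecording, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_CSV_RATE_KEY}{rec.sampling_rate:g}\n")
        fh.write(",".join(rec.ch_names) + "\n")
        np.savetxt(fh, rec.potentials.T, fmt="%.6f", delimiter=",")


def _read_csv(path: Path) -> EEGRecording:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith(_CSV_RATE_KEY):
            raise ValueError(f"{path}: missing '{_CSV_RATE_KEY}' header comment")
        rate = float(header[len(_CSV_RATE_KEY):])
        labels = [c.strip() for c in fh.readline().strip().split(",")]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}: duplicate channel labels")
        frame = pd.read_csv(fh, header=None)
    if frame.shape[1] != len(labels):
        raise ValueError(f"{path}: inconsistent channel count")
    return EEGRecording(frame.to_numpy(dtype=float).T, rate, labels)


# --- minimal plain-EDF support ------------------------------------------------
# EDF stores 16-bit integers scaled per channel between a physical and a
# digital range; the header is fixed-width ASCII.  Only single-rate,
# single-datarecord-layout files are produced here, which is all the
# package's own artifacts require.  Reading goes through MNE after a
# header check that rejects mixed-rate files.

def _edf_field(value: str, width: int) -> bytes:
    text = value[:width].ljust(width)
    return text.encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    data = rec.potentials
    n_ch, n_samp = data.shape
    # one-second records when the rate divides the length, else one record
    spr = int(round(rec.sampling_rate))
    if spr <= 0 or n_samp % spr != 0 or abs(rec.sampling_rate - spr) > 1e-9:
        spr = n_samp
    n_rec = n_samp // spr
    rec_dur = spr / rec.sampling_rate

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),          # patient id (anonymous)
        _edf_field("Startdate X", 80),      # recording id
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_field(f"{rec_dur:g}", 8),
        _edf_field(str(n_ch), 4),
    ])
    header += b"".join(_edf_field(lbl, 16) for lbl in rec.ch_names)
    header += b"".join(_edf_field("EEG", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmin)
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmax)
    header += b"".join(_edf_field(str(dmin), 8) for _ in range(n_ch))
    header += b"".join(_edf_field(str(dmax), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    # re-read the physical ranges exactly as an EDF reader will parse them,
    # so quantization is computed against the stored (truncated) values
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (dmax - dmin) / (pmax_r - pmin_r)
    digital = np.clip(
        np.rint((data - pmin_r[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def _edf_header_rates(path: Path) -> tuple[int, list[float]]:
    """Parse signal count and per-signal rates from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        rec_dur = float(head[244:252].decode("ascii").strip() or "1")
        n_sig = int(head[252:256].decode("ascii").strip())
        sig_head = fh.read(256 * n_sig)
    off = 16 * n_sig + 80 * n_sig + 8 * n_sig + 8 * n_sig + 8 * n_sig + 8 * n_sig + 8 * n_sig + 80 * n_sig
    spr = [
        int(sig_head[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_sig)
    ]
    if rec_dur <= 0:
        raise ValueError(f"{path}: non-positive EDF record duration")
    return n_sig, [s / rec_dur for s in spr]


def _read_edf(path: Path) -> EEGRecording:
    n_sig, rates = _edf_header_rates(path)
    data_rates = [r for r in rates]
    if len(set(data_rates)) > 1:
        raise ValueError(
            f"{path}: EDF signals have mixed sampling rates {sorted(set(data_rates))}; "
            "only single-rate files are supported"
        )
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    potentials = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(potentials, float(raw.info["sfreq"]), list(raw.ch_names))


def write_metadata(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write the subject metadata table (subject_id, group, HAMD scores)."""
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    path = Path(path)
    table.loc[:, METADATA_COLUMNS].to_csv(path, index=False)
    return path


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: metadata table missing columns: {missing}")
    return table
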