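"""Reading, filtering and segmenting multichannel EEG.

A :class:`Recording` is a full-length multichannel signal (microvolts); an
:class:`EEGSegment` is one fixed-length analysis window cut from it.  EDF
files are read through :mod:`mne`; a minimal 16-bit EDF writer is provided
for exporting synthetic recordings (one data record per second).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .defaults import (
    FILTER_HI,
    FILTER_LO,
    N_CHANNELS,
    RATE,
    SEGMENT_SECONDS,
)


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclass
class Recording:
    """Full multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz, identical for every channel.
    channel_names : list of str
        Channel labels in storage order.
    """

    data: np.ndarray
    rate: float
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate


@dataclass
class EEGSegment:
    """One fixed-length analysis window.

    ``data`` is channels x samples in microvolts; the canonical window is
    23 x 2560 (10 s at 256 Hz).  ``label`` is ``"ictal"``, ``"interictal"``
    or ``"unknown"``.
    """

    data: np.ndarray
    rate: float = RATE
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite values")
        if self.label not in ("ictal", "interictal", "unknown"):
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def require_standard(self, override: bool = False) -> "EEGSegment":
        """Refuse segments that are not 23-channel unless overridden.

        Network and oscillator stages are specified at N=23; this guard
        makes accidental channel loss loud rather than silent.
        """
        if not override and self.n_channels != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channels, got {self.n_channels}; "
                "pass override=True to proceed anyway"
            )
        return self


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def _edf_header_rates(path: str):
    """Parse per-signal samples-per-record from an EDF header.

    Used to reject files whose channels are stored at different rates
    before handing the file to the reader (which would silently resample).
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        record_dur = float(header[244:252].decode("ascii", "replace").strip() or "0")
        ns = int(header[252:256].decode("ascii", "replace").strip())
        sig = fh.read(ns * 256)
    # per-signal layout: label(16) transducer(80) dim(8) pmin(8) pmax(8)
    # dmin(8) dmax(8) prefilter(80) n_samples(8) reserved(32)
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    samps = [
        int(sig[off + i * 8: off + (i + 1) * 8].decode("ascii", "replace").strip())
        for i in range(ns)
    ]
    labels = [sig[i * 16:(i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)]
    return record_dur, labels, samps


def read_edf(path: str) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Channel order is preserved as stored.  Files whose channels are sampled
    at different rates are rejected with :class:`FormatError`.
    """
    if not path or not os.path.exists(path):
        raise IOError(f"EDF file not found: {path}")
    record_dur, _labels, samps = _edf_header_rates(path)
    data_samps = [s for s in samps if s > 0]
    if len(set(data_samps)) > 1:
        raise FormatError(
            f"{path}: channels have non-uniform sampling rates {sorted(set(data_samps))}"
        )

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned EEG
    return Recording(data=data, rate=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names))


def write_edf(path: str, rec: Recording) -> None:
    """Write a recording as 16-bit EDF, one data record per second.

    The recording duration must be an integer number of seconds (records).
    """
    n_ch, n_samp = rec.data.shape
    spr = int(round(rec.rate))  # samples per 1 s record
    if n_samp % spr != 0:
        raise ValueError("recording length must be a whole number of seconds")
    n_rec = n_samp // spr

    pmax = float(np.max(np.abs(rec.data))) if n_samp else 1.0
    pmax = max(pmax, 1.0)
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", "replace")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("EDF", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        [pad(nm, 16) for nm in rec.channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{-pmax:.6g}"[:8], 8)] * n_ch,
        [pad(f"{pmax:.6g}"[:8], 8)] * n_ch,
        [pad(str(dmin), 8)] * n_ch,
        [pad(str(dmax), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    scale = (dmax - dmin) / (2 * pmax)
    digital = np.clip(np.round((rec.data + pmax) * scale) + dmin, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(digital[:, sl].tobytes())


# ---------------------------------------------------------------------------
# Segmentation and filtering
# ---------------------------------------------------------------------------

def segment_recording(rec: Recording, window_s: float = SEGMENT_SECONDS,
                      label: str = "unknown", source_id: str = "") -> list:
    """Split a recording into non-overlapping fixed-length segments.

    A trailing partial window is dropped; the number of segments is
    ``floor(duration / window_s)``.  A recording shorter than one window
    yields an empty list (warning condition, not an error).
    """
    win = int(round(window_s * rec.rate))
    n_seg = rec.data.shape[1] // win
    return [
        EEGSegment(
            data=rec.data[:, i * win:(i + 1) * win].copy(),
            rate=rec.rate, label=label,
            source_id=f"{source_id}[{i}]" if source_id else str(i),
        )
        for i in range(n_seg)
    ]


def bandpass_filter(seg: EEGSegment, lo: float = FILTER_LO,
                    hi: float = FILTER_HI, order: int = 4) -> EEGSegment:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering preserves instantaneous phase, which the
    Hilbert stages depend on.  ``hi`` must stay below Nyquist.
    """
    nyq = seg.rate / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"hi={hi} must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=seg.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, seg.data, axis=1)
    return replace(seg, data=np.ascontiguousarray(filtered))


def remove_artifacts(seg: EEGSegment) -> EEGSegment:
    """Artifact-removal hook (identity).

    Scalp recordings carry blink/EMG/line artifacts that real studies clean
    with ICA; synthetic signals carry none, so this stage is a documented
    no-op kept so the pipeline's stage order matches a real deployment.
    """
    return seg
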