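"""Minimal EDF+C I/O for synthetic recordings.

Writing is implemented directly against the EDF+ byte layout (256-byte
fixed header, 256 bytes per signal, 16-bit little-endian samples in 1-s
data records, seizure onsets encoded as time-stamped annotation lists in a
dedicated ``EDF Annotations`` signal). Reading goes through
:func:`mne.io.read_raw_edf`.

Signals are stored in microvolt units with per-channel physical scaling
fitted to the data range, so the representable resolution is
``(max - min) / 65535`` per channel; round-trips are exact only up to that
16-bit quantization step.
"""

from __future__ import annotations

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767
_ANN_BYTES = 120  # annotation signal bytes per 1-s record


def _pad(value, n: int) -> bytes:
    raw = str(value).encode("ascii")[:n]
    return raw + b" " * (n - len(raw))


def _fmt8(v: float) -> str:
    s = f"{v:.6f}"
    if len(s) > 8:
        s = s[:8].rstrip(".")
    return s


def quantization_step(signal: np.ndarray) -> np.ndarray:
    """Per-channel physical value of one digital unit for ``signal``."""
    span = signal.max(axis=0) - signal.min(axis=0)
    span = np.where(span < 1e-12, 1.0, span)
    return span / (_DIG_MAX - _DIG_MIN)


def write_edf(
    path,
    signal: np.ndarray,
    sampling_rate: int,
    channel_labels,
    annotations=(),
    patient_id: str = "X",
) -> None:
    """Write ``signal`` ([n_samples, n_channels], arbitrary units read as uV)
    as an EDF+C file with 1-s records.

    ``annotations`` is an iterable of ``(onset_seconds, duration_seconds,
    text)``. ``n_samples`` must be a whole number of seconds.
    """
    signal = np.asarray(signal, dtype=float)
    n_samples, n_ch = signal.shape
    sampling_rate = int(sampling_rate)
    if n_samples % sampling_rate:
        raise ValueError("signal length must be a whole number of seconds")
    n_rec = n_samples // sampling_rate

    pmin = signal.min(axis=0)
    step = quantization_step(signal)
    pmax = pmin + step * (_DIG_MAX - _DIG_MIN)
    digital = np.rint((signal - pmin) / step + _DIG_MIN).astype("<i2")

    tals = [b"+%d\x14\x14\x00" % r for r in range(n_rec)]
    for onset, duration, text in annotations:
        rec = min(int(onset), n_rec - 1)
        tal = f"+{onset:g}\x15{duration:g}\x14{text}\x14\x00".encode("ascii")
        if len(tals[rec]) + len(tal) > _ANN_BYTES:
            raise ValueError(f"too many annotations in record {rec}")
        tals[rec] += tal

    ns = n_ch + 1
    labels = [f"EEG {c}" for c in channel_labels] + ["EDF Annotations"]
    hdr = b"".join(
        [
            _pad("0", 8),
            _pad(f"{patient_id} X X X", 80),
            _pad("Startdate 01-JAN-2020 X X X", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(256 * (ns + 1), 8),
            _pad("EDF+C", 44),
            _pad(n_rec, 8),
            _pad("1", 8),
            _pad(ns, 4),
        ]
        + [_pad(lab, 16) for lab in labels]
        + [_pad("", 80)] * ns                               # transducer
        + [_pad("uV", 8)] * n_ch + [_pad("", 8)]            # dimension
        + [_pad(_fmt8(v), 8) for v in pmin] + [_pad(-1, 8)]
        + [_pad(_fmt8(v), 8) for v in pmax] + [_pad(1, 8)]
        + [_pad(_DIG_MIN, 8)] * ns
        + [_pad(_DIG_MAX, 8)] * ns
        + [_pad("", 80)] * ns                               # prefiltering
        + [_pad(sampling_rate, 8)] * n_ch + [_pad(_ANN_BYTES // 2, 8)]
        + [_pad("", 32)] * ns
    )
    if len(hdr) != 256 * (ns + 1):  # pragma: no cover - layout guard
        raise AssertionError("malformed EDF header")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_rec):
            block = digital[rec * sampling_rate : (rec + 1) * sampling_rate]
            fh.write(block.T.tobytes())
            fh.write(tals[rec].ljust(_ANN_BYTES, b"\x00"))


def read_edf(path):
    """Read an EDF file.

    Returns ``(signal [n_samples, n_channels] in uV, sampling_rate,
    channel_labels, onset_seconds)`` where ``onset_seconds`` lists the
    start times of ``seizure`` annotations.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data(units="uV").T
    labels = [name.removeprefix("EEG ").strip() for name in raw.ch_names]
    onsets = [
        float(onset)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if "seizure" in desc.lower()
    ]
    return signal, float(raw.info["sfreq"]), labels, sorted(onsets)
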