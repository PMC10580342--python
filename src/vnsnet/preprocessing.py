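"""Ictal epoch extraction and cohort preparation.

A recording with annotated seizure onsets is reduced to fixed-size epoch
matrices: 60 s of raw signal per onset, each second collapsed to its
per-channel mean, yielding a 60 x 19 matrix per epoch. Patients are then
balanced to a fixed epoch count by bootstrap resampling of their own raw
epochs, and split into discovery/testing cohorts by stratified random
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vnsnet import edf
from vnsnet.montage import CHANNELS, N_CHANNELS, channel_index

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NONRESPONDER = "nonresponder"


@dataclass(eq=False)
class RawRecording:
    """Continuous multichannel EEG with seizure-onset annotations.

    ``signal`` is [n_samples, n_channels] in recording units; ``onsets``
    are sample indices of seizure starts.
    """

    signal: np.ndarray
    sampling_rate: int
    channel_labels: tuple[str, ...]
    onsets: list[int]
    patient_id: str

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.channel_labels):
            raise ValueError("signal shape does not match channel labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        self.onsets = sorted(int(o) for o in self.onsets)


@dataclass(eq=False)
class EpochMatrix:
    """One ictal epoch as per-second channel means ([60, 19])."""

    values: np.ndarray
    patient_id: str
    label: str
    origin: str = "raw"  # raw | bootstrap
    source_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("epoch contains non-finite values")


@dataclass
class CohortAssignment:
    discovery: set[str]
    testing: set[str]
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def cohort_of(self, patient_id: str) -> str:
        if patient_id in self.discovery:
            return "discovery"
        if patient_id in self.testing:
            return "testing"
        raise KeyError(patient_id)


def canonicalize_channels(signal: np.ndarray, labels) -> np.ndarray:
    """Reorder signal columns into the canonical 10-20 montage order.

    Labels are matched case-insensitively; unknown labels raise.
    """
    order = [channel_index(lab) for lab in labels]
    if sorted(order) != list(range(N_CHANNELS)):
        raise ValueError("labels do not cover the 19-channel montage exactly")
    out = np.empty_like(np.asarray(signal, dtype=float))
    out[:, order] = signal
    return out


def extract_ictal_epochs(
    rec: RawRecording, epoch_seconds: int = 60
) -> list[np.ndarray]:
    """Cut one raw signal block per seizure onset.

    Blocks start exactly at the onset sample and span ``epoch_seconds``.
    Overlapping windows keep the earlier onset and drop the later one with
    a warning; a window running past the end of the recording is an error.
    """
    window = int(epoch_seconds * rec.sampling_rate)
    blocks: list[np.ndarray] = []
    last_end = -1
    for onset in rec.onsets:
        if onset + window > rec.signal.shape[0]:
            raise ValueError(
                f"onset {onset} of patient {rec.patient_id}: window exceeds recording"
            )
        if onset < last_end:
            logger.warning(
                "patient %s: onset %d overlaps previous window, dropped",
                rec.patient_id,
                onset,
            )
            continue
        blocks.append(rec.signal[onset : onset + window])
        last_end = onset + window
    return blocks


def per_second_average(block: np.ndarray, sampling_rate: int = 1000) -> np.ndarray:
    """Collapse a raw block to per-second channel means.

    Row j of the output is the mean of raw rows [j*rate, (j+1)*rate),
    computed per channel over nonoverlapping 1-s windows.
    """
    block = np.asarray(block, dtype=float)
    n, p = block.shape
    rate = int(sampling_rate)
    if n % rate:
        raise ValueError(f"{n} samples do not divide into whole seconds at {rate} Hz")
    return block.reshape(n // rate, rate, p).mean(axis=1)


def epochs_from_recording(
    rec: RawRecording, label: str, epoch_seconds: int = 60
) -> list[EpochMatrix]:
    """Extract, average and wrap every ictal epoch of one recording."""
    signal = canonicalize_channels(rec.signal, rec.channel_labels)
    rec = RawRecording(signal, rec.sampling_rate, CHANNELS, rec.onsets, rec.patient_id)
    return [
        EpochMatrix(
            per_second_average(block, rec.sampling_rate),
            patient_id=rec.patient_id,
            label=label,
            origin="raw",
            source_index=k,
        )
        for k, block in enumerate(extract_ictal_epochs(rec, epoch_seconds))
    ]


def load_recording(path, patient_id: str) -> RawRecording:
    """Read one EDF file into a RawRecording (onsets to sample indices)."""
    signal, sfreq, labels, onset_seconds = edf.read_edf(path)
    onsets = [int(round(o * sfreq)) for o in onset_seconds]
    return RawRecording(signal, int(sfreq), tuple(labels), onsets, patient_id)


def bootstrap_augment(
    epochs: list[EpochMatrix], target: int = 56, seed=None, mode: str = "keep_raw"
) -> list[EpochMatrix]:
    """Balance one patient to exactly ``target`` epochs.

    Default ``mode='keep_raw'``: every raw epoch is kept once and the
    remainder is filled by drawing raw epochs with replacement (values
    copied verbatim, tagged ``origin='bootstrap'``).
    ``mode='resample_all'`` instead draws all ``target`` slots with
    replacement. Deterministic under ``seed``.
    """
    if not epochs:
        raise ValueError("patient has no raw epochs")
    pids = {e.patient_id for e in epochs}
    if len(pids) != 1:
        raise ValueError("bootstrap_augment is per-patient; got multiple ids")
    if mode not in ("keep_raw", "resample_all"):
        raise ValueError("mode must be 'keep_raw' or 'resample_all'")
    if mode == "keep_raw" and len(epochs) > target:
        raise ValueError(
            f"patient {epochs[0].patient_id} has {len(epochs)} raw epochs "
            f"> target {target}; configure subsampling instead"
        )
    rng = np.random.default_rng(seed)
    out = list(epochs) if mode == "keep_raw" else []
    draws = rng.integers(0, len(epochs), size=target - len(out))
    for idx in draws:
        src = epochs[idx]
        out.append(
            EpochMatrix(
                src.values.copy(),
                patient_id=src.patient_id,
                label=src.label,
                origin="bootstrap",
                source_index=src.source_index,
            )
        )
    return out


def assign_cohorts(
    manifest: pd.DataFrame,
    n_disc_resp: int = 10,
    n_disc_nonresp: int = 6,
    seed=None,
) -> CohortAssignment:
    """Stratified random discovery/testing split of the patient manifest.

    ``manifest`` needs columns ``patient_id`` and ``label``. Per stratum,
    the requested number of patients is drawn uniformly without
    replacement into the discovery cohort; the rest go to testing.
    """
    rng = np.random.default_rng(seed)
    discovery: set[str] = set()
    for label, k in ((RESPONDER, n_disc_resp), (NONRESPONDER, n_disc_nonresp)):
        ids = sorted(manifest.loc[manifest["label"] == label, "patient_id"])
        if len(ids) < k:
            raise ValueError(f"need {k} {label}s for discovery, have {len(ids)}")
        discovery.update(rng.choice(ids, size=k, replace=False))
    testing = set(manifest["patient_id"]) - discovery
    counts = {
        cohort: {
            label: int(
                manifest["patient_id"].isin(members)[manifest["label"] == label].sum()
            )
            for label in (RESPONDER, NONRESPONDER)
        }
        for cohort, members in (("discovery", discovery), ("testing", testing))
    }
    return CohortAssignment(discovery=discovery, testing=testing, counts=counts)
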