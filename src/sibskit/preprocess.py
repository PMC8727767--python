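"""EEG preprocessing and GCS-guided section selection.

Preprocessing is deliberately minimal and mirrors routine clinical-EEG
practice: re-reference every channel to the instantaneous cross-channel
average, then band-pass 0.5-45 Hz (zero-phase 4th-order Butterworth) to
attenuate drift, muscle artifact and line noise.  Artifact cleaning proper
(manual exclusion, ICA) is out of scope; cleaned-out stretches enter only as
a boolean ``bad_mask`` that downstream statistics exclude.

Section selection implements a greedy minimum-responsiveness rule: sort GCS
assessments ascending by score (ties broken by earlier timestamp), seed the
selection with the lowest, then walk the sorted list adding any assessment
whose timestamp is at least ``min_spacing_h`` (default 24 h) from every
already-selected one.  A fixed-duration EEG section (default 600 s) is then
extracted starting at each selected timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "GCSSeries",
    "EEGRecord",
    "EEGSection",
    "rereference_average",
    "bandpass",
    "select_section_times",
    "extract_sections",
]


@dataclass
class GCSSeries:
    """Timestamped Glasgow Coma Scale assessments (hours since admission)."""

    timestamps: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.scores = np.asarray(self.scores, dtype=int)
        if self.timestamps.shape != self.scores.shape:
            raise ValueError("timestamps and scores must have equal length")
        if self.timestamps.size == 0:
            raise ValueError("empty GCS series")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any((self.scores < 3) | (self.scores > 15)):
            raise ValueError("GCS scores must lie in [3, 15]")

    def __len__(self) -> int:
        return self.timestamps.size

    def score_at(self, t: float) -> int:
        """Score of the assessment nearest in time to ``t`` (hours)."""
        return int(self.scores[np.argmin(np.abs(self.timestamps - t))])


@dataclass
class EEGRecord:
    """A multichannel EEG recording: channels x samples, microvolts."""

    signal: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    start_time: float = 0.0          # hours since admission
    bad_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.signal.shape[1], dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if self.bad_mask.shape != (self.signal.shape[1],):
            raise ValueError("bad_mask length must equal number of samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EEGSection:
    """A fixed-duration excerpt of an :class:`EEGRecord`.

    ``usable`` is False when extraction failed or the bad mask covers more
    than the allowed fraction; ``note`` says why.
    """

    signal: np.ndarray
    fs: float
    t0: float                        # hours since admission
    duration_s: float
    gcs_at_extraction: Optional[int] = None
    bad_mask: Optional[np.ndarray] = None
    patient_id: Optional[int] = None
    usable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.signal.shape[-1], dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def rereference_average(rec: EEGRecord) -> EEGRecord:
    """Subtract the instantaneous cross-channel mean from every channel.

    Requires at least two channels; the output cross-channel mean is zero at
    every sample (to floating-point tolerance).
    """
    if rec.n_channels < 2:
        raise ValueError("average re-reference requires >= 2 channels")
    out = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return EEGRecord(signal=out, fs=rec.fs, channel_labels=list(rec.channel_labels),
                     start_time=rec.start_time, bad_mask=rec.bad_mask.copy())


def bandpass(rec: EEGRecord, low_hz: float = 0.5, high_hz: float = 45.0,
             order: int = 4) -> EEGRecord:
    """Zero-phase Butterworth band-pass (default 0.5-45 Hz).

    Applied forward-backward (:func:`scipy.signal.sosfiltfilt`) so burst and
    suppression boundaries are not latency-shifted.
    """
    nyq = rec.fs / 2.0
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyq})")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return EEGRecord(signal=out, fs=rec.fs, channel_labels=list(rec.channel_labels),
                     start_time=rec.start_time, bad_mask=rec.bad_mask.copy())


def select_section_times(gcs: GCSSeries, min_spacing_h: float = 24.0) -> List[float]:
    """Greedy selection of minimum-responsiveness extraction times.

    Assessments are sorted ascending by (score, timestamp); the lowest seeds
    the selection, and each subsequent assessment is added iff its timestamp
    is at least ``min_spacing_h`` from every already-selected timestamp.

    Returns
    -------
    list of float
        Selected timestamps in chronological order; every pair differs by at
        least ``min_spacing_h``.
    """
    order = np.lexsort((gcs.timestamps, gcs.scores))
    selected: List[float] = []
    for idx in order:
        t = float(gcs.timestamps[idx])
        if all(abs(t - s) >= min_spacing_h for s in selected):
            selected.append(t)
    return sorted(selected)


def extract_sections(rec: EEGRecord, times: Sequence[float],
                     duration_s: float = 600.0,
                     gcs: Optional[GCSSeries] = None,
                     max_bad_fraction: float = 0.5,
                     patient_id: Optional[int] = None) -> List[EEGSection]:
    """Extract one fixed-duration section starting at each timestamp.

    A timestamp falling (partly) outside the recording yields a section with
    ``usable=False`` and an explanatory ``note`` rather than a global
    failure; a section whose bad mask covers more than ``max_bad_fraction``
    of its samples is likewise flagged unusable.
    """
    out: List[EEGSection] = []
    n_keep = int(round(duration_s * rec.fs))
    for t in times:
        score = gcs.score_at(t) if gcs is not None else None
        i0 = int(round((t - rec.start_time) * 3600.0 * rec.fs))
        if i0 < 0 or i0 + n_keep > rec.n_samples:
            out.append(EEGSection(
                signal=np.empty((rec.n_channels, 0)), fs=rec.fs, t0=float(t),
                duration_s=duration_s, gcs_at_extraction=score,
                bad_mask=np.empty(0, dtype=bool), patient_id=patient_id,
                usable=False, note="timestamp outside recording"))
            continue
        mask = rec.bad_mask[i0:i0 + n_keep].copy()
        usable = bool(mask.mean() <= max_bad_fraction)
        out.append(EEGSection(
            signal=rec.signal[:, i0:i0 + n_keep].copy(), fs=rec.fs, t0=float(t),
            duration_s=duration_s, gcs_at_extraction=score, bad_mask=mask,
            patient_id=patient_id, usable=usable,
            note="" if usable else "bad mask exceeds allowed fraction"))
    return out
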